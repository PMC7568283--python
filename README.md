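# nucleoshift

Case/control single-nucleus RNA-seq analysis pipeline: quality control,
graph-based clustering with marker annotation, per-cell-type differential
expression, and identification of disease-associated cell subpopulations by
DEG z-score enrichment, with proportion-shift quantification and
cross-study direction concordance.

The package is aimed at analysts working with cohort-style snRNA-seq
designs — several case and several control subjects, one 10x-convention
count matrix per subject — who want the standard Seurat-style workflow plus
the subpopulation-enrichment statistic as tested, scriptable Python. A
negative-binomial synthetic-cohort generator with complete ground truth
(planted cell types, subpopulations, DEGs and proportion shifts) is a
first-class part of the package and powers the validation suite.

## Method

For each annotated cell type the pipeline tests case vs control expression
gene-by-gene with the two-sample Wilcoxon rank-sum test on log-normalized
values (cells as units), computes

&nbsp;&nbsp;log<sub>2</sub>FC = log<sub>2</sub>[(mean(e<sup>x̄</sup><sub>case</sub> − 1) + ε) / (mean(e<sup>x̄</sup><sub>ctrl</sub> − 1) + ε)],

and calls a gene a DEG at adjusted *P* < 0.1 and |log<sub>2</sub>FC| ≥ 0.1
(Bonferroni by default, Benjamini–Hochberg selectable). Each glial or
vascular cell type is then re-clustered at a low, type-specific resolution
(astrocytes 0.2, endothelial 0.2, microglia 0.3, oligodendrocytes 0.2). For
a subpopulation *s* and DEG set *G* (up- and down-regulated sets scored
separately), the enrichment score is

&nbsp;&nbsp;E(s, G) = mean<sub>g∈G, c∈s</sub> z<sub>gc</sub>,

where z<sub>gc</sub> is gene *g*'s expression z-scored across **all** cells
of the type. A subpopulation with a score > 0.5 is classified
disease-associated (up- or down-regulated). Proportion shifts between
conditions are quantified with samples as the unit: per-sample within-type
shares, condition means ± SEM, the percentage-point difference and the
relative change. An external DE table (gene, signed effect, adjusted *P*)
can be matched against the internal DEGs to count replicable genes
(external adjusted *P* < 0.05) and their direction-concordance percentage.

Counts are read from Matrix Market files with genes as rows (1-based
indices, the 10x convention; transposed inputs are detected and
normalized); barcodes are namespaced `<sample_id>:<barcode>` on cohort
assembly. QC removes nuclei with ≤ 200 detected genes, ≥ 20,000 UMIs, or
≥ 20% mitochondrial UMIs ("MT-" symbol prefix). Clustering follows the
standard workflow: log-normalization (scale factor 10,000), top-1,000
variance-stabilized HVGs, PCA (50 computed, 20 used), shared-nearest-
neighbor graph (k = 20, Jaccard pruning at 1/15), Leiden modularity
clustering at resolution 1, and marker-reference annotation (AQP4
astrocytes, CLDN5 endothelial, CAMK2A excitatory neurons, GAD1 inhibitory
neurons, C3 microglia, MBP oligodendrocytes).

## Worked example

Run the whole pipeline on a simulated 21-subject cohort (12 case, 9
control, 400 nuclei/sample, 2,000 genes):

```python
import pandas as pd
from nucleoshift import PipelineConfig, run_all
from nucleoshift.synthetic_cohort import default_cohort_config

run_all(PipelineConfig(seed=1), "out", simulate=True,
        cohort_config=default_cohort_config(seed=1))

qc = pd.read_csv("out/qc/cell_qc.csv")
cells = pd.read_csv("out/cluster/cell_table.csv")
report = pd.read_csv("out/subshift/subpop_report.csv")
print(f"nuclei passing QC: {qc['keep'].sum()} / {len(qc)}")
print(f"clusters: {cells['cluster'].nunique()}")
print(report[report.cell_type == "astrocyte"]
      [["subpop", "mean_prop_case", "mean_prop_control", "delta_pp",
        "up_score", "down_score", "classification"]].round(3))
```

prints

```
nuclei passing QC: 7977 / 8400
clusters: 12
subpop  mean_prop_case  mean_prop_control  delta_pp  up_score  down_score classification
    s1           0.447              0.342    10.428     0.556      -0.391   up_regulated
    s2           0.376              0.413    -3.780    -0.227      -0.025     unaffected
    s3           0.178              0.244    -6.648    -0.653       0.811 down_regulated
```

All 420 planted debris nuclei are removed by QC; the 12 clusters annotate
to the six planted cell types. The astrocyte compartment resolves into
three subpopulations: s1 carries the up-regulated DEG signature (score
0.556 > 0.5) and expands by ~10 percentage points in cases, s3 carries the
down-regulated signature (0.811) and shrinks — exactly the planted
structure (+10 / −3 / −7 pp).

The same stages are available from the shell:

```bash
nucleoshift simulate --seed 1 --out cohort/
nucleoshift qc --in cohort/ --out qc/
nucleoshift cluster --in cohort/ --qc qc/ --out cluster/
nucleoshift de --cluster cluster/ --out de/
nucleoshift subshift --cluster cluster/ --de de/ --out subshift/
nucleoshift concord --de de/ --external external_de.csv --out concord.json
nucleoshift run-all --simulate --seed 1 --out out/
```

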