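"""End-to-end orchestration: qc -> cluster -> de -> subshift [-> concord].

Each stage reads its predecessor's serialized outputs and writes its own,
so any stage can be re-run in isolation; ``run_all`` chains them and emits
a reproducibility manifest (library versions, seed, config hash, per-stage
row counts).  Identical config + seed yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .celltype_de import DEThresholds, deg_overlap, run_celltype_de
from .cluster_annotate import (ClusterParams, cluster_and_annotate,
                               find_markers, log_normalize)
from .concordance import run_concordance
from .io_formats import (CountMatrix, SampleMetadata, frame_to_samples,
                         read_10x_mtx, read_table, samples_to_frame,
                         write_10x_mtx, write_table)
from .qc import QCThresholds, apply_qc_filters, compute_cell_qc, \
    pmd_independence, sample_qc_summary
from .subpop_shift import SubpopParams, analyze_subpopulations
from .synthetic_cohort import (CohortConfig, default_cohort_config,
                               generate_cohort, load_cohort, write_cohort)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "stage_simulate", "stage_qc",
           "stage_cluster", "stage_de", "stage_subshift", "stage_concord"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one serializable object."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    de: DEThresholds = field(default_factory=DEThresholds)
    subpop: SubpopParams = field(default_factory=SubpopParams)
    adjust_method: str = "bonferroni"
    concordance_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # propagate the global seed into the stage params
        self.cluster = dataclasses.replace(self.cluster, seed=self.seed)
        self.subpop = dataclasses.replace(self.subpop, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "qc": dataclasses.asdict(self.qc),
            "cluster": dataclasses.asdict(self.cluster),
            "de": dataclasses.asdict(self.de),
            "subpop": dataclasses.asdict(self.subpop),
            "adjust_method": self.adjust_method,
            "concordance_alpha": self.concordance_alpha,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            qc=QCThresholds(**d.get("qc", {})),
            cluster=ClusterParams(**d.get("cluster", {})),
            de=DEThresholds(**d.get("de", {})),
            subpop=SubpopParams(**d.get("subpop", {})),
            adjust_method=d.get("adjust_method", "bonferroni"),
            concordance_alpha=d.get("concordance_alpha", 0.05),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d or {})


# ---------------------------------------------------------------------------
# Stages (disk in, disk out)
# ---------------------------------------------------------------------------

def stage_simulate(cohort_config: CohortConfig | None, out_dir: str,
                   seed: int = 0) -> str:
    """Generate a synthetic cohort and serialize it under ``out_dir``."""
    if cohort_config is None:
        cohort_config = default_cohort_config(seed=seed)
    matrices, samples, truth = generate_cohort(cohort_config)
    write_cohort(out_dir, matrices, samples, truth)
    logger.info("simulate: %d samples, %d genes, %d cells/sample",
                len(samples), cohort_config.n_genes,
                cohort_config.cells_per_sample)
    return out_dir


def stage_qc(cohort_dir: str, out_dir: str,
             thresholds: QCThresholds | None = None) -> str:
    """Per-cell QC metrics + keep flags + per-sample summary."""
    if thresholds is None:
        thresholds = QCThresholds()
    matrices, samples, _ = load_cohort(cohort_dir)
    os.makedirs(out_dir, exist_ok=True)
    qc_tables, masks = [], []
    parts = []
    for meta, mat in zip(samples, matrices):
        qc = compute_cell_qc(mat)
        mask = apply_qc_filters(qc, thresholds)
        qc_tables.append(qc)
        masks.append(mask)
        part = qc.copy()
        part.insert(0, "sample_id", meta.sample_id)
        part["keep"] = mask
        parts.append(part)
    cell_qc = pd.concat(parts, ignore_index=True)
    write_table(cell_qc, os.path.join(out_dir, "cell_qc.csv"))
    summary = sample_qc_summary(matrices, samples, masks, qc_tables)
    write_table(summary, os.path.join(out_dir, "qc_summary.csv"))
    try:
        pmd = pmd_independence(summary)
    except ValueError:
        pmd = {}
    with open(os.path.join(out_dir, "pmd_independence.json"), "w") as fh:
        json.dump(pmd, fh, indent=2)
    logger.info("qc: kept %d/%d nuclei",
                int(cell_qc["keep"].sum()), len(cell_qc))
    return out_dir


def _assemble_filtered(cohort_dir: str, qc_dir: str
                       ) -> tuple[CountMatrix, pd.DataFrame,
                                  list[SampleMetadata]]:
    """Pool kept cells of all samples with sample-prefixed barcodes."""
    matrices, samples, _ = load_cohort(cohort_dir)
    cell_qc = pd.read_csv(os.path.join(qc_dir, "cell_qc.csv"))
    blocks, rows = [], []
    for meta, mat in zip(samples, matrices):
        keep = cell_qc.loc[cell_qc["sample_id"] == meta.sample_id, "keep"] \
            .to_numpy(dtype=bool)
        if keep.size != mat.n_cells:
            raise ValueError(
                f"QC mask length mismatch for sample {meta.sample_id}")
        blocks.append(mat.values[:, keep])
        for i in np.flatnonzero(keep):
            rows.append({
                "cell": f"{meta.sample_id}:{mat.cell_barcodes[i]}",
                "sample_id": meta.sample_id,
                "condition": meta.condition,
            })
    pooled = CountMatrix(
        sp.hstack(blocks), matrices[0].gene_ids, matrices[0].gene_symbols,
        [r["cell"] for r in rows])
    return pooled, pd.DataFrame(rows), samples


def stage_cluster(cohort_dir: str, qc_dir: str, out_dir: str,
                  params: ClusterParams | None = None,
                  reference: dict | None = None) -> str:
    """Cluster + annotate the QC-passed pooled cohort; persist artifacts."""
    pooled, cell_table, _ = _assemble_filtered(cohort_dir, qc_dir)
    os.makedirs(out_dir, exist_ok=True)
    result = cluster_and_annotate(pooled, params, reference)
    cell_table = cell_table.assign(
        cluster=result["labels"], cell_type=result["cell_types"])
    write_table(cell_table, os.path.join(out_dir, "cell_table.csv"))
    markers = find_markers(result["normalized"], pooled.gene_symbols,
                           result["labels"])
    write_table(markers, os.path.join(out_dir, "markers.csv"))
    write_10x_mtx(pooled, os.path.join(out_dir, "filtered_matrix"))
    logger.info("cluster: %d cells, %d clusters, types %s",
                pooled.n_cells, len(result["cluster_types"]),
                sorted(set(result["cluster_types"].values())))
    return out_dir


def stage_de(cluster_dir: str, out_dir: str,
             thresholds: DEThresholds | None = None,
             method: str = "bonferroni") -> str:
    """Per-cell-type case/control DE + cross-type overlap summary."""
    pooled = read_10x_mtx(os.path.join(cluster_dir, "filtered_matrix"))
    cell_table = pd.read_csv(os.path.join(cluster_dir, "cell_table.csv"))
    os.makedirs(out_dir, exist_ok=True)
    normalized = log_normalize(pooled)
    de = run_celltype_de(normalized, pooled.gene_symbols, cell_table,
                         thresholds, method=method)
    write_table(de, os.path.join(out_dir, "de_table.csv"))
    overlap = {}
    if not de.empty and de["cell_type"].nunique() >= 2:
        overlap = deg_overlap(de)
    with open(os.path.join(out_dir, "overlap_summary.json"), "w") as fh:
        json.dump(overlap, fh, indent=2)
    logger.info("de: %d records, %d significant", len(de),
                int(de["significant"].sum()) if not de.empty else 0)
    return out_dir


def stage_subshift(cluster_dir: str, de_dir: str, out_dir: str,
                   params: SubpopParams | None = None,
                   de_thresholds: DEThresholds | None = None) -> str:
    """Subcluster configured types, score/classify, quantify shifts."""
    pooled = read_10x_mtx(os.path.join(cluster_dir, "filtered_matrix"))
    cell_table = pd.read_csv(os.path.join(cluster_dir, "cell_table.csv"))
    de = pd.read_csv(os.path.join(de_dir, "de_table.csv"))
    os.makedirs(out_dir, exist_ok=True)
    normalized = log_normalize(pooled)
    result = analyze_subpopulations(pooled, normalized, cell_table, de,
                                    params, de_thresholds)
    write_table(result["report"], os.path.join(out_dir, "subpop_report.csv"))
    cells = cell_table.assign(subpop=result["subpop_labels"])
    write_table(cells, os.path.join(out_dir, "cell_subpops.csv"))
    for ctype, sig in result["signatures"].items():
        write_table(sig, os.path.join(out_dir, f"signature_{ctype}.csv"))
    logger.info("subshift: %d subpopulation rows", len(result["report"]))
    return out_dir


def stage_concord(de_dir: str, external_path: str, out_path: str,
                  alpha: float = 0.05) -> dict:
    """Concordance of the internal DE table with an external DE table."""
    internal = pd.read_csv(os.path.join(de_dir, "de_table.csv"))
    internal = internal[internal["significant"]]
    external = read_table(external_path, "external_de")
    result = run_concordance(internal, external, alpha)
    os.makedirs(os.path.dirname(out_path) or ".", exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(result, fh, indent=2)
    return result


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig, out_dir: str,
            cohort_dir: str | None = None,
            simulate: bool = False,
            cohort_config: CohortConfig | None = None,
            external_de_path: str | None = None) -> dict:
    """Run every stage in order and write a reproducibility manifest.

    Either ``cohort_dir`` points at an existing cohort (per-sample 10x
    directories + sample_metadata.csv) or ``simulate=True`` generates one.
    """
    os.makedirs(out_dir, exist_ok=True)
    if simulate:
        cohort_dir = stage_simulate(
            cohort_config, os.path.join(out_dir, "cohort"), seed=config.seed)
    if cohort_dir is None:
        raise ValueError("either cohort_dir or simulate=True is required")

    stages = {}
    qc_dir = stage_qc(cohort_dir, os.path.join(out_dir, "qc"), config.qc)
    stages["qc"] = {"rows": len(pd.read_csv(
        os.path.join(qc_dir, "cell_qc.csv")))}
    cluster_dir = stage_cluster(
        cohort_dir, qc_dir, os.path.join(out_dir, "cluster"),
        config.cluster)
    stages["cluster"] = {"rows": len(pd.read_csv(
        os.path.join(cluster_dir, "cell_table.csv")))}
    de_dir = stage_de(cluster_dir, os.path.join(out_dir, "de"), config.de,
                      config.adjust_method)
    stages["de"] = {"rows": len(pd.read_csv(
        os.path.join(de_dir, "de_table.csv")))}
    sub_dir = stage_subshift(cluster_dir, de_dir,
                             os.path.join(out_dir, "subshift"),
                             config.subpop, config.de)
    stages["subshift"] = {"rows": len(pd.read_csv(
        os.path.join(sub_dir, "subpop_report.csv")))}
    if external_de_path:
        result = stage_concord(de_dir, external_de_path,
                               os.path.join(out_dir, "concord.json"),
                               config.concordance_alpha)
        stages["concord"] = {"n_replicable": result["n_replicable"]}

    import scipy
    import sklearn
    manifest = {
        "nucleoshift_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": stages,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
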