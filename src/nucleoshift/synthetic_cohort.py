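"""Synthetic multi-sample case/control snRNA-seq cohort generator.

Emulates the statistical structure a case/control single-nucleus study
assumes: several samples per condition, a cell-type hierarchy with marker
genes, within-type subpopulations (with optional condition-dependent
proportion shifts and signature-gene overexpression), condition-specific
planted differentially expressed genes (DEGs), per-cell library-size
variation, mitochondrial-count fractions, and QC-violating debris nuclei.
Counts are drawn gene-wise from a negative binomial with a single shared
dispersion; full ground truth is returned alongside the matrices.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, SampleMetadata

__all__ = [
    "CellTypeSpec",
    "SubpopSpec",
    "PlantedDEG",
    "CohortConfig",
    "CohortTruth",
    "ConfigError",
    "default_cohort_config",
    "generate_cohort",
    "null_cohort",
    "write_cohort",
    "load_cohort",
]


class ConfigError(ValueError):
    """The cohort configuration is internally inconsistent or infeasible."""


def write_cohort(directory: str, matrices: "list[CountMatrix]",
                 samples: "list[SampleMetadata]", truth: "CohortTruth"
                 ) -> None:
    """Serialize a cohort: one 10x directory per sample + metadata + truth."""
    import os

    from .io_formats import samples_to_frame, write_10x_mtx, write_table

    os.makedirs(directory, exist_ok=True)
    for meta, mat in zip(samples, matrices):
        write_10x_mtx(mat, os.path.join(directory, "samples", meta.sample_id))
    write_table(samples_to_frame(samples),
                os.path.join(directory, "sample_metadata.csv"))
    write_table(truth.cells, os.path.join(directory, "truth_cells.csv"))
    write_table(truth.genes, os.path.join(directory, "truth_genes.csv"))
    write_table(truth.subpop_shifts,
                os.path.join(directory, "truth_subpop_shifts.csv"))


def load_cohort(directory: str):
    """Load a cohort written by :func:`write_cohort`.

    Returns (matrices, samples, truth-or-None); truth files are optional
    so real cohorts laid out the same way load too.
    """
    import os

    from .io_formats import frame_to_samples, read_10x_mtx, read_table

    meta_df = read_table(os.path.join(directory, "sample_metadata.csv"),
                         "sample_metadata")
    samples = frame_to_samples(meta_df)
    matrices = [
        read_10x_mtx(os.path.join(directory, "samples", s.sample_id))
        for s in samples
    ]
    truth = None
    cells_path = os.path.join(directory, "truth_cells.csv")
    if os.path.exists(cells_path):
        import pandas as _pd
        truth = CohortTruth(
            cells=_pd.read_csv(cells_path),
            genes=_pd.read_csv(os.path.join(directory, "truth_genes.csv")),
            subpop_shifts=_pd.read_csv(
                os.path.join(directory, "truth_subpop_shifts.csv")),
        )
    return matrices, samples, truth


# Canonical marker symbols used for the first marker gene of each default
# cell type, so reference-based annotation is exercisable on synthetic data.
CANONICAL_MARKERS = {
    "astrocyte": "AQP4",
    "endothelial": "CLDN5",
    "excitatory_neuron": "CAMK2A",
    "inhibitory_neuron": "GAD1",
    "microglia": "C3",
    "oligodendrocyte": "MBP",
}

_MITO_SYMBOLS = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4", "MT-ND5", "MT-CYB",
]


@dataclass
class CellTypeSpec:
    name: str
    baseline_proportion: float
    marker_genes: int = 10
    marker_log2fc: float = 3.0


@dataclass
class SubpopSpec:
    """A subpopulation within one cell type.

    ``deg_overexpression_log2fc`` shifts the type's planted DEG genes in
    this subpopulation's cells in both conditions: up-DEGs by ``+x`` and
    down-DEGs by ``-x`` — the constitutive signature-gene enrichment that
    makes a subpopulation disease-associated.
    """

    cell_type: str
    name: str
    baseline_share_within_type: float
    case_share_within_type: float
    marker_genes: int = 12
    marker_log2fc: float = 2.5
    deg_overexpression_log2fc: float = 0.0


@dataclass
class PlantedDEG:
    """A block of genes differentially expressed in case cells.

    The effect multiplies the gene mean by ``2**log2fc`` in case-condition
    cells of ``cell_type`` (restricted to ``subpop`` unless it is "all").
    """

    cell_type: str
    gene_count: int
    log2fc: float
    subpop: str = "all"


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults mirror a 21-subject postmortem-cortex design (12 case, 9
    control) at desk scale: a few hundred nuclei per sample over a
    2,000-gene panel.
    """

    n_samples_case: int = 12
    n_samples_control: int = 9
    cells_per_sample: int = 400
    n_genes: int = 2000
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    subpops: list[SubpopSpec] = field(default_factory=list)
    planted_degs: list[PlantedDEG] = field(default_factory=list)
    nb_dispersion: float = 1.0
    libsize_lognormal_sigma: float = 0.35
    mito_gene_count: int = 10
    mito_baseline_fraction: float = 0.05
    debris_fraction: float = 0.05
    debris_mito_violator_share: float = 0.3
    debris_libsize_scale: float = 0.1
    gene_mean_median: float = 0.25
    gene_mean_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ConfigError("at least one cell type is required")
        props = [t.baseline_proportion for t in self.cell_types]
        if abs(sum(props) - 1.0) > 1e-8:
            raise ConfigError(
                f"cell-type baseline proportions sum to {sum(props)}, not 1"
            )
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigError("cell type names are not unique")
        by_type: dict[str, list[SubpopSpec]] = {}
        for s in self.subpops:
            if s.cell_type not in names:
                raise ConfigError(f"subpop {s.name} references unknown type "
                                  f"{s.cell_type}")
            by_type.setdefault(s.cell_type, []).append(s)
        for t, subs in by_type.items():
            for attr in ("baseline_share_within_type", "case_share_within_type"):
                total = sum(getattr(s, attr) for s in subs)
                if abs(total - 1.0) > 1e-8:
                    raise ConfigError(
                        f"{attr} for type {t} sums to {total}, not 1"
                    )
        for d in self.planted_degs:
            if d.cell_type not in names:
                raise ConfigError(f"planted DEG set references unknown type "
                                  f"{d.cell_type}")
            if d.subpop != "all" and d.subpop not in {
                s.name for s in by_type.get(d.cell_type, [])
            }:
                raise ConfigError(
                    f"planted DEG set references unknown subpop {d.subpop} "
                    f"of type {d.cell_type}"
                )
        n_special = (
            self.mito_gene_count
            + sum(t.marker_genes for t in self.cell_types)
            + sum(s.marker_genes for s in self.subpops)
            + sum(d.gene_count for d in self.planted_degs)
        )
        if n_special > self.n_genes:
            raise ConfigError(
                f"config requires {n_special} special genes but n_genes is "
                f"only {self.n_genes}"
            )
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not 0 <= self.debris_fraction < 1:
            raise ConfigError("debris_fraction must be in [0, 1)")
        if self.libsize_lognormal_sigma < 0:
            raise ConfigError("libsize_lognormal_sigma must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth for one generated cohort.

    ``cells``: one row per cell (sample_id, barcode, cell, condition,
    cell_type, subpop, is_debris, is_mito_violator).
    ``genes``: one row per gene with its planted roles.
    ``subpop_shifts``: planted within-type share per condition and the
    planted percentage-point delta.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    subpop_shifts: pd.DataFrame


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """A cohort emulating the postmortem-cortex study design.

    Six cortical cell types at roughly the observed abundances; glial and
    vascular types carry subpopulations, the astrocyte compartment carrying
    one up-signature-enriched subpopulation that expands in case samples and
    one down-signature-enriched subpopulation that shrinks.
    """
    cell_types = [
        CellTypeSpec("excitatory_neuron", 0.35),
        CellTypeSpec("oligodendrocyte", 0.24),
        CellTypeSpec("astrocyte", 0.16),
        CellTypeSpec("inhibitory_neuron", 0.12),
        CellTypeSpec("microglia", 0.08),
        CellTypeSpec("endothelial", 0.05),
    ]
    subpops = [
        SubpopSpec("astrocyte", "a1", 0.35, 0.45, deg_overexpression_log2fc=2.0),
        SubpopSpec("astrocyte", "a2", 0.40, 0.37),
        SubpopSpec("astrocyte", "a3", 0.25, 0.18, deg_overexpression_log2fc=-2.0),
        SubpopSpec("oligodendrocyte", "o1", 0.60, 0.65),
        SubpopSpec("oligodendrocyte", "o2", 0.40, 0.35),
        SubpopSpec("microglia", "m1", 0.70, 0.60),
        SubpopSpec("microglia", "m2", 0.30, 0.40),
        SubpopSpec("endothelial", "e1", 0.60, 0.60),
        SubpopSpec("endothelial", "e2", 0.40, 0.40),
    ]
    planted = []
    for t in ("astrocyte", "oligodendrocyte", "microglia", "endothelial"):
        planted.append(PlantedDEG(t, 20, +0.8))
        planted.append(PlantedDEG(t, 20, -0.8))
    return CohortConfig(
        cell_types=cell_types, subpops=subpops, planted_degs=planted, seed=seed
    )


# ---------------------------------------------------------------------------
# Deterministic apportionment
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``shares``."""
    shares = np.asarray(shares, dtype=float)
    if total == 0 or shares.sum() == 0:
        return np.zeros(len(shares), dtype=int)
    quotas = total * shares / shares.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = quotas - counts
        # stable tie-break: larger fraction first, then lower index
        order = np.lexsort((np.arange(len(shares)), -frac))
        counts[order[:remainder]] += 1
    return counts


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

def _build_gene_table(config: CohortConfig, rng: np.random.Generator
                      ) -> pd.DataFrame:
    n = config.n_genes
    symbols = [f"G{i:04d}" for i in range(n)]
    gene_ids = [f"SYNENSG{i:08d}" for i in range(n)]
    is_mito = np.zeros(n, dtype=bool)
    marker_of_type = np.array([""] * n, dtype=object)
    marker_of_subpop = np.array([""] * n, dtype=object)
    deg_cell_type = np.array([""] * n, dtype=object)
    deg_subpop = np.array([""] * n, dtype=object)
    deg_log2fc = np.zeros(n)

    cursor = 0
    for i in range(config.mito_gene_count):
        symbols[cursor] = (_MITO_SYMBOLS[i] if i < len(_MITO_SYMBOLS)
                           else f"MT-G{i}")
        is_mito[cursor] = True
        cursor += 1
    for t in config.cell_types:
        for j in range(t.marker_genes):
            if j == 0 and t.name in CANONICAL_MARKERS:
                symbols[cursor] = CANONICAL_MARKERS[t.name]
            else:
                symbols[cursor] = f"{t.name.upper()[:3]}-M{j}"
            marker_of_type[cursor] = t.name
            cursor += 1
    for s in config.subpops:
        for j in range(s.marker_genes):
            symbols[cursor] = f"{s.cell_type.upper()[:3]}-{s.name.upper()}-M{j}"
            marker_of_subpop[cursor] = f"{s.cell_type}/{s.name}"
            marker_of_type[cursor] = s.cell_type
            cursor += 1
    for k, d in enumerate(config.planted_degs):
        for j in range(d.gene_count):
            symbols[cursor] = f"DEG{k}-{j:03d}"
            deg_cell_type[cursor] = d.cell_type
            deg_subpop[cursor] = d.subpop
            deg_log2fc[cursor] = d.log2fc
            cursor += 1

    # Baseline means: lognormal across genes, sparse-data regime.  Planted
    # features (markers, DEGs) are floored at expressed levels — real marker
    # and effect genes are not drawn from the silent tail.
    mu_ln = np.log(config.gene_mean_median)
    base_mean = rng.lognormal(mean=mu_ln, sigma=config.gene_mean_sigma, size=n)
    special = (marker_of_type != "") | (marker_of_subpop != "")
    base_mean[special] = np.maximum(base_mean[special], config.gene_mean_median)
    degm = deg_cell_type != ""
    base_mean[degm] = np.maximum(base_mean[degm], config.gene_mean_median)

    # Scale mitochondrial means to the configured baseline mito share.
    if config.mito_gene_count and config.mito_baseline_fraction > 0:
        frac = config.mito_baseline_fraction
        non_mito_total = base_mean[~is_mito].sum()
        target = frac / (1 - frac) * non_mito_total
        base_mean[is_mito] *= target / base_mean[is_mito].sum()

    return pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": symbols,
        "base_mean": base_mean,
        "is_mito": is_mito,
        "marker_of_type": marker_of_type,
        "marker_of_subpop": marker_of_subpop,
        "deg_cell_type": deg_cell_type,
        "deg_subpop": deg_subpop,
        "deg_log2fc": deg_log2fc,
    })


def _group_mean_vector(genes: pd.DataFrame, config: CohortConfig,
                       cell_type: str, subpop: str, condition: str
                       ) -> np.ndarray:
    """Expected counts/cell (before library-size scaling) for one cell group."""
    mu = genes["base_mean"].to_numpy().copy()
    mu[genes["marker_of_type"].to_numpy() == cell_type] *= 2.0 ** next(
        t.marker_log2fc for t in config.cell_types if t.name == cell_type
    )
    if subpop:
        key = f"{cell_type}/{subpop}"
        spec = next(s for s in config.subpops
                    if s.cell_type == cell_type and s.name == subpop)
        mu[genes["marker_of_subpop"].to_numpy() == key] *= 2.0 ** spec.marker_log2fc
        if spec.deg_overexpression_log2fc != 0.0:
            in_type = genes["deg_cell_type"].to_numpy() == cell_type
            lfc = genes["deg_log2fc"].to_numpy()
            mu[in_type & (lfc > 0)] *= 2.0 ** spec.deg_overexpression_log2fc
            mu[in_type & (lfc < 0)] *= 2.0 ** -spec.deg_overexpression_log2fc
    if condition == "AD":
        in_type = genes["deg_cell_type"].to_numpy() == cell_type
        scope = genes["deg_subpop"].to_numpy()
        applies = in_type & ((scope == "all") | (scope == subpop))
        mu[applies] *= 2.0 ** genes["deg_log2fc"].to_numpy()[applies]
    return mu


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_metadata(config: CohortConfig, rng: np.random.Generator
                     ) -> list[SampleMetadata]:
    out = []
    for i in range(config.n_samples_case):
        out.append(SampleMetadata(
            sample_id=f"AD{i + 1:02d}",
            condition="AD",
            age_years=round(float(rng.normal(75.0, 7.0)), 1),
            sex="M" if i % 3 != 2 else "F",
            postmortem_delay_hours=round(float(rng.uniform(6.0, 72.0)), 1),
            braak_stage=int(rng.integers(4, 7)),
        ))
    for i in range(config.n_samples_control):
        out.append(SampleMetadata(
            sample_id=f"NC{i + 1:02d}",
            condition="NC",
            age_years=round(float(rng.normal(82.0, 6.0)), 1),
            sex="M" if i % 3 != 2 else "F",
            postmortem_delay_hours=round(float(rng.uniform(6.0, 72.0)), 1),
            braak_stage=int(rng.integers(0, 3)),
        ))
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with mean ``mu`` and size ``1/dispersion``."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[CountMatrix], list[SampleMetadata],
                               CohortTruth]:
    """Generate per-sample count matrices, metadata, and ground truth.

    Cells are apportioned to debris / cell types / subpopulations by
    deterministic largest-remainder allocation, so planted proportions hold
    exactly; stochasticity enters only through expression sampling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    samples = _sample_metadata(config, rng)

    subpops_by_type: dict[str, list[SubpopSpec]] = {}
    for s in config.subpops:
        subpops_by_type.setdefault(s.cell_type, []).append(s)

    # Pre-compute group mean vectors (cell_type, subpop, condition).
    mean_cache: dict[tuple[str, str, str], np.ndarray] = {}

    def group_mu(cell_type: str, subpop: str, condition: str) -> np.ndarray:
        key = (cell_type, subpop, condition)
        if key not in mean_cache:
            mean_cache[key] = _group_mean_vector(
                genes, config, cell_type, subpop, condition)
        return mean_cache[key]

    is_mito = genes["is_mito"].to_numpy()
    matrices: list[CountMatrix] = []
    cell_rows: list[dict] = []

    for meta in samples:
        n = config.cells_per_sample
        n_debris = round(config.debris_fraction * n)
        n_mito_viol = round(config.debris_mito_violator_share * n_debris)
        n_real = n - n_debris

        type_counts = _largest_remainder(
            n_real, np.array([t.baseline_proportion for t in config.cell_types])
        )
        assignments: list[tuple[str, str, bool, bool]] = []
        for t, n_t in zip(config.cell_types, type_counts):
            subs = subpops_by_type.get(t.name)
            if subs:
                attr = ("case_share_within_type" if meta.condition == "AD"
                        else "baseline_share_within_type")
                sub_counts = _largest_remainder(
                    n_t, np.array([getattr(s, attr) for s in subs]))
                for s, n_s in zip(subs, sub_counts):
                    assignments += [(t.name, s.name, False, False)] * n_s
            else:
                assignments += [(t.name, "", False, False)] * n_t
        assignments += [("debris", "", True, True)] * n_mito_viol
        assignments += [("debris", "", True, False)] * (n_debris - n_mito_viol)

        # Per-cell library-size factors (lognormal, median 1).
        lib = rng.lognormal(0.0, config.libsize_lognormal_sigma, size=n)

        mu_matrix = np.empty((config.n_genes, n))
        for j, (ctype, sub, debris, viol) in enumerate(assignments):
            if debris:
                mu = genes["base_mean"].to_numpy().copy()
                if viol:
                    # boost mito means to an expected ~50% mito share, well
                    # past the 20% removal boundary despite NB noise
                    non_mito_total = mu[~is_mito].sum()
                    mito_total = mu[is_mito].sum()
                    if mito_total > 0:
                        mu[is_mito] *= non_mito_total / mito_total
                else:
                    mu = mu * config.debris_libsize_scale
            else:
                mu = group_mu(ctype, sub, meta.condition)
            mu_matrix[:, j] = mu * lib[j]

        counts = _nb_draw(rng, mu_matrix, config.nb_dispersion)
        barcodes = [f"C{j:05d}" for j in range(n)]
        matrices.append(CountMatrix(
            sp.csc_matrix(counts), list(genes["gene_id"]),
            list(genes["symbol"]), barcodes,
        ))
        for j, (ctype, sub, debris, viol) in enumerate(assignments):
            cell_rows.append({
                "sample_id": meta.sample_id,
                "barcode": barcodes[j],
                "cell": f"{meta.sample_id}:{barcodes[j]}",
                "condition": meta.condition,
                "cell_type": ctype,
                "subpop": sub,
                "is_debris": debris,
                "is_mito_violator": viol,
            })

    cells = pd.DataFrame(cell_rows)
    shift_rows = []
    for s in config.subpops:
        shift_rows.append({
            "cell_type": s.cell_type,
            "subpop": s.name,
            "control_share": s.baseline_share_within_type,
            "case_share": s.case_share_within_type,
            "delta_pp": 100.0 * (s.case_share_within_type
                                 - s.baseline_share_within_type),
        })
    truth = CohortTruth(
        cells=cells,
        genes=genes.drop(columns=["base_mean"]).assign(
            base_mean=genes["base_mean"]),
        subpop_shifts=pd.DataFrame(
            shift_rows, columns=["cell_type", "subpop", "control_share",
                                 "case_share", "delta_pp"]),
    )
    return matrices, samples, truth


def null_cohort(config: CohortConfig
                ) -> tuple[list[CountMatrix], list[SampleMetadata], CohortTruth]:
    """The same cohort design with every condition-dependent effect removed.

    Planted DEG sets are dropped and case subpopulation shares are set equal
    to the baseline shares, so case and control cells are exchangeable —
    the substrate for type-I error checks.
    """
    null_subpops = [
        dataclasses.replace(
            s, case_share_within_type=s.baseline_share_within_type,
            deg_overexpression_log2fc=0.0)
        for s in config.subpops
    ]
    null_config = dataclasses.replace(
        config, planted_degs=[], subpops=null_subpops)
    return generate_cohort(null_config)
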