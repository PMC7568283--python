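"""Disease-associated subpopulation analysis within annotated cell types.

Each cell type (glial and vascular types by default; neurons are excluded)
is re-clustered at a type-specific low resolution.  For every
subpopulation, an enrichment score summarizes the case/control DEG sets of
the parent type: each DEG's normalized expression is z-scored across all
cells of the type, and the score is the mean z over the subpopulation's
cells and the direction's genes.  A subpopulation whose up-score (resp.
down-score) exceeds 0.5 is classified disease-up-regulated (resp.
down-regulated).  Proportion shifts between conditions are quantified with
samples as the unit, reported both in percentage points and as relative
change.

Because z-scores are centered over all cells of the type, the
cell-count-weighted mean of any score over a type's subpopulations is 0 —
an identity the tests rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .celltype_de import (DEThresholds, adjust_pvalues,
                          log2_fold_change_matrix, rank_sum_matrix)
from .cluster_annotate import (ClusterParams, cluster_cells, embed_pca,
                               select_hvg)
from .io_formats import CountMatrix

__all__ = [
    "SubpopParams",
    "subcluster",
    "enrichment_scores",
    "classify_subpops",
    "subpop_signatures",
    "proportion_shift",
    "analyze_subpopulations",
]

DEFAULT_RESOLUTIONS = {
    "astrocyte": 0.2,
    "endothelial": 0.2,
    "microglia": 0.3,
    "oligodendrocyte": 0.2,
}


@dataclass
class SubpopParams:
    resolution_by_type: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESOLUTIONS))
    enrichment_threshold: float = 0.5
    n_hvg: int = 1000
    n_pcs_computed: int = 50
    n_pcs_used: int = 20
    knn_k: int = 20
    min_cells: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.resolution_by_type.values()):
            raise ValueError("resolutions must be > 0")
        if self.enrichment_threshold <= 0:
            raise ValueError("enrichment_threshold must be > 0")


def subcluster(counts_of_type: CountMatrix, resolution: float,
               params: SubpopParams | None = None) -> np.ndarray:
    """Re-cluster the cells of one type; labels "s1".."sK" by size.

    Repeats HVG selection, scaling, PCA and SNN modularity clustering on
    the type's cells alone, at the type's resolution.  Below the cell
    floor a single subpopulation is returned with a warning.
    """
    if params is None:
        params = SubpopParams()
    n = counts_of_type.n_cells
    if n < params.min_cells:
        warnings.warn(
            f"only {n} cells (< {params.min_cells}); single subpopulation")
        return np.array(["s1"] * n)
    from .cluster_annotate import log_normalize

    cp = ClusterParams(
        n_hvg=min(params.n_hvg, counts_of_type.n_genes),
        n_pcs_computed=min(params.n_pcs_computed, n - 1),
        n_pcs_used=min(params.n_pcs_used, n - 1),
        knn_k=params.knn_k, resolution=resolution, seed=params.seed)
    normalized = log_normalize(counts_of_type)
    hvg = select_hvg(counts_of_type, n_hvg=cp.n_hvg)
    emb = embed_pca(normalized[hvg], cp)
    labels = cluster_cells(emb[:, : cp.n_pcs_used], cp.knn_k, resolution,
                           cp.seed)
    return np.array([f"s{c + 1}" for c in labels])


def enrichment_scores(normalized_type, gene_symbols, labels,
                      up_genes, down_genes) -> pd.DataFrame:
    """Per-subpopulation mean z-score of the up- and down-DEG sets.

    z is computed per gene across *all* cells of the type; zero-variance
    genes contribute 0.  An empty DEG set yields a null score for that
    direction.
    """
    labels = np.asarray(labels)
    gene_symbols = list(gene_symbols)
    sym_to_idx: dict[str, int] = {}
    for i, s in enumerate(gene_symbols):
        sym_to_idx.setdefault(s, i)
    Xs = sp.csr_matrix(normalized_type)

    def mean_z_by_subpop(genes: set[str] | list[str]) -> dict | None:
        idx = [sym_to_idx[g] for g in sorted(set(genes)) if g in sym_to_idx]
        if not idx:
            return None
        dense = Xs[idx].toarray()
        mu = dense.mean(axis=1, keepdims=True)
        sd = dense.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (dense - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return {s: float(z[:, labels == s].mean())
                for s in np.unique(labels)}

    up = mean_z_by_subpop(up_genes) if up_genes else None
    down = mean_z_by_subpop(down_genes) if down_genes else None
    if up is None and down is None:
        raise ValueError("both DEG sets are empty or absent from the matrix")
    subpops = sorted(np.unique(labels))
    return pd.DataFrame({
        "subpop": subpops,
        "up_score": [up[s] if up else np.nan for s in subpops],
        "down_score": [down[s] if down else np.nan for s in subpops],
    })


def classify_subpops(scores: pd.DataFrame, threshold: float = 0.5
                     ) -> pd.DataFrame:
    """Designate disease-associated subpopulations from enrichment scores.

    up_regulated if up_score > threshold, down_regulated if down_score >
    threshold; when both exceed it the larger score wins and an exact tie
    is "ambiguous"; otherwise "unaffected".
    """
    out = scores.copy()
    cls = []
    for _, row in scores.iterrows():
        up = row["up_score"]
        down = row["down_score"]
        up_hit = (not pd.isna(up)) and up > threshold
        down_hit = (not pd.isna(down)) and down > threshold
        if up_hit and down_hit:
            if up > down:
                cls.append("up_regulated")
            elif down > up:
                cls.append("down_regulated")
            else:
                cls.append("ambiguous")
        elif up_hit:
            cls.append("up_regulated")
        elif down_hit:
            cls.append("down_regulated")
        else:
            cls.append("unaffected")
    out["classification"] = cls
    return out


def subpop_signatures(normalized_type, gene_symbols, labels,
                      classifications: pd.DataFrame,
                      thresholds: DEThresholds | None = None,
                      method: str = "bonferroni") -> pd.DataFrame:
    """DE signature of up- vs down-regulated subpopulations (pooled cells)."""
    if thresholds is None:
        thresholds = DEThresholds()
    labels = np.asarray(labels)
    up_subs = set(classifications.loc[
        classifications["classification"] == "up_regulated", "subpop"])
    down_subs = set(classifications.loc[
        classifications["classification"] == "down_regulated", "subpop"])
    if not up_subs or not down_subs:
        raise ValueError(
            "signature comparison undefined: need at least one up- and one "
            "down-regulated subpopulation")
    up_mask = np.isin(labels, sorted(up_subs))
    down_mask = np.isin(labels, sorted(down_subs))
    keep = up_mask | down_mask
    X = sp.csr_matrix(normalized_type)[:, keep].toarray()
    case_mask = up_mask[keep]
    expressed = X.sum(axis=1) > 0
    X = X[expressed]
    syms = np.asarray(list(gene_symbols))[expressed]
    lfc = log2_fold_change_matrix(X, case_mask)
    tested = np.abs(lfc) >= thresholds.prefilter_log2fc
    p = rank_sum_matrix(X[tested], case_mask)
    adj = adjust_pvalues(p, method=method)
    lfc_t = lfc[tested]
    sig = (adj < thresholds.max_adjusted_p) & (
        np.abs(lfc_t) >= thresholds.min_abs_log2fc)
    return pd.DataFrame({
        "gene": syms[tested],
        "log2fc": lfc_t,
        "raw_p": p,
        "adjusted_p": adj,
        "direction": np.where(lfc_t > 0, "up",
                              np.where(lfc_t < 0, "down", "none")),
        "significant": sig,
    })


def proportion_shift(cell_table: pd.DataFrame,
                     case_label: str = "AD", control_label: str = "NC",
                     all_samples: list[str] | None = None) -> pd.DataFrame:
    """Within-type subpopulation proportion shift between conditions.

    ``cell_table`` holds the cells of one type with columns ``sample_id``,
    ``condition``, ``subpop``.  Per-sample within-type proportions are the
    analysis unit; condition means, SEMs, the percentage-point delta and
    the relative delta are reported per subpopulation.  Samples with no
    cells of the type are excluded (with a warning when ``all_samples``
    names them).
    """
    if cell_table.empty:
        raise ValueError("cell_table is empty")
    present = set(cell_table["sample_id"])
    if all_samples:
        missing = sorted(set(all_samples) - present)
        if missing:
            warnings.warn(
                f"samples with no cells of this type excluded: {missing}")
    counts = (cell_table.groupby(["sample_id", "condition", "subpop"])
              .size().rename("n").reset_index())
    totals = counts.groupby("sample_id")["n"].transform("sum")
    counts["prop"] = counts["n"] / totals

    subpops = sorted(cell_table["subpop"].unique())
    sample_cond = cell_table.drop_duplicates("sample_id")[
        ["sample_id", "condition"]]
    rows = []
    for s in subpops:
        sub = counts[counts["subpop"] == s].set_index("sample_id")
        per_sample = {}
        for _, rec in sample_cond.iterrows():
            per_sample[rec["sample_id"]] = (
                float(sub.loc[rec["sample_id"], "prop"])
                if rec["sample_id"] in sub.index else 0.0)
        case_props = np.array([
            per_sample[r["sample_id"]] for _, r in sample_cond.iterrows()
            if r["condition"] == case_label])
        ctrl_props = np.array([
            per_sample[r["sample_id"]] for _, r in sample_cond.iterrows()
            if r["condition"] == control_label])
        mean_case = float(case_props.mean()) if case_props.size else np.nan
        mean_ctrl = float(ctrl_props.mean()) if ctrl_props.size else np.nan
        sem = lambda v: (float(np.std(v, ddof=1) / np.sqrt(v.size))
                         if v.size > 1 else np.nan)
        n_case = int(cell_table[(cell_table["subpop"] == s) &
                                (cell_table["condition"] == case_label)]
                     .shape[0])
        n_ctrl = int(cell_table[(cell_table["subpop"] == s) &
                                (cell_table["condition"] == control_label)]
                     .shape[0])
        rows.append({
            "subpop": s,
            "n_cells_case": n_case,
            "n_cells_control": n_ctrl,
            "mean_prop_case": mean_case,
            "sem_case": sem(case_props),
            "mean_prop_control": mean_ctrl,
            "sem_control": sem(ctrl_props),
            "delta_pp": 100.0 * (mean_case - mean_ctrl),
            "delta_relative": ((mean_case - mean_ctrl) / mean_ctrl
                               if mean_ctrl else np.nan),
        })
    return pd.DataFrame(rows)


def analyze_subpopulations(counts: CountMatrix, normalized,
                           cell_table: pd.DataFrame,
                           de_table: pd.DataFrame,
                           params: SubpopParams | None = None,
                           de_thresholds: DEThresholds | None = None,
                           ) -> dict:
    """Full subpopulation stage over every configured cell type.

    ``cell_table`` has one row per matrix column with ``sample_id``,
    ``condition`` and ``cell_type``; ``de_table`` is the per-type DERecord
    table whose significant genes define the enrichment inputs.  Returns a
    dict with the combined ``report`` (SubpopReport rows incl. scores and
    classifications), per-cell ``subpop_labels``, and per-type
    ``signatures`` where both an up- and a down-regulated subpopulation
    exist.
    """
    if params is None:
        params = SubpopParams()
    cell_types = cell_table["cell_type"].to_numpy()
    subpop_labels = np.array([""] * len(cell_table), dtype=object)
    reports = []
    signatures: dict[str, pd.DataFrame] = {}

    for ctype, resolution in sorted(params.resolution_by_type.items()):
        mask = cell_types == ctype
        if mask.sum() == 0:
            continue
        sub_counts = CountMatrix(
            counts.values[:, mask], counts.gene_ids, counts.gene_symbols,
            [counts.cell_barcodes[i] for i in np.flatnonzero(mask)])
        labels = subcluster(sub_counts, resolution, params)
        subpop_labels[mask] = labels

        degs = de_table[(de_table["cell_type"] == ctype)
                        & de_table["significant"]]
        up_genes = sorted(degs.loc[degs["direction"] == "up", "gene"])
        down_genes = sorted(degs.loc[degs["direction"] == "down", "gene"])
        norm_type = normalized[:, mask]
        if up_genes or down_genes:
            scores = enrichment_scores(
                norm_type, counts.gene_symbols, labels, up_genes, down_genes)
            classified = classify_subpops(scores, params.enrichment_threshold)
        else:
            warnings.warn(f"no significant DEGs for {ctype}; scores null")
            classified = pd.DataFrame({
                "subpop": sorted(np.unique(labels)),
                "up_score": np.nan, "down_score": np.nan,
                "classification": "unaffected"})

        type_cells = cell_table.loc[mask, ["sample_id", "condition"]].copy()
        type_cells["subpop"] = labels
        shifts = proportion_shift(type_cells)
        merged = shifts.merge(classified, on="subpop")
        merged.insert(0, "cell_type", ctype)
        reports.append(merged)

        has_up = (classified["classification"] == "up_regulated").any()
        has_down = (classified["classification"] == "down_regulated").any()
        if has_up and has_down:
            signatures[ctype] = subpop_signatures(
                norm_type, counts.gene_symbols, labels, classified,
                de_thresholds)

    report = (pd.concat(reports, ignore_index=True)
              if reports else pd.DataFrame())
    return {"report": report, "subpop_labels": subpop_labels,
            "signatures": signatures}
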