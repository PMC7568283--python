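"""Per-cell-type case/control differential expression.

The test of record is the two-sample Wilcoxon rank-sum (Mann-Whitney U)
test applied to log-normalized expression with cells as the units, exactly
as single-cell toolchains run it: an exact null enumeration for small
tie-free samples and a tie- and continuity-corrected normal approximation
otherwise.  Fold changes are computed on de-logged group means with a small
pseudocount, in base 2.  Multiple-testing adjustment is Bonferroni by
default (Benjamini-Hochberg selectable), applied within the tested gene set
of each cell type.

A gene is called a DEG when its adjusted P is below ``max_adjusted_p`` and
|log2FC| >= ``min_abs_log2fc`` (defaults 0.1 and 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

__all__ = [
    "DEThresholds",
    "wilcoxon_rank_sum",
    "rank_sum_matrix",
    "log2_fold_change",
    "log2_fold_change_matrix",
    "adjust_pvalues",
    "run_celltype_de",
    "deg_overlap",
    "LOG2FC_EPS",
]

LOG2FC_EPS = 1e-9


@dataclass
class DEThresholds:
    max_adjusted_p: float = 0.1
    min_abs_log2fc: float = 0.1
    prefilter_log2fc: float = 0.0

    def __post_init__(self) -> None:
        if self.max_adjusted_p <= 0 or self.min_abs_log2fc <= 0:
            raise ValueError("DE thresholds must be positive")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of ways to choose n1 of ranks 1..n1+n2 with each rank-sum.

    counts[s] = #subsets of size n1 of {1..N} summing to s.  Dynamic
    programme over ranks; the exact null distribution of the rank sum.
    """
    N = n1 + n2
    max_sum = n1 * N  # loose upper bound on achievable rank sums
    table = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for rank in range(1, N + 1):
        for k in range(min(rank, n1), 0, -1):
            table[k, rank:] += table[k - 1, :-rank or None]
    return table[n1]


def _exact_two_sided_p(w: float, n1: int, n2: int) -> float:
    counts = _rank_sum_counts(n1, n2)
    total = counts.sum()
    w_int = int(round(w))
    lo = counts[: w_int + 1].sum() / total
    hi = counts[w_int:].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> dict:
    """Two-sample Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y
        Numeric samples (each nonempty).
    mode
        "exact": enumerate the tie-free rank-sum null (requires no ties);
        "normal": tie- and continuity-corrected normal approximation;
        "auto": exact when n_x + n_y <= 16 and the pooled data are tie-free.

    Returns a dict with the Mann-Whitney ``statistic`` (U of ``x``),
    ``two_sided_p``, the ``method`` used, and a ``degenerate`` flag (set
    when every value is identical across both groups, in which case p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if np.ptp(pooled) == 0:
        return {"statistic": u, "two_sided_p": 1.0, "method": "degenerate",
                "degenerate": True}

    use_exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= 16 and not has_ties)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        return {"statistic": u, "two_sided_p": _exact_two_sided_p(r1, n1, n2),
                "method": "exact", "degenerate": False}

    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return {"statistic": u, "two_sided_p": 1.0, "method": "degenerate",
                "degenerate": True}
    mean = n1 * n2 / 2.0
    z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
    return {"statistic": u, "two_sided_p": p, "method": "normal",
            "degenerate": False}


def rank_sum_matrix(X: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Row-wise Wilcoxon rank-sum p-values (normal approximation).

    ``X`` is genes x cells (dense); ``group1`` a boolean cell mask.  Each
    row is tested group1 vs rest with tie and continuity corrections —
    the vectorized path used for genome-wide scans.
    """
    X = np.asarray(X, dtype=float)
    group1 = np.asarray(group1, dtype=bool)
    n1 = int(group1.sum())
    n2 = X.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    N = n1 + n2
    ranks = scipy.stats.rankdata(X, axis=1)
    r1 = ranks[:, group1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0

    # Tie correction per gene: sum over tied groups of (t^3 - t).
    Xs = np.sort(X, axis=1)
    same = Xs[:, 1:] == Xs[:, :-1]
    tie_term = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        # run lengths of equal values in the sorted row
        boundaries = np.flatnonzero(~same[i])
        runs = np.diff(np.concatenate([[-1], boundaries, [N - 1]]))
        tie_term[i] = float(((runs ** 3) - runs).sum())

    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    mean = n1 * n2 / 2.0
    p = np.ones(X.shape[0])
    ok = var > 0
    z = np.zeros(X.shape[0])
    z[ok] = (u[ok] - mean - 0.5 * np.sign(u[ok] - mean)) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * scipy.stats.norm.sf(np.abs(z[ok])))
    return p


# ---------------------------------------------------------------------------
# Fold change and adjustment
# ---------------------------------------------------------------------------

def log2_fold_change(norm_case, norm_control, eps: float = LOG2FC_EPS) -> float:
    """log2 ratio of de-logged group means (case over control).

    Inputs are log1p-normalized expression vectors; means are taken on the
    expm1 scale with pseudocount ``eps`` in numerator and denominator.
    """
    norm_case = np.asarray(norm_case, dtype=float)
    norm_control = np.asarray(norm_control, dtype=float)
    if norm_case.size == 0 or norm_control.size == 0:
        raise ValueError("both groups must be nonempty")
    m1 = np.expm1(norm_case).mean()
    m2 = np.expm1(norm_control).mean()
    return float(np.log2((m1 + eps) / (m2 + eps)))


def log2_fold_change_matrix(X, case_mask, eps: float = LOG2FC_EPS
                            ) -> np.ndarray:
    """Row-wise log2 fold changes for a genes x cells normalized matrix."""
    case_mask = np.asarray(case_mask, dtype=bool)
    ctrl_mask = ~case_mask
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    if sp.issparse(X):
        E = X.copy()
        E.data = np.expm1(E.data)
        m1 = np.asarray(E[:, case_mask].mean(axis=1)).ravel()
        m2 = np.asarray(E[:, ctrl_mask].mean(axis=1)).ravel()
    else:
        E = np.expm1(np.asarray(X, dtype=float))
        m1 = E[:, case_mask].mean(axis=1)
        m2 = E[:, ctrl_mask].mean(axis=1)
    return np.log2((m1 + eps) / (m2 + eps))


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, p * m).  ``bh``: Benjamini-Hochberg step-up
    (monotone non-decreasing in p-rank).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# Per-cell-type DE scan
# ---------------------------------------------------------------------------

def run_celltype_de(normalized, gene_symbols, cell_table: pd.DataFrame,
                    thresholds: DEThresholds | None = None,
                    method: str = "bonferroni",
                    case_label: str = "AD", control_label: str = "NC",
                    ) -> pd.DataFrame:
    """Case-vs-control Wilcoxon DE within each annotated cell type.

    ``normalized`` is a genes x cells matrix (sparse or dense) of
    log-normalized expression; ``cell_table`` has one row per column with
    at least ``condition`` and ``cell_type``.  Genes with zero expression
    in all cells of a type are untestable and absent from that type's
    records; adjustment is within the tested gene set of the type.
    """
    if thresholds is None:
        thresholds = DEThresholds()
    if len(cell_table) != normalized.shape[1]:
        raise ValueError("cell_table must have one row per matrix column")
    gene_symbols = np.asarray(gene_symbols)
    condition = cell_table["condition"].to_numpy()
    cell_type = cell_table["cell_type"].to_numpy()

    records = []
    for ctype in sorted(pd.unique(cell_type)):
        in_type = cell_type == ctype
        case = in_type & (condition == case_label)
        ctrl = in_type & (condition == control_label)
        if case.sum() == 0 or ctrl.sum() == 0:
            warnings.warn(
                f"cell type {ctype!r} present in only one condition; skipped")
            continue
        sub = normalized[:, in_type]
        sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
        expressed = sub.sum(axis=1) > 0
        if not expressed.any():
            continue
        sub = sub[expressed]
        case_mask = condition[in_type] == case_label
        lfc = log2_fold_change_matrix(sub, case_mask)
        tested = np.abs(lfc) >= thresholds.prefilter_log2fc
        if not tested.any():
            continue
        p = rank_sum_matrix(sub[tested], case_mask)
        adj = adjust_pvalues(p, method=method)
        lfc_t = lfc[tested]
        sig = (adj < thresholds.max_adjusted_p) & (
            np.abs(lfc_t) >= thresholds.min_abs_log2fc)
        direction = np.where(lfc_t > 0, "up",
                             np.where(lfc_t < 0, "down", "none"))
        syms = gene_symbols[expressed][tested]
        for i in range(len(syms)):
            records.append({
                "gene": syms[i], "cell_type": ctype,
                "log2fc": float(lfc_t[i]), "raw_p": float(p[i]),
                "adjusted_p": float(adj[i]), "direction": direction[i],
                "significant": bool(sig[i]),
            })
    return pd.DataFrame(
        records, columns=["gene", "cell_type", "log2fc", "raw_p",
                          "adjusted_p", "direction", "significant"])


def deg_overlap(tables: pd.DataFrame | list[pd.DataFrame]) -> dict:
    """Cross-type overlap of significant DEG sets.

    Accepts one concatenated DERecord table or a list of per-type tables
    (>= 2 cell types required).  Reports per-type up/down counts, the genes
    significant in every type, and the genes exclusive to a single type.
    """
    if isinstance(tables, list):
        table = pd.concat(tables, ignore_index=True)
    else:
        table = tables
    types = sorted(table["cell_type"].unique())
    if len(types) < 2:
        raise ValueError("deg_overlap requires tables for >= 2 cell types")
    sig_sets = {
        t: set(table.loc[(table["cell_type"] == t) & table["significant"],
                         "gene"])
        for t in types
    }
    shared = set.intersection(*sig_sets.values())
    per_type_counts = {}
    for t in types:
        sub = table[(table["cell_type"] == t) & table["significant"]]
        per_type_counts[t] = {
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
            "total": len(sub),
        }
    exclusives = {}
    for t in types:
        others = set.union(*(sig_sets[o] for o in types if o != t)) \
            if len(types) > 1 else set()
        exclusives[t] = sorted(sig_sets[t] - others)
    return {
        "per_type_counts": per_type_counts,
        "shared_all_types": sorted(shared),
        "n_shared_all_types": len(shared),
        "exclusive_per_type": exclusives,
    }
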