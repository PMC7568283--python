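"""Cross-study validation of DE results.

Given the pipeline's per-cell-type DE records and an external DE table
(gene, signed effect, adjusted P) from an independent cohort, count the
replicable DEGs (external adjusted P below alpha among matched genes) and
compute the direction-concordance percentage — the share of replicable
genes whose effect signs agree between the two studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "match_genes",
    "replicable_degs",
    "direction_concordance",
    "run_concordance",
]


def _normalize_symbol(s: str) -> str:
    return str(s).strip().upper()


def match_genes(internal: pd.DataFrame, external: pd.DataFrame
                ) -> pd.DataFrame:
    """Inner join of internal DE records with an external DE table.

    Symbols are matched case-insensitively after whitespace stripping.
    Duplicate external rows for one gene are collapsed to the median effect
    and median adjusted P (flagged in the ``external_collapsed`` column).
    """
    if internal.empty or external.empty:
        raise ValueError("both tables must be nonempty")
    internal = internal.copy()
    internal["_gene_key"] = internal["gene"].map(_normalize_symbol)
    ext = external.copy()
    ext["_gene_key"] = ext["gene"].map(_normalize_symbol)

    dup_keys = set(ext.loc[ext["_gene_key"].duplicated(), "_gene_key"])
    if dup_keys:
        warnings.warn(
            f"{len(dup_keys)} duplicated external genes collapsed to median")
    collapsed = (ext.groupby("_gene_key", as_index=False)
                 .agg(external_effect=("effect", "median"),
                      external_adjusted_p=("adjusted_p", "median")))
    collapsed["external_collapsed"] = collapsed["_gene_key"].isin(dup_keys)

    joined = internal.merge(collapsed, on="_gene_key", how="inner")
    if joined.empty:
        raise ValueError("no common genes between internal and external "
                         "tables")
    return joined.drop(columns=["_gene_key"])


def replicable_degs(joined: pd.DataFrame, alpha: float = 0.05
                    ) -> tuple[int, pd.DataFrame]:
    """Matched genes externally significant at adjusted P < alpha (strict)."""
    if joined.empty:
        raise ValueError("joined table is empty")
    subset = joined[joined["external_adjusted_p"] < alpha]
    return len(subset), subset


def direction_concordance(replicable: pd.DataFrame) -> dict:
    """Percentage of replicable genes with agreeing effect signs.

    Rows with a zero effect on either side are excluded (their count is
    reported).  When internal records carry a ``cell_type`` column a
    per-type breakdown and its mean are reported alongside the pooled
    percentage.
    """
    if replicable.empty:
        warnings.warn("no replicable genes; concordance undefined")
        return {"concordance_pct": None, "n_used": 0, "n_zero_excluded": 0}
    internal_sign = np.sign(replicable["log2fc"].to_numpy(dtype=float))
    external_sign = np.sign(replicable["external_effect"].to_numpy(dtype=float))
    nonzero = (internal_sign != 0) & (external_sign != 0)
    n_zero = int((~nonzero).sum())
    used = replicable[nonzero]
    if used.empty:
        warnings.warn("all replicable genes have a zero effect; "
                      "concordance undefined")
        return {"concordance_pct": None, "n_used": 0,
                "n_zero_excluded": n_zero}
    agree = internal_sign[nonzero] == external_sign[nonzero]
    out = {
        "concordance_pct": float(100.0 * agree.mean()),
        "n_used": int(nonzero.sum()),
        "n_zero_excluded": n_zero,
    }
    if "cell_type" in used.columns:
        per_type = {}
        for t, sub in used.assign(_agree=agree).groupby("cell_type"):
            per_type[t] = {
                "concordance_pct": float(100.0 * sub["_agree"].mean()),
                "n_used": len(sub),
            }
        out["per_cell_type"] = per_type
        out["mean_of_per_type_pct"] = float(np.mean(
            [v["concordance_pct"] for v in per_type.values()]))
    return out


def run_concordance(internal: pd.DataFrame, external: pd.DataFrame,
                    alpha: float = 0.05) -> dict:
    """Match, count replicable DEGs, and compute direction concordance."""
    joined = match_genes(internal, external)
    n_rep, subset = replicable_degs(joined, alpha)
    result = direction_concordance(subset)
    result["n_matched"] = len(joined)
    result["n_replicable"] = n_rep
    result["alpha"] = alpha
    return result
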