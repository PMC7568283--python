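"""Nucleus-level quality control.

Debris and dead nuclei are removed with the standard three-way filter:
a nucleus is discarded when it has <=``min_genes`` detected genes,
>=``max_umi`` total UMIs, or a mitochondrial UMI fraction >=
``max_mito_fraction`` (boundary values are removal conditions; the kept set
is strict).  Mitochondrial genes are identified by the "MT-" symbol prefix
unless an explicit predicate is given; the mitochondrial fraction is a
fraction of UMIs, the standard convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import CountMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "apply_qc_filters",
    "sample_qc_summary",
    "pmd_independence",
    "default_mito_predicate",
]


@dataclass
class QCThresholds:
    """Removal boundaries (each boundary value itself is removed)."""

    min_genes: int = 200
    max_umi: int = 20_000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.max_umi <= 0:
            raise ValueError("max_umi must be positive")


def default_mito_predicate(symbol: str) -> bool:
    return symbol.startswith("MT-")


def compute_cell_qc(matrix: CountMatrix,
                    mito_gene_predicate: Callable[[str], bool] | None = None,
                    ) -> pd.DataFrame:
    """Per-cell QC metrics, one row per cell in matrix column order.

    Returns a DataFrame with columns ``barcode``, ``n_genes_detected``,
    ``n_umi``, ``mito_fraction``.
    """
    if mito_gene_predicate is None:
        mito_gene_predicate = default_mito_predicate
    X = matrix.values.tocsc()
    X.eliminate_zeros()
    n_umi = np.asarray(X.sum(axis=0)).ravel()
    n_genes = X.getnnz(axis=0)
    mito_mask = np.fromiter(
        (mito_gene_predicate(s) for s in matrix.gene_symbols),
        dtype=bool, count=matrix.n_genes,
    )
    mito_counts = np.asarray(X[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1),
                                 0.0)
    return pd.DataFrame({
        "barcode": matrix.cell_barcodes,
        "n_genes_detected": n_genes.astype(int),
        "n_umi": n_umi.astype(int),
        "mito_fraction": mito_fraction,
    })


def apply_qc_filters(qc: pd.DataFrame, thresholds: QCThresholds | None = None
                     ) -> np.ndarray:
    """Boolean keep mask: strictly above the gene floor and strictly below
    the UMI and mitochondrial ceilings."""
    if thresholds is None:
        thresholds = QCThresholds()
    keep = (
        (qc["n_genes_detected"].to_numpy() > thresholds.min_genes)
        & (qc["n_umi"].to_numpy() < thresholds.max_umi)
        & (qc["mito_fraction"].to_numpy() < thresholds.max_mito_fraction)
    )
    return keep


def sample_qc_summary(matrices: Sequence[CountMatrix],
                      samples: Sequence[SampleMetadata],
                      masks: Sequence[np.ndarray],
                      qc_tables: Sequence[pd.DataFrame] | None = None,
                      ) -> pd.DataFrame:
    """Per-sample means of genes/nucleus and UMIs/nucleus over kept cells.

    A sample with no kept cells yields a row with null means and a warning.
    """
    if not (len(matrices) == len(samples) == len(masks)):
        raise ValueError("matrices, samples and masks must be parallel")
    if qc_tables is None:
        qc_tables = [compute_cell_qc(m) for m in matrices]
    rows = []
    for meta, qc, mask in zip(samples, qc_tables, masks):
        mask = np.asarray(mask, dtype=bool)
        n_kept = int(mask.sum())
        if n_kept == 0:
            warnings.warn(f"sample {meta.sample_id}: no cells passed QC")
            mean_genes = mean_umi = np.nan
        else:
            mean_genes = float(qc["n_genes_detected"].to_numpy()[mask].mean())
            mean_umi = float(qc["n_umi"].to_numpy()[mask].mean())
        rows.append({
            "sample_id": meta.sample_id,
            "condition": meta.condition,
            "postmortem_delay_hours": meta.postmortem_delay_hours,
            "mean_genes_per_nucleus": mean_genes,
            "mean_umi_per_nucleus": mean_umi,
            "n_kept": n_kept,
            "n_total": len(mask),
        })
        logger.info("QC %s: kept %d/%d nuclei", meta.sample_id, n_kept,
                    len(mask))
    return pd.DataFrame(rows)


def pmd_independence(summary: pd.DataFrame) -> dict[str, dict]:
    """Correlation of per-sample QC means with postmortem delay.

    For each of mean genes/nucleus and mean UMIs/nucleus, the Pearson r
    against postmortem delay and its two-sided t-test p-value (n-2 df).
    Constant inputs are flagged "degenerate" with r reported as 0.
    """
    ok = summary.dropna(
        subset=["postmortem_delay_hours", "mean_genes_per_nucleus",
                "mean_umi_per_nucleus"])
    if len(ok) < 3:
        raise ValueError(
            f"insufficient samples for correlation: need >= 3, got {len(ok)}")
    pmd = ok["postmortem_delay_hours"].to_numpy(dtype=float)
    out = {}
    for label, col in (("genes_per_nucleus", "mean_genes_per_nucleus"),
                       ("umi_per_nucleus", "mean_umi_per_nucleus")):
        y = ok[col].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(pmd) == 0:
            out[label] = {"pearson_r": 0.0, "p_value": np.nan,
                          "degenerate": True}
            continue
        r, p = scipy.stats.pearsonr(pmd, y)
        out[label] = {"pearson_r": float(r), "p_value": float(p),
                      "degenerate": False}
    return out
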