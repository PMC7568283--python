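"""Normalization, HVG selection, PCA, graph clustering, markers, annotation.

The stage mirrors the standard single-cell workflow: per-cell log
normalization, variance-stabilizing-transform ranking of highly variable
genes, PCA on scaled and clipped HVG expression, modularity community
detection on a shared-nearest-neighbor (SNN) graph, one-vs-rest Wilcoxon
marker tests, and marker-reference scoring of clusters into cell types.

Determinism contract: for a fixed seed the whole stage is reproducible;
PCA component signs are fixed (largest-magnitude loading positive) and all
ties break lexicographically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .celltype_de import (adjust_pvalues, log2_fold_change_matrix,
                          rank_sum_matrix)
from .io_formats import CountMatrix

__all__ = [
    "ClusterParams",
    "DEFAULT_CELL_TYPE_REFERENCE",
    "log_normalize",
    "select_hvg",
    "embed_pca",
    "cluster_cells",
    "find_markers",
    "assign_cell_types",
    "cluster_and_annotate",
]

# Canonical cortical cell-type markers: astrocytes AQP4, endothelial CLDN5,
# excitatory neurons CAMK2A, inhibitory neurons GAD1, microglia C3,
# oligodendrocytes MBP.
DEFAULT_CELL_TYPE_REFERENCE: dict[str, list[str]] = {
    "astrocyte": ["AQP4"],
    "endothelial": ["CLDN5"],
    "excitatory_neuron": ["CAMK2A"],
    "inhibitory_neuron": ["GAD1"],
    "microglia": ["C3"],
    "oligodendrocyte": ["MBP"],
}

SNN_PRUNE = 1.0 / 15.0  # Jaccard floor below which SNN edges are dropped
PCA_CLIP = 10.0         # scaled-expression clip before PCA


@dataclass
class ClusterParams:
    n_hvg: int = 1000
    n_pcs_computed: int = 50
    n_pcs_used: int = 20
    knn_k: int = 20
    resolution: float = 1.0
    scale_factor: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs_used > self.n_pcs_computed:
            raise ValueError("n_pcs_used must be <= n_pcs_computed")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


def log_normalize(matrix: CountMatrix | sp.spmatrix,
                  scale_factor: float = 1e4) -> sp.csr_matrix:
    """Per-cell library-size normalization followed by log1p.

    x_norm = ln(1 + count * scale_factor / cell_total); all-zero cells map
    to all-zero columns.  Returns a sparse genes x cells float matrix.
    """
    X = matrix.values if isinstance(matrix, CountMatrix) else matrix
    X = sp.csc_matrix(X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=0)).ravel()
    scale = np.divide(scale_factor, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return X.tocsr()


def select_hvg(counts: CountMatrix | sp.spmatrix,
               gene_ids: list[str] | None = None,
               n_hvg: int = 1000) -> np.ndarray:
    """Rank genes by variance-stabilized standardized variance; top n_hvg.

    A lowess trend of log10 variance vs log10 mean is fitted over raw
    counts; each gene is standardized by its fitted standard deviation with
    values clipped at sqrt(n_cells); genes are ranked by the variance of
    the clipped standardized values.  Ties break by gene id.  Returns row
    indices in rank order.
    """
    if isinstance(counts, CountMatrix):
        if gene_ids is None:
            gene_ids = counts.gene_ids
        X = counts.values
    else:
        X = counts
    X = sp.csr_matrix(X, dtype=np.float64)
    n_genes, n_cells = X.shape
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n_genes)]
    if n_cells < 2:
        raise ValueError("HVG selection needs >= 2 cells")

    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean ** 2) * n_cells / (n_cells - 1)

    informative = (var > 0) & (mean > 0)
    score = np.zeros(n_genes)
    if informative.any():
        lx = np.log10(mean[informative])
        ly = np.log10(var[informative])
        fit = lowess(ly, lx, frac=0.3, return_sorted=False)
        sd_fit = np.sqrt(10.0 ** fit)
        clip = np.sqrt(n_cells)
        idx_inf = np.flatnonzero(informative)
        for pos, g in enumerate(idx_inf):
            row = X.getrow(g)
            mu, sd = mean[g], sd_fit[pos]
            z_nz = np.minimum((row.data - mu) / sd, clip)
            z0 = -mu / sd  # value of the (n_cells - nnz) zero entries
            n0 = n_cells - row.nnz
            s = z_nz.sum() + n0 * z0
            s2 = (z_nz ** 2).sum() + n0 * z0 ** 2
            score[g] = (s2 - s ** 2 / n_cells) / (n_cells - 1)

    n_informative = int(informative.sum())
    if n_informative < n_hvg:
        warnings.warn(
            f"only {n_informative} informative genes for n_hvg={n_hvg}; "
            "returning all")
    order = sorted(range(n_genes), key=lambda g: (-score[g], gene_ids[g]))
    order = [g for g in order if informative[g]]
    return np.array(order[:n_hvg], dtype=int)


def embed_pca(normalized_hvg, params: ClusterParams | None = None
              ) -> np.ndarray:
    """PCA embedding of scaled, clipped HVG expression (cells x components).

    Genes are scaled to zero mean, unit variance and clipped at +-10;
    component signs are fixed so the largest-magnitude loading is positive.
    """
    if params is None:
        params = ClusterParams()
    X = normalized_hvg
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    # accept genes x cells and transpose to cells x genes
    data = X.T
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    data = np.clip((data - mu) / sd, -PCA_CLIP, PCA_CLIP)

    n_comp = min(params.n_pcs_computed, data.shape[0] - 1, data.shape[1])
    if n_comp < params.n_pcs_computed:
        warnings.warn(
            f"reducing n_pcs_computed from {params.n_pcs_computed} to "
            f"{n_comp} (limited by data shape)")
    pca = PCA(n_components=n_comp, svd_solver="full")
    emb = pca.fit_transform(data)
    for j in range(n_comp):
        loadings = pca.components_[j]
        k = np.argmax(np.abs(loadings))
        if loadings[k] < 0:
            emb[:, j] *= -1.0
    return emb


def _snn_graph(embedding: np.ndarray, knn_k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard weights, pruned."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=knn_k).fit(embedding)
    indices = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), knn_k - 1)
    cols = indices[:, : knn_k - 1].ravel()
    # neighbor sets of size knn_k including self, as a binary matrix
    A = sp.csr_matrix(
        (np.ones(n + rows.size), (np.concatenate([np.arange(n), rows]),
                                  np.concatenate([np.arange(n), cols]))),
        shape=(n, n))
    A.data[:] = 1.0
    shared = (A @ A.T).tocoo()
    union = 2 * knn_k - shared.data
    jac = shared.data / union
    keep = (jac >= SNN_PRUNE) & (shared.row != shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                         shape=(n, n))


def cluster_cells(embedding: np.ndarray, knn_k: int = 20,
                  resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden modularity clustering of the SNN graph over the embedding.

    Labels are renumbered 0..K-1 by decreasing cluster size and the result
    is deterministic for a fixed seed.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n < knn_k + 1:
        warnings.warn(
            f"only {n} cells for knn_k={knn_k}; returning a single cluster")
        return np.zeros(n, dtype=int)
    if np.all(embedding == embedding[0]):
        # degenerate geometry: every cell identical
        return np.zeros(n, dtype=int)
    snn = _snn_graph(embedding, knn_k)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                     edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership)
    # renumber by decreasing size, ties by original label
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    remap = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def find_markers(normalized, gene_symbols, labels,
                 logfc_threshold: float = 0.25,
                 max_adjusted_p: float = 0.1,
                 method: str = "bonferroni") -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker scan per cluster.

    Genes are pre-filtered at |log2FC| >= ``logfc_threshold`` before
    testing; adjustment is within the tested gene set of each cluster and
    markers are significant at adjusted P < ``max_adjusted_p``.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("find_markers requires >= 2 clusters")
    gene_symbols = np.asarray(gene_symbols)
    Xs = sp.csr_matrix(normalized)
    records = []
    for c in uniq:
        mask = labels == c
        if mask.sum() < 2:
            warnings.warn(f"cluster {c} is a singleton; skipped")
            continue
        lfc = log2_fold_change_matrix(Xs, mask)
        tested = np.flatnonzero(np.abs(lfc) >= logfc_threshold)
        if tested.size == 0:
            continue
        dense = Xs[tested].toarray()
        p = rank_sum_matrix(dense, mask)
        adj = adjust_pvalues(p, method=method)
        pct_in = (dense[:, mask] > 0).mean(axis=1)
        pct_out = (dense[:, ~mask] > 0).mean(axis=1)
        for i, g in enumerate(tested):
            records.append({
                "gene": gene_symbols[g], "cluster": int(c),
                "log2fc": float(lfc[g]), "raw_p": float(p[i]),
                "adjusted_p": float(adj[i]),
                "pct_in": float(pct_in[i]), "pct_out": float(pct_out[i]),
                "significant": bool(adj[i] < max_adjusted_p),
            })
    return pd.DataFrame(
        records, columns=["gene", "cluster", "log2fc", "raw_p", "adjusted_p",
                          "pct_in", "pct_out", "significant"])


def assign_cell_types(normalized, gene_symbols, labels,
                      reference: dict[str, list[str]] | None = None,
                      margin: float = 0.0) -> dict[int, str]:
    """Score clusters against a marker reference and assign cell types.

    score(type, cluster) = mean over the type's markers of the gene's
    z-scored (across cluster means) expression; the argmax wins if it beats
    the runner-up by more than ``margin``, else the cluster is
    "unassigned".
    """
    if reference is None:
        reference = DEFAULT_CELL_TYPE_REFERENCE
    if not reference:
        raise ValueError("marker reference is empty")
    gene_symbols = list(gene_symbols)
    sym_to_idx: dict[str, int] = {}
    for i, s in enumerate(gene_symbols):
        sym_to_idx.setdefault(s, i)
    missing = sorted({g for gs in reference.values() for g in gs
                      if g not in sym_to_idx})
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")

    labels = np.asarray(labels)
    uniq = np.unique(labels)
    Xs = sp.csr_matrix(normalized)
    means = np.column_stack([
        np.asarray(Xs[:, labels == c].mean(axis=1)).ravel() for c in uniq
    ])  # genes x clusters
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True) if uniq.size > 1 else \
        np.ones_like(mu)
    sd[sd == 0] = np.inf  # zero-variance genes contribute z = 0
    z = (means - mu) / sd

    assignment: dict[int, str] = {}
    for j, c in enumerate(uniq):
        scores = {
            t: float(np.mean([z[sym_to_idx[g], j] for g in gs]))
            for t, gs in reference.items()
        }
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best_t, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else -np.inf
        assignment[int(c)] = best_t if best - second > margin else "unassigned"
    return assignment


def cluster_and_annotate(counts: CountMatrix,
                         params: ClusterParams | None = None,
                         reference: dict[str, list[str]] | None = None
                         ) -> dict:
    """Run the full stage: normalize -> HVG -> PCA -> cluster -> annotate.

    Returns a dict with ``normalized`` (sparse genes x cells), ``hvg``
    (gene row indices), ``embedding``, ``labels``, ``cluster_types`` and
    per-cell ``cell_types``.
    """
    if params is None:
        params = ClusterParams()
    normalized = log_normalize(counts, params.scale_factor)
    hvg = select_hvg(counts, n_hvg=params.n_hvg)
    emb = embed_pca(normalized[hvg], params)
    labels = cluster_cells(emb[:, : params.n_pcs_used], params.knn_k,
                           params.resolution, params.seed)
    cluster_types = assign_cell_types(
        normalized, counts.gene_symbols, labels, reference)
    cell_types = np.array([cluster_types[int(c)] for c in labels])
    return {
        "normalized": normalized,
        "hvg": hvg,
        "embedding": emb,
        "labels": labels,
        "cluster_types": cluster_types,
        "cell_types": cell_types,
    }
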