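import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoshift.celltype_de import (DEThresholds, adjust_pvalues,
                                     deg_overlap, log2_fold_change,
                                     log2_fold_change_matrix,
                                     rank_sum_matrix, run_celltype_de,
                                     wilcoxon_rank_sum)


def brute_force_exact_p(x, y):
    """Enumerate all rank assignments of the pooled tie-free sample."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    sums = np.array(sums)
    lo = (sums <= w_obs).mean()
    hi = (sums >= w_obs).mean()
    return min(1.0, 2 * min(lo, hi))


def test_exact_p_separated_triples():
    r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
    assert r["two_sided_p"] == pytest.approx(0.1, abs=1e-12)
    assert r["method"] == "exact"


def test_identical_multisets_degenerate():
    r = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
    assert r["two_sided_p"] == 1.0
    assert r["degenerate"]


def test_exact_matches_brute_force_small():
    rng = np.random.default_rng(1)
    for n1, n2 in [(1, 3), (2, 2), (3, 4), (4, 4), (5, 3)]:
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
        r = wilcoxon_rank_sum(x, y, mode="exact")
        assert r["two_sided_p"] == pytest.approx(
            brute_force_exact_p(x, y), abs=1e-12)


def test_normal_mode_agrees_with_scipy():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=30), rng.normal(0.5, size=25)
    r = wilcoxon_rank_sum(x, y, mode="normal")
    ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic")
    assert r["two_sided_p"] == pytest.approx(ref.pvalue, rel=1e-9)
    assert r["statistic"] == pytest.approx(ref.statistic)


def test_rank_sum_matrix_matches_scalar_path():
    rng = np.random.default_rng(3)
    X = rng.poisson(1.0, size=(20, 40)).astype(float)
    mask = np.zeros(40, dtype=bool)
    mask[:18] = True
    p_mat = rank_sum_matrix(X, mask)
    for i in range(20):
        r = wilcoxon_rank_sum(X[i, mask], X[i, ~mask], mode="normal")
        assert p_mat[i] == pytest.approx(r["two_sided_p"], abs=1e-12)


@given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
       st.lists(st.floats(-50, 50), min_size=1, max_size=12))
@settings(max_examples=60, deadline=None)
def test_wilcoxon_p_is_probability_and_symmetric(x, y):
    r1 = wilcoxon_rank_sum(x, y)
    r2 = wilcoxon_rank_sum(y, x)
    assert 0 <= r1["two_sided_p"] <= 1
    assert r1["two_sided_p"] == pytest.approx(r2["two_sided_p"], abs=1e-9)


def test_log2_fold_change_definition():
    assert log2_fold_change([1.0, 1.0], [1.0, 1.0]) == 0.0
    # case de-logged mean exactly 2x control
    case = np.log1p([4.0, 4.0])
    ctrl = np.log1p([2.0, 2.0])
    assert log2_fold_change(case, ctrl) == pytest.approx(1.0, abs=1e-6)
    assert log2_fold_change([0.0, 0.0], [0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        log2_fold_change([], [1.0])


def test_adjust_bonferroni_and_bh_hand_values():
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.5], "bonferroni"), [0.02, 1.0])
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4)


def test_adjust_rejects_bad_p():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_pvalues([0.5], method="holm")


@given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
@settings(max_examples=60, deadline=None)
def test_adjusted_at_least_raw_and_matches_statsmodels(p):
    from statsmodels.stats.multitest import multipletests
    for method, sm_name in (("bonferroni", "bonferroni"), ("bh", "fdr_bh")):
        adj = adjust_pvalues(p, method)
        assert (adj >= np.asarray(p) - 1e-15).all()
        ref = multipletests(p, method=sm_name)[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)


def _toy_de_input(seed=0, n_genes=60, n_cells=120, lfc=1.5):
    """One cell type; first 5 genes shifted up in AD cells."""
    rng = np.random.default_rng(seed)
    X = rng.poisson(1.0, size=(n_genes, n_cells)).astype(float)
    condition = np.where(np.arange(n_cells) < n_cells // 2, "AD", "NC")
    X[:5, condition == "AD"] *= 2 ** lfc
    norm = np.log1p(X)
    table = pd.DataFrame({"condition": condition,
                          "cell_type": ["astrocyte"] * n_cells})
    return norm, [f"G{i}" for i in range(n_genes)], table


def test_run_celltype_de_direction_antisymmetry():
    norm, genes, table = _toy_de_input()
    de = run_celltype_de(norm, genes, table)
    swapped = table.assign(
        condition=np.where(table["condition"] == "AD", "NC", "AD"))
    de_sw = run_celltype_de(norm, genes, swapped)
    merged = de.merge(de_sw, on="gene", suffixes=("", "_sw"))
    np.testing.assert_allclose(merged["log2fc"], -merged["log2fc_sw"],
                               atol=1e-12)
    np.testing.assert_allclose(merged["raw_p"], merged["raw_p_sw"],
                               atol=1e-12)


def test_run_celltype_de_order_invariance():
    norm, genes, table = _toy_de_input()
    de = run_celltype_de(norm, genes, table)
    perm = np.random.default_rng(4).permutation(norm.shape[1])
    de_perm = run_celltype_de(norm[:, perm], genes,
                              table.iloc[perm].reset_index(drop=True))
    a = de.sort_values("gene").reset_index(drop=True)
    b = de_perm.sort_values("gene").reset_index(drop=True)
    assert (a["significant"] == b["significant"]).all()
    np.testing.assert_allclose(a["raw_p"], b["raw_p"], atol=1e-12)


def test_all_zero_gene_absent_and_one_condition_skipped():
    norm, genes, table = _toy_de_input()
    norm[10, :] = 0.0
    de = run_celltype_de(norm, genes, table)
    assert "G10" not in set(de["gene"])
    solo = table.assign(condition="AD")
    with pytest.warns(UserWarning, match="one condition"):
        empty = run_celltype_de(norm, genes, solo)
    assert empty.empty


def test_planted_deg_recovered_up():
    norm, genes, table = _toy_de_input(n_cells=400)
    de = run_celltype_de(norm, genes, table)
    top = de[de["gene"].isin([f"G{i}" for i in range(5)])]
    assert top["significant"].all()
    assert (top["direction"] == "up").all()


def _records(ctype, genes):
    return pd.DataFrame({
        "gene": list(genes), "cell_type": ctype,
        "log2fc": 1.0, "raw_p": 0.001, "adjusted_p": 0.001,
        "direction": "up", "significant": True,
    })


def test_deg_overlap_toy_tables():
    tables = [_records("t1", ["A", "B"]), _records("t2", ["B", "C"]),
              _records("t3", ["B"])]
    out = deg_overlap(tables)
    assert out["shared_all_types"] == ["B"]
    assert out["n_shared_all_types"] == 1
    assert out["exclusive_per_type"] == {"t1": ["A"], "t2": ["C"], "t3": []}


def test_deg_overlap_disjoint_and_identical():
    disjoint = deg_overlap([_records("t1", ["A"]), _records("t2", ["B"])])
    assert disjoint["n_shared_all_types"] == 0
    same = deg_overlap([_records("t1", ["X", "Y"]), _records("t2", ["X", "Y"])])
    assert same["n_shared_all_types"] == 2
    assert same["exclusive_per_type"] == {"t1": [], "t2": []}
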