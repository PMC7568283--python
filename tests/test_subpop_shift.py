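import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucleoshift.io_formats import CountMatrix
from nucleoshift.subpop_shift import (SubpopParams, classify_subpops,
                                      enrichment_scores, proportion_shift,
                                      subcluster, subpop_signatures)


def test_enrichment_single_subpop_centering():
    rng = np.random.default_rng(0)
    norm = np.log1p(rng.poisson(1.0, size=(20, 100)).astype(float))
    labels = np.array(["s1"] * 100)
    sc = enrichment_scores(norm, [f"G{i}" for i in range(20)], labels,
                           up_genes=["G0", "G1", "G2"], down_genes=[])
    assert sc["up_score"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(sc["down_score"].iloc[0])


def test_enrichment_binary_gene_forced_values():
    # one gene, two equal subpops, values +a in A and -a after z-scoring
    norm = np.array([[2.0] * 50 + [0.0] * 50])
    labels = np.array(["A"] * 50 + ["B"] * 50)
    sc = enrichment_scores(norm, ["G0"], labels, ["G0"], [])
    up = sc.set_index("subpop")["up_score"]
    assert up["A"] == pytest.approx(1.0, abs=1e-12)
    assert up["B"] == pytest.approx(-1.0, abs=1e-12)


def test_enrichment_zero_variance_gene_contributes_zero():
    norm = np.vstack([np.ones(40), np.r_[np.ones(20) * 3, np.ones(20)]])
    labels = np.array(["A"] * 20 + ["B"] * 20)
    both = enrichment_scores(norm, ["C0", "G1"], labels, ["C0", "G1"], [])
    only_var = enrichment_scores(norm, ["C0", "G1"], labels, ["G1"], [])
    a_both = both.set_index("subpop")["up_score"]["A"]
    a_var = only_var.set_index("subpop")["up_score"]["A"]
    assert a_both == pytest.approx(a_var / 2, abs=1e-12)


def test_centering_identity_weighted_mean_zero(six_type_cohort):
    from tests.conftest import pool_cohort
    from nucleoshift.cluster_annotate import log_normalize

    _, matrices, _, truth = six_type_cohort
    pooled, cells = pool_cohort(matrices, truth)
    astro = cells["cell_type"].to_numpy() == "astrocyte"
    norm = log_normalize(pooled)[:, astro]
    labels = cells.loc[astro, "subpop"].to_numpy()
    tg = truth.genes
    up = sorted(tg[(tg["deg_cell_type"] == "astrocyte")
                   & (tg["deg_log2fc"] > 0)]["symbol"])
    sc = enrichment_scores(norm, pooled.gene_symbols, labels, up, [])
    weights = pd.Series(labels).value_counts()
    weighted = sum(sc.set_index("subpop")["up_score"][s] * weights[s]
                   for s in weights.index) / weights.sum()
    assert weighted == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("up,down,expected", [
    (0.6, 0.1, "up_regulated"),
    (0.4, 0.4, "unaffected"),
    (0.7, 0.7, "ambiguous"),
    (0.6, 0.8, "down_regulated"),
    (np.nan, 0.6, "down_regulated"),
])
def test_classification_rules(up, down, expected):
    scores = pd.DataFrame({"subpop": ["s1"], "up_score": [up],
                           "down_score": [down]})
    out = classify_subpops(scores, threshold=0.5)
    assert out["classification"].iloc[0] == expected


def test_classification_monotone_in_threshold():
    rng = np.random.default_rng(1)
    scores = pd.DataFrame({
        "subpop": [f"s{i}" for i in range(20)],
        "up_score": rng.uniform(-1, 1, 20),
        "down_score": rng.uniform(-1, 1, 20),
    })
    prev = None
    for thr in (0.2, 0.5, 0.8):
        out = classify_subpops(scores, thr)
        hits = set(out.loc[out["classification"] != "unaffected", "subpop"])
        if prev is not None:
            assert hits <= prev
        prev = hits


def test_proportion_shift_hand_arithmetic():
    rows = []
    for sid, cond, prop in [("c1", "AD", 0.4), ("c2", "AD", 0.6),
                            ("n1", "NC", 0.1), ("n2", "NC", 0.3)]:
        n = 100
        rows += [{"sample_id": sid, "condition": cond, "subpop": "s1"}] \
            * int(prop * n)
        rows += [{"sample_id": sid, "condition": cond, "subpop": "s2"}] \
            * int((1 - prop) * n)
    rep = proportion_shift(pd.DataFrame(rows)).set_index("subpop")
    s1 = rep.loc["s1"]
    assert s1["mean_prop_case"] == pytest.approx(0.5)
    assert s1["mean_prop_control"] == pytest.approx(0.2)
    assert s1["delta_pp"] == pytest.approx(30.0)
    assert s1["delta_relative"] == pytest.approx(1.5)
    assert s1["sem_case"] == pytest.approx(0.1)


def test_proportion_shift_identical_conditions_zero_delta():
    rows = []
    for sid, cond in [("c1", "AD"), ("n1", "NC")]:
        rows += [{"sample_id": sid, "condition": cond, "subpop": "s1"}] * 30
        rows += [{"sample_id": sid, "condition": cond, "subpop": "s2"}] * 70
    rep = proportion_shift(pd.DataFrame(rows))
    np.testing.assert_allclose(rep["delta_pp"], 0.0, atol=1e-12)


def test_proportion_shift_missing_sample_warns():
    rows = [{"sample_id": "c1", "condition": "AD", "subpop": "s1"}] * 10
    with pytest.warns(UserWarning, match="no cells"):
        proportion_shift(pd.DataFrame(rows), all_samples=["c1", "n1"])


def test_subcluster_below_floor_single_subpop():
    rng = np.random.default_rng(2)
    m = CountMatrix(sp.csc_matrix(rng.poisson(1.0, size=(50, 20))),
                    [f"g{i}" for i in range(50)],
                    [f"G{i}" for i in range(50)],
                    [f"c{j}" for j in range(20)])
    with pytest.warns(UserWarning, match="single subpopulation"):
        labels = subcluster(m, 0.2, SubpopParams(min_cells=50))
    assert set(labels) == {"s1"}


def test_subcluster_deterministic(six_type_cohort):
    from tests.conftest import pool_cohort

    _, matrices, _, truth = six_type_cohort
    pooled, cells = pool_cohort(matrices, truth)
    astro_idx = np.flatnonzero(cells["cell_type"].to_numpy() == "astrocyte")
    sub = CountMatrix(pooled.values[:, astro_idx], pooled.gene_ids,
                      pooled.gene_symbols,
                      [pooled.cell_barcodes[i] for i in astro_idx])
    l1 = subcluster(sub, 0.2)
    l2 = subcluster(sub, 0.2)
    assert (l1 == l2).all()


def _signature_setup():
    rng = np.random.default_rng(3)
    n = 200
    norm = np.log1p(rng.poisson(1.0, size=(30, n)).astype(float))
    labels = np.array(["s1"] * 100 + ["s2"] * 100)
    norm[0, labels == "s1"] += 1.0  # planted signature gene, up in s1
    cls = pd.DataFrame({
        "subpop": ["s1", "s2"],
        "up_score": [0.8, -0.2], "down_score": [-0.1, 0.7],
        "classification": ["up_regulated", "down_regulated"]})
    return norm, [f"G{i}" for i in range(30)], labels, cls


def test_signatures_planted_gene_and_antisymmetry():
    norm, genes, labels, cls = _signature_setup()
    sig = subpop_signatures(norm, genes, labels, cls)
    row = sig[sig["gene"] == "G0"].iloc[0]
    assert row["significant"] and row["direction"] == "up"
    flipped = cls.assign(classification=["down_regulated", "up_regulated"])
    sig_fl = subpop_signatures(norm, genes, labels, flipped)
    merged = sig.merge(sig_fl, on="gene", suffixes=("", "_fl"))
    np.testing.assert_allclose(merged["log2fc"], -merged["log2fc_fl"],
                               atol=1e-12)


def test_signatures_require_both_sides():
    norm, genes, labels, cls = _signature_setup()
    only_up = cls.assign(classification=["up_regulated", "unaffected"])
    with pytest.raises(ValueError, match="signature comparison undefined"):
        subpop_signatures(norm, genes, labels, only_up)
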