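import numpy as np
import pandas as pd
import pytest

from tepmced.consensus import (
    agreement_matrix,
    topk_overlap,
    weighted_consensus,
)

from ._oracles import spearman_no_ties


def _imp(values, genes):
    return pd.Series(np.asarray(values, dtype=float), index=genes)


def test_consensus_matches_spreadsheet_arithmetic_on_a_toy_table():
    genes = ["g1", "g2", "g3", "g4", "g5"]
    imps = {
        "A": _imp([0.0, 1.0, 2.0, 3.0, 4.0], genes),
        "B": _imp([4.0, 3.0, 2.0, 1.0, 0.0], genes),
        "C": _imp([1.0, 1.0, 1.0, 1.0, 3.0], genes),
    }
    aucs = {"A": 0.9, "B": 0.8, "C": 0.7}
    ranking = weighted_consensus(imps, aucs, exclude=(), top_k=3)
    # hand arithmetic: min-max scale each column, then sum auc * scaled
    scaled = {
        "A": [0, 0.25, 0.5, 0.75, 1.0],
        "B": [1.0, 0.75, 0.5, 0.25, 0],
        "C": [0, 0, 0, 0, 1.0],
    }
    for i, g in enumerate(genes):
        expected = 0.9 * scaled["A"][i] + 0.8 * scaled["B"][i] + 0.7 * scaled["C"][i]
        assert ranking.scores[g] == pytest.approx(expected)
    # g5: 0.9 + 0.7 = 1.6; g1: 0.8; g2: .225+.6=.825; g3: .45+.4=.85; g4: .675+.2=.875
    assert list(ranking.scores.index[:3]) == ["g5", "g4", "g3"]
    assert ranking.top_k == ["g5", "g4", "g3"]


def test_single_model_consensus_preserves_its_own_order():
    genes = [f"g{i}" for i in range(6)]
    imp = _imp([3.0, 6.0, 1.0, 5.0, 2.0, 4.0], genes)
    ranking = weighted_consensus({"M": imp}, {"M": 0.9}, exclude=())
    assert list(ranking.scores.index) == list(imp.sort_values(ascending=False).index)


def test_consensus_is_invariant_to_positive_rescaling_of_one_model():
    genes = [f"g{i}" for i in range(8)]
    rng = np.random.default_rng(0)
    a = _imp(rng.random(8), genes)
    b = _imp(rng.random(8), genes)
    aucs = {"A": 0.9, "B": 0.7}
    r1 = weighted_consensus({"A": a, "B": b}, aucs, exclude=())
    r2 = weighted_consensus({"A": a * 37.5, "B": b}, aucs, exclude=())
    pd.testing.assert_series_equal(r1.scores, r2.scores)


def test_identical_vectors_give_the_common_order_regardless_of_weights():
    genes = [f"g{i}" for i in range(5)]
    v = _imp([5.0, 1.0, 4.0, 2.0, 3.0], genes)
    ranking = weighted_consensus({"A": v, "B": v.copy()}, {"A": 0.99, "B": 0.51}, exclude=())
    assert list(ranking.scores.index) == ["g0", "g2", "g4", "g3", "g1"]


def test_excluded_models_contribute_nothing_but_are_recorded():
    genes = ["g1", "g2", "g3"]
    a = _imp([3.0, 2.0, 1.0], genes)
    d = _imp([0.0, 0.0, 9.0], genes)  # would invert the order if included
    ranking = weighted_consensus({"A": a, "DT": d}, {"A": 0.9, "DT": 0.95})
    assert ranking.excluded_models == ["DT"]
    assert list(ranking.scores.index) == ["g1", "g2", "g3"]
    assert "DT" in ranking.per_model_scaled.columns  # still visible for inspection
    with pytest.raises(ValueError):
        weighted_consensus({"DT": d}, {"DT": 0.9})


def test_missing_genes_default_to_zero_importance():
    a = _imp([2.0, 1.0], ["g1", "g2"])
    b = _imp([1.0, 2.0], ["g2", "g3"])
    ranking = weighted_consensus({"A": a, "B": b}, {"A": 1.0, "B": 1.0}, exclude=())
    assert set(ranking.scores.index) == {"g1", "g2", "g3"}
    assert ranking.per_model_scaled.loc["g3", "A"] == 0.0


def test_agreement_is_one_with_itself_and_minus_one_when_reversed():
    genes = [f"g{i}" for i in range(6)]
    v = _imp([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], genes)
    rev = _imp([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], genes)
    out = agreement_matrix({"A": v, "B": v.copy(), "C": rev})
    assert out.rho.loc["A", "A"] == 1.0
    assert out.rho.loc["A", "B"] == pytest.approx(1.0)
    assert out.rho.loc["A", "C"] == pytest.approx(-1.0)
    out.validate()


def test_agreement_restricts_to_shared_nonzero_genes_matching_textbook_formula():
    genes = [f"g{i}" for i in range(8)]
    rng = np.random.default_rng(1)
    a_vals = rng.permutation(np.arange(1.0, 9.0))
    b_vals = rng.permutation(np.arange(1.0, 9.0))
    a = _imp(a_vals, genes)
    b = _imp(b_vals, genes)
    a[["g6", "g7"]] = 0.0  # two genes carry no importance in model A
    out = agreement_matrix({"A": a, "B": b})
    shared = sorted(set(a.index[a != 0]) & set(b.index[b != 0]))
    assert out.shared_counts.loc["A", "B"] == 6
    expected = spearman_no_ties(a[shared].to_numpy(), b[shared].to_numpy())
    assert out.rho.loc["A", "B"] == pytest.approx(expected)


def test_agreement_with_too_few_shared_genes_is_flagged_undefined():
    a = _imp([1.0, 2.0, 0.0, 0.0], list("wxyz"))
    b = _imp([0.0, 3.0, 1.0, 0.0], list("wxyz"))
    out = agreement_matrix({"A": a, "B": b})
    assert np.isnan(out.rho.loc["A", "B"])
    assert out.shared_counts.loc["A", "B"] == 1
    with pytest.raises(ValueError):
        agreement_matrix({"A": a})


def test_topk_overlap_counts_intersection():
    genes = [f"g{i}" for i in range(20)]
    v = _imp(np.arange(20.0, 0.0, -1.0), genes)
    r1 = weighted_consensus({"A": v}, {"A": 0.9}, exclude=())
    r2 = weighted_consensus({"A": v}, {"A": 0.9}, exclude=())
    assert topk_overlap(r1, r2, k=15) == 15
    other = _imp(np.arange(20.0, 0.0, -1.0), [f"h{i}" for i in range(20)])
    r3 = weighted_consensus({"A": other}, {"A": 0.9}, exclude=())
    assert topk_overlap(r1, r3, k=15) == 0
    with pytest.warns(UserWarning):
        n = topk_overlap(r1, r2, k=50)
    assert n == 20
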