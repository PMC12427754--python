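import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tepmced.preprocess import (
    Scaler,
    SchemaError,
    anova_select,
    bh_adjust,
    correlation_prune,
    exclude_flagged,
    harmonize_external,
    select_features,
)

from ._oracles import anova_f_and_p, bh_stepup, greedy_prune


def test_exclude_flagged_drops_flagged_and_unlabeled_preserving_order(small_cohort):
    meta = small_cohort.metadata.copy()
    meta.loc[meta.index[3], "label"] = None
    kept = exclude_flagged(meta)
    assert kept["flagged"].sum() == 0
    assert meta.loc[meta.index[3], "sample_id"] not in set(kept["sample_id"])
    assert len(kept) == len(meta) - 60 - 1
    # original row order is preserved
    pos = {s: i for i, s in enumerate(meta["sample_id"])}
    order = [pos[s] for s in kept["sample_id"]]
    assert order == sorted(order)


def test_exclude_flagged_requires_flag_column():
    with pytest.raises(SchemaError):
        exclude_flagged(pd.DataFrame({"sample_id": ["a"], "label": ["cancer"]}))


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_adjustment_matches_stepup_oracle(pvals):
    p = np.asarray(pvals)
    np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), rtol=0, atol=1e-12)


def test_bh_adjustment_is_monotone_and_bounded():
    rng = np.random.default_rng(0)
    p = rng.random(500)
    q = bh_adjust(p)
    assert np.all((q >= p - 1e-12) & (q <= 1.0))
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def _toy_expr_meta(seed=0, n=90, p=40, shift_first=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    x = rng.standard_normal((n, p))
    x[:, 0] += shift_first * y
    ids = [f"T{i:03d}" for i in range(n)]
    expr = pd.DataFrame(x, index=ids, columns=[f"g{j:02d}" for j in range(p)])
    meta = pd.DataFrame(
        {"sample_id": ids, "label": np.where(y == 1, "cancer", "control"), "flagged": 0}
    )
    return expr, meta


def test_anova_statistics_match_direct_formula_oracle():
    expr, meta = _toy_expr_meta(seed=1)
    report = anova_select(expr, meta, discovery_fraction=1.0, fdr=1.1, cap=1000)
    table = report.anova_pass.set_index("gene")
    groups = meta.set_index("sample_id").loc[expr.index, "label"].to_numpy()
    pvals = np.empty(expr.shape[1])
    for j, g in enumerate(expr.columns):
        f_o, p_o = anova_f_and_p(expr[g].to_numpy(), groups)
        pvals[j] = p_o
        np.testing.assert_allclose(table.loc[g, "F"], f_o, rtol=1e-9)
    q_o = bh_stepup(pvals)
    for j, g in enumerate(expr.columns):
        np.testing.assert_allclose(table.loc[g, "q"], q_o[j], rtol=1e-9)


def test_anova_selects_shifted_gene_and_respects_cap():
    expr, meta = _toy_expr_meta(seed=2, shift_first=3.0)
    report = anova_select(expr, meta, discovery_fraction=1.0, fdr=0.001, cap=300)
    assert report.capped[0] == "g00"
    capped = anova_select(expr, meta, discovery_fraction=1.0, fdr=1.1, cap=5)
    assert len(capped.capped) == 5
    qs = capped.anova_pass.set_index("gene").loc[capped.capped, "q"].to_numpy()
    assert np.all(np.diff(qs) >= 0)


def test_anova_constant_gene_gets_q_one_and_is_never_selected():
    expr, meta = _toy_expr_meta(seed=3)
    expr["g05"] = 7.0
    report = anova_select(expr, meta, discovery_fraction=1.0, fdr=0.5, cap=300)
    assert "g05" not in report.capped
    full = anova_select(expr, meta, discovery_fraction=1.0, fdr=1.1, cap=1000)
    assert full.anova_pass.set_index("gene").loc["g05", "q"] == 1.0


def test_discovery_subset_is_stratified_and_of_requested_size():
    expr, meta = _toy_expr_meta(seed=4, n=120)
    report = anova_select(expr, meta, discovery_fraction=0.33, fdr=1.1, cap=1000, seed=5)
    ids = report.discovery_sample_ids
    assert len(ids) == int(0.33 * 120)  # floor, per the stratified splitter
    labels = meta.set_index("sample_id").loc[ids, "label"]
    frac = (labels == "cancer").mean()
    assert abs(frac - 0.5) < 0.05  # stratification preserves the 50/50 mix


def test_correlation_pruning_matches_greedy_oracle():
    rng = np.random.default_rng(6)
    n, p = 200, 15
    base = rng.standard_normal((n, 5))
    mix = rng.standard_normal((5, p))
    x = base @ mix + 0.8 * rng.standard_normal((n, p))
    genes = [f"g{j:02d}" for j in range(p)]
    expr = pd.DataFrame(x, columns=genes)
    corr = np.corrcoef(x, rowvar=False)
    expected = [genes[j] for j in greedy_prune(corr, 0.8)]
    report = correlation_prune(expr, genes, r_threshold=0.8)
    assert report.retained == expected
    # every drop names a retained partner with |r| above the threshold
    for kept, dropped, r in report.dropped_pairs:
        assert kept in report.retained and dropped not in report.retained
        assert abs(r) > 0.8


def test_duplicate_gene_is_pruned_and_constant_gene_is_kept():
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
    expr["dup"] = expr["a"]
    expr["flat"] = 1.0
    report = correlation_prune(expr, ["a", "dup", "flat", "b"], r_threshold=0.8)
    assert report.retained == ["a", "flat", "b"]
    assert report.dropped_pairs[0][:2] == ("a", "dup")


def test_select_features_prioritizes_stronger_member_of_correlated_pair():
    rng = np.random.default_rng(8)
    n = 300
    y = np.array([1, 0] * (n // 2))
    strong = 2.5 * y + rng.standard_normal(n)
    weak = strong + 0.3 * rng.standard_normal(n)  # correlated, noisier copy
    noise = rng.standard_normal((n, 10))
    ids = [f"S{i:03d}" for i in range(n)]
    expr = pd.DataFrame(noise, index=ids, columns=[f"n{j}" for j in range(10)])
    expr.insert(0, "weak", weak)
    expr.insert(0, "strong", strong)
    meta = pd.DataFrame({"sample_id": ids, "label": np.where(y == 1, "cancer", "control"), "flagged": 0})
    report = select_features(expr, meta, discovery_fraction=1.0, fdr=0.001, cap=300)
    assert "strong" in report.retained
    assert "weak" not in report.retained


def test_scaler_standardizes_train_and_maps_constant_genes_to_zero():
    rng = np.random.default_rng(9)
    train = pd.DataFrame(rng.normal(3, 2, size=(80, 4)), columns=list("abcd"))
    train["d"] = 5.0
    sc = Scaler().fit(train)
    z = sc.transform(train)
    np.testing.assert_allclose(z[["a", "b", "c"]].mean(), 0, atol=1e-12)
    np.testing.assert_allclose(z[["a", "b", "c"]].std(ddof=0), 1, atol=1e-12)
    assert (z["d"] == 0).all()
    # new data is scaled with *training* statistics
    test = pd.DataFrame(rng.normal(10, 1, size=(20, 4)), columns=list("abcd"))
    zt = sc.transform(test)
    np.testing.assert_allclose(
        zt["a"].to_numpy(), (test["a"] - train["a"].mean()) / train["a"].std(ddof=0)
    )


def test_harmonization_drops_overlap_and_keeps_training_gene_order(small_cohort):
    from tepmced.cohort import generate_external_cohort

    ext = generate_external_cohort(small_cohort, n_samples=100, n_overlap=15, gene_subset_fraction=0.9, seed=4)
    train_genes = list(small_cohort.expression.columns[:40])
    overlap = sorted(set(ext.metadata["sample_id"]) & set(small_cohort.metadata["sample_id"]))
    expr, meta, missing = harmonize_external(train_genes, ext.expression, ext.metadata, None, overlap)
    assert len(meta) == 100 - 15
    assert not set(meta["sample_id"]) & set(overlap)
    shared = [g for g in train_genes if g in ext.expression.columns]
    assert list(expr.columns) == shared
    assert sorted(missing) == sorted(set(train_genes) - set(shared))
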