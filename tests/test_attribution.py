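import numpy as np
import pandas as pd
import pytest

from tepmced.attribution import (
    DEFAULT_K_GRID,
    AttributionSet,
    compute_attributions,
    dependence_data,
    filter_outliers,
    global_importance,
    local_explanation,
    select_background,
)
from tepmced.models import ModelConfig, tune_and_fit


def _attr(values, genes=None, ids=None, family="LR"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return AttributionSet(
        model_family=family,
        values=pd.DataFrame(values, index=ids, columns=genes),
        base_value=0.0,
        background_spec="test",
    )


@pytest.fixture(scope="module")
def lr_model(toy_xy):
    X, y = toy_xy
    genes = [f"f{i}" for i in range(X.shape[1])]
    cfg = ModelConfig(family="LR", n_search_iters=2, seed=0)
    Xdf = pd.DataFrame(X, columns=genes, index=[f"s{i}" for i in range(len(X))])
    return tune_and_fit(X, y, cfg, genes=genes), Xdf


def test_gaussian_column_accepts_the_first_k_whose_tail_mass_is_in_band():
    rng = np.random.default_rng(0)
    col = rng.standard_normal(1000)
    attr = _attr(col.reshape(-1, 1))
    filter_outliers(attr)
    report = attr.filter_reports[0]
    # oracle: direct counting of out-of-bounds points for each k on the grid
    q1, q3 = np.percentile(col, [25, 75])
    iqr = q3 - q1
    expected_k = None
    for k in DEFAULT_K_GRID:
        frac = np.mean((col < q1 - k * iqr) | (col > q3 + k * iqr))
        if 0.05 <= frac <= 0.10:
            expected_k = k
            break
    assert expected_k is not None
    assert report.method == "iqr"
    assert report.iqr_multiplier == pytest.approx(expected_k)
    assert 0.05 <= report.fraction_zeroed <= 0.10
    zeroed = attr.filtered_values.to_numpy().ravel() == 0
    lo, hi = report.bounds
    np.testing.assert_array_equal(zeroed, (col < lo) | (col > hi))


def test_band_miss_falls_back_to_percentile_zeroing():
    # uniform data: the IQR tail fraction jumps from far below 5% straight to
    # far above 10% as k shrinks, so no grid point lands in the band
    rng = np.random.default_rng(1)
    col = rng.random(1000)
    attr = _attr(col.reshape(-1, 1))
    filter_outliers(attr)
    report = attr.filter_reports[0]
    if report.method == "iqr":  # pragma: no cover - guard against a lucky draw
        pytest.skip("draw happened to land in the band")
    assert report.method == "percentile_fallback"
    lo, hi = np.percentile(col, [1, 99])
    expected = (col < lo) | (col > hi)
    zeroed = attr.filtered_values.to_numpy().ravel() == 0
    np.testing.assert_array_equal(zeroed, expected)


def test_constant_column_is_left_untouched():
    attr = _attr(np.full((50, 1), 3.14))
    filter_outliers(attr)
    assert attr.filter_reports[0].method == "none"
    np.testing.assert_array_equal(attr.filtered_values.to_numpy(), attr.values.to_numpy())


def test_filtering_rejects_non_finite_values():
    attr = _attr(np.array([[1.0], [np.nan]]))
    with pytest.raises(ValueError):
        filter_outliers(attr)


def test_global_importance_matches_hand_arithmetic_on_a_toy_table():
    table = np.array([
        [1.0, -2.0, 0.0],
        [3.0, 2.0, 0.0],
        [-1.0, -2.0, 0.0],
        [1.0, 2.0, 0.0],
    ])
    attr = _attr(table, genes=["a", "b", "c"])
    imp = global_importance(attr, use_filtered=False)
    assert imp["a"] == pytest.approx(6 / 4)
    assert imp["b"] == pytest.approx(8 / 4)
    assert imp["c"] == 0.0
    assert list(imp.index) == ["b", "a", "c"]  # descending, ties by gene id


def test_filtered_importance_differs_only_where_the_filter_acted():
    rng = np.random.default_rng(2)
    vals = rng.standard_normal((400, 6))
    vals[:5, 0] += 40  # heavy outliers in gene 0 only
    attr = _attr(vals)
    filter_outliers(attr)
    unfiltered = global_importance(attr, use_filtered=False)
    filtered = global_importance(attr, use_filtered=True)
    for rep in attr.filter_reports:
        if rep.fraction_zeroed == 0:
            assert filtered[rep.gene] == pytest.approx(unfiltered[rep.gene])
        else:
            assert filtered[rep.gene] < unfiltered[rep.gene]


def test_local_explanation_orders_by_magnitude_and_checks_sample():
    attr = _attr(np.array([[0.1, -5.0, 2.0, 0.0]]), genes=list("abcd"), ids=["s0"])
    top = local_explanation(attr, "s0", top_k=3)
    assert list(top.index) == ["b", "c", "a"]
    assert top["b"] == -5.0
    everything = local_explanation(attr, "s0", top_k=99)
    assert len(everything) == 4
    with pytest.raises(KeyError):
        local_explanation(attr, "nope")


def test_linear_model_attributions_are_additive_to_the_margin(lr_model):
    model, X = lr_model
    bg = X.iloc[:100]
    aset = compute_attributions(model, X.iloc[:20], bg)
    assert aset.additive_exact
    totals = aset.values.sum(axis=1).to_numpy() + aset.base_value
    np.testing.assert_allclose(totals, aset.model_outputs, atol=1e-8)
    # full-contribution sum reproduces the model score for each sample
    for sid in aset.sample_ids[:3]:
        contrib = local_explanation(aset, sid, top_k=len(aset.genes))
        i = aset.sample_ids.index(sid)
        assert contrib.sum() + aset.base_value == pytest.approx(aset.model_outputs[i], abs=1e-3)


def test_background_selection_uses_kmeans_only_for_the_kernel_family(toy_xy):
    X, _ = toy_xy
    Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    assert select_background(Xdf, "RF") is Xdf
    bg = select_background(Xdf, "SVM", seed=0)
    assert bg.shape == (50, X.shape[1])
    small = Xdf.iloc[:10]
    with pytest.warns(UserWarning):
        bg_small = select_background(small, "SVM")
    assert bg_small.shape[0] == 10
    with pytest.raises(ValueError):
        select_background(Xdf.iloc[:0], "RF")


def test_dependence_table_shape_and_drop_filtered_noop():
    rng = np.random.default_rng(3)
    n = 200
    expr = pd.DataFrame(
        rng.standard_normal((n, 3)), columns=["t", "m", "z"],
        index=[f"s{i}" for i in range(n)],
    )
    phi_t = expr["t"].to_numpy() * expr["m"].to_numpy()  # modulated by m
    vals = np.column_stack([phi_t, rng.standard_normal(n) * 0.01, rng.standard_normal(n) * 0.01])
    attr = _attr(vals, genes=["t", "m", "z"], ids=list(expr.index))
    table = dependence_data(attr, expr, "t", interaction="z")
    assert len(table) == n
    assert (table["interaction_gene"] == "z").all()
    # auto selection picks the gene that modulates the target's slope
    auto = dependence_data(attr, expr, "t", interaction="auto")
    assert auto["interaction_gene"].iloc[0] == "m"
    # no filtering applied -> drop_filtered changes nothing
    same = dependence_data(attr, expr, "t", interaction="z", drop_filtered=True)
    pd.testing.assert_frame_equal(table, same)
    with pytest.raises(KeyError):
        dependence_data(attr, expr, "nope")


def test_dependence_drop_filtered_removes_zeroed_rows():
    rng = np.random.default_rng(4)
    n = 400
    col = rng.standard_normal(n)
    expr = pd.DataFrame(
        {"t": col, "o": rng.standard_normal(n)}, index=[f"s{i}" for i in range(n)]
    )
    attr = _attr(np.column_stack([col, expr["o"]]), genes=["t", "o"], ids=list(expr.index))
    filter_outliers(attr)
    zeroed = (attr.filtered_values["t"].to_numpy() == 0) & (attr.values["t"].to_numpy() != 0)
    n_zeroed = int(zeroed.sum())
    table = dependence_data(attr, expr, "t", interaction="o", drop_filtered=True)
    assert len(table) == n - n_zeroed
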