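"""Per-model Shapley attribution, adaptive IQR outlier filtering, and
global/local/dependence exports.

The explainer backend is chosen by model family: exact interventional tree
attribution for DT/RF/XGB, closed-form linear attribution for LR,
sampling-based kernel attribution for SVM (with background and evaluated
samples capped at 50 by default), and integrated gradients for NN/DNN.
Attributions are always for the cancer-class output: probabilities for
DT/RF/NN/DNN/SVM, margin (log-odds) for XGB and LR.

Outlier filtering is adaptive per gene: the first IQR multiplier k (scanning
a descending grid) whose out-of-bounds fraction lies in [0.05, 0.10] wins
and those values are zeroed; if no k qualifies, values outside the 1st/99th
empirical percentiles are zeroed instead (fallback). Filtered values drive
global importance and the consensus; unfiltered values drive local
explanations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from tepmced import explainers
from tepmced.models import TrainedModel

DEFAULT_RATIO_BAND = (0.05, 0.10)
DEFAULT_K_GRID = tuple(np.arange(3.0, 0.5 - 1e-9, -0.25))  # 3.0 -> 0.5 step 0.25
DEFAULT_FALLBACK_PERCENTILES = (1.0, 99.0)
KERNEL_FAMILY = "SVM"
KERNEL_BACKGROUND_K = 50
KERNEL_SAMPLE_BUDGET = 50


@dataclass
class FilterReport:
    gene: str
    method: str  # {"iqr", "percentile_fallback", "none"}
    iqr_multiplier: float | None
    fraction_zeroed: float
    bounds: tuple[float, float] | None


@dataclass
class AttributionSet:
    """Per-model signed Shapley values for the cancer class."""

    model_family: str
    values: pd.DataFrame  # samples x genes, signed, unfiltered
    base_value: float
    background_spec: str
    model_outputs: np.ndarray | None = None  # per-sample output on the explained scale
    additive_exact: bool = True
    filtered_values: pd.DataFrame | None = None
    filter_reports: list[FilterReport] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]


def select_background(
    train_expr: pd.DataFrame,
    model_family: str,
    k: int = KERNEL_BACKGROUND_K,
    seed: int = 0,
) -> pd.DataFrame:
    """Background matrix: full training set, except k-means representatives
    (k = 50) for the kernel-based family."""
    if train_expr.shape[0] == 0:
        raise ValueError("empty training matrix")
    if model_family != KERNEL_FAMILY:
        return train_expr
    if train_expr.shape[0] < k:
        warnings.warn(
            f"training set smaller than {k}; using all {train_expr.shape[0]} rows as background",
            stacklevel=2,
        )
        return train_expr
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(train_expr.to_numpy(dtype=float))
    bg = pd.DataFrame(km.cluster_centers_, columns=train_expr.columns)
    return bg


def compute_attributions(
    model: TrainedModel,
    X: pd.DataFrame,
    background: pd.DataFrame,
    kernel_sample_budget: int = KERNEL_SAMPLE_BUDGET,
    kernel_coalitions: int = 2048,
    seed: int = 0,
) -> AttributionSet:
    """Cancer-class Shapley attributions for the samples in ``X``.

    ``X`` and ``background`` are on the expression scale of the model's
    genes; both are pushed through the pipeline's fitted scaler before the
    backend runs (Shapley values are invariant to this monotone per-feature
    reparameterization because only function values enter the game).
    """
    if model.genes and list(X.columns) != list(model.genes):
        if set(model.genes) - set(X.columns):
            raise ValueError("X columns do not match the model's training genes")
        X = X[model.genes]
        background = background[model.genes]
    pipe = model.pipeline
    scaler = pipe.scaler_
    if scaler is None:
        raise RuntimeError("model pipeline is not fitted")
    Xs = scaler.transform(X.to_numpy(dtype=float))
    Zs = scaler.transform(background.to_numpy(dtype=float))
    clf = pipe.classifier
    fam = model.family
    index = X.index
    additive = True
    outputs: np.ndarray

    if fam == "LR":
        beta = np.asarray(clf.coef_).ravel()
        phi, base = explainers.linear_shap(beta, float(clf.intercept_[0]), Xs, Zs)
        outputs = Xs @ beta + float(clf.intercept_[0])  # margin
        spec = f"full_train({Zs.shape[0]})"
    elif fam in ("DT", "RF"):
        exp = explainers.TreeEnsembleExplainer.from_sklearn(clf)
        phi, base = exp.shap_values(Xs, Zs)
        outputs = exp.evaluate(Xs)  # cancer-class probability
        spec = f"full_train({Zs.shape[0]})"
    elif fam == "XGB":
        exp = explainers.TreeEnsembleExplainer.from_xgboost(clf, Zs[0])
        phi, base = exp.shap_values(Xs, Zs)
        outputs = exp.evaluate(Xs)  # margin
        spec = f"full_train({Zs.shape[0]})"
    elif fam == KERNEL_FAMILY:
        if Xs.shape[0] > kernel_sample_budget:
            warnings.warn(
                f"kernel backend limited to {kernel_sample_budget} samples; truncating",
                stacklevel=2,
            )
            Xs = Xs[:kernel_sample_budget]
            index = index[:kernel_sample_budget]
        f = lambda a: clf.predict_proba(a)[:, 1]  # noqa: E731
        phi, base = explainers.kernel_shap(f, Xs, Zs, n_coalitions=kernel_coalitions, seed=seed)
        outputs = f(Xs)
        spec = f"k_representatives({Zs.shape[0]})"
    elif fam in ("NN", "DNN"):
        f = lambda a: clf.predict_proba(a)[:, 1]  # noqa: E731
        phi, base = explainers.integrated_gradients((f, clf.input_gradients), Xs, Zs, seed=seed)
        outputs = f(Xs)
        additive = False  # additive only up to discretization error
        spec = f"full_train({Zs.shape[0]})"
    else:
        raise ValueError(f"no attribution backend for family {fam!r}")

    return AttributionSet(
        model_family=fam,
        values=pd.DataFrame(phi, index=index, columns=X.columns),
        base_value=base,
        background_spec=spec,
        model_outputs=np.asarray(outputs, dtype=float),
        additive_exact=additive,
    )


def filter_outliers(
    attr: AttributionSet,
    ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND,
    k_grid: tuple[float, ...] = DEFAULT_K_GRID,
    fallback_percentiles: tuple[float, float] = DEFAULT_FALLBACK_PERCENTILES,
) -> AttributionSet:
    """Adaptive per-gene IQR filter with percentile fallback (see module doc)."""
    values = attr.values.to_numpy(dtype=float)
    if values.shape[0] == 0:
        raise ValueError("attribution set has no samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("attribution values must be finite")
    filtered = values.copy()
    reports: list[FilterReport] = []
    lo_band, hi_band = ratio_band
    n = values.shape[0]
    for j, gene in enumerate(attr.values.columns):
        col = values[:, j]
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            reports.append(FilterReport(str(gene), "none", None, 0.0, None))
            continue
        chosen = None
        for k in k_grid:
            lo, hi = q1 - k * iqr, q3 + k * iqr
            out = (col < lo) | (col > hi)
            frac = out.mean()
            if lo_band <= frac <= hi_band:
                chosen = (k, lo, hi, out, frac)
                break
        if chosen is not None:
            k, lo, hi, out, frac = chosen
            filtered[out, j] = 0.0
            reports.append(FilterReport(str(gene), "iqr", float(k), float(frac), (float(lo), float(hi))))
        else:
            lo, hi = np.percentile(col, list(fallback_percentiles))
            out = (col < lo) | (col > hi)
            filtered[out, j] = 0.0
            reports.append(
                FilterReport(str(gene), "percentile_fallback", None, float(out.mean()), (float(lo), float(hi)))
            )
    attr.filtered_values = pd.DataFrame(filtered, index=attr.values.index, columns=attr.values.columns)
    attr.filter_reports = reports
    return attr


def global_importance(attr: AttributionSet, use_filtered: bool = True) -> pd.Series:
    """Per-gene mean absolute attribution, descending, ties broken by gene id."""
    source = attr.filtered_values if (use_filtered and attr.filtered_values is not None) else attr.values
    imp = source.abs().mean(axis=0)
    order = sorted(imp.index, key=lambda g: (-imp[g], str(g)))
    return imp.loc[order]


def local_explanation(attr: AttributionSet, sample_id: str, top_k: int = 10) -> pd.Series:
    """Top-k signed contributions (unfiltered) for one sample, by |value| descending."""
    if sample_id not in attr.values.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    row = attr.values.loc[sample_id]
    order = sorted(row.index, key=lambda g: (-abs(row[g]), str(g)))
    return row.loc[order[: min(top_k, len(order))]]


def _interaction_score(target_expr, target_phi, candidate_expr) -> float:
    """Strength with which the candidate's expression modulates the
    target's attribution-vs-expression slope: |slope_low - slope_high|
    across a median split of the candidate."""
    med = np.median(candidate_expr)
    lo = candidate_expr <= med
    hi = ~lo
    score = 0.0
    slopes = []
    for mask in (lo, hi):
        if mask.sum() < 3 or np.std(target_expr[mask]) == 0:
            return 0.0
        slope = np.polyfit(target_expr[mask], target_phi[mask], 1)[0]
        slopes.append(slope)
    score = abs(slopes[0] - slopes[1])
    return float(score)


def dependence_data(
    attr: AttributionSet,
    expr: pd.DataFrame,
    gene: str,
    interaction: str = "auto",
    drop_filtered: bool = False,
) -> pd.DataFrame:
    """Per-sample (expression, attribution, interaction expression) triples.

    ``interaction="auto"`` selects the candidate gene with the strongest
    modulation of the target's attribution-vs-expression slope (median-split
    heuristic; ties broken by gene id). ``drop_filtered`` removes samples
    whose target attribution was zeroed by the outlier filter.
    """
    if gene not in attr.values.columns:
        raise KeyError(f"unknown gene {gene!r}")
    ids = attr.values.index
    x = expr.loc[ids, gene].to_numpy(dtype=float)
    phi = attr.values[gene].to_numpy(dtype=float)

    if interaction == "auto":
        best_gene, best_score = None, -1.0
        for cand in attr.values.columns:
            if cand == gene:
                continue
            s = _interaction_score(x, phi, expr.loc[ids, cand].to_numpy(dtype=float))
            if s > best_score + 1e-15 or (abs(s - best_score) <= 1e-15 and str(cand) < str(best_gene)):
                best_gene, best_score = cand, s
        interaction = best_gene
    elif interaction not in expr.columns:
        raise KeyError(f"unknown interaction gene {interaction!r}")

    table = pd.DataFrame(
        {
            "sample_id": [str(s) for s in ids],
            "expression": x,
            "attribution": phi,
            "interaction_gene": str(interaction),
            "interaction_expression": expr.loc[ids, interaction].to_numpy(dtype=float),
        }
    )
    if drop_filtered and attr.filtered_values is not None:
        zeroed = (attr.filtered_values[gene].to_numpy() == 0.0) & (phi != 0.0)
        table = table.loc[~zeroed]
    return table.reset_index(drop=True)
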