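"""Covariate-balanced train/test partition via constrained optimization.

The 80/20 split is posed as a continuous relaxation solved with SLSQP. The
objective ("divergence") is the sum over the categorical covariates (class
label, sex, cancer type, institution) of squared gaps between train-side
and test-side category proportions, plus the squared standardized
difference of age means; it is zero iff the two sides are balanced.

Because the categorical terms are constant within strata (the joint levels
of the categorical covariates), the relaxation is parameterized by one
test-count variable per stratum, bounded by the stratum size, with the
equality constraint that counts sum to the target test size; the age term
uses within-stratum mean ages. This is exact for the categorical terms and
reduces a cohort of thousands of samples to a few hundred variables. The
solution is rounded by largest remainder, samples are drawn within each
stratum at random (several seeded draws, keeping the best exact discrete
divergence), and the final partition is compared against label-stratified
random baselines — it is never worse than the best baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

CATEGORICAL_COVARIATES = ("label", "sex", "cancer_type", "institution")
AGE_COVARIATE = "age"


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    divergence: float
    balance_table: pd.DataFrame
    baseline_divergences: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    used_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "divergence": float(self.divergence),
            "balance_table": self.balance_table.to_dict(orient="records"),
            "baseline_divergence_median": (
                float(np.median(self.baseline_divergences)) if self.baseline_divergences.size else None
            ),
            "converged": self.converged,
            "used_fallback": self.used_fallback,
        }


def _design(metadata: pd.DataFrame) -> tuple[list[np.ndarray], np.ndarray, float]:
    """One-hot matrices per categorical covariate, age vector, age sd."""
    mats = []
    for cov in CATEGORICAL_COVARIATES:
        if cov not in metadata.columns:
            continue
        onehot = pd.get_dummies(metadata[cov].astype(str)).to_numpy(dtype=float)
        mats.append(onehot)
    age = metadata[AGE_COVARIATE].to_numpy(dtype=float) if AGE_COVARIATE in metadata.columns else None
    age_sd = float(np.std(age)) if age is not None else 1.0
    if age is None:
        age = np.zeros(len(metadata))
        age_sd = 1.0
    if age_sd == 0:
        age_sd = 1.0
    return mats, age, age_sd


def divergence(metadata: pd.DataFrame, assignment: np.ndarray) -> float:
    """Balance objective for a (possibly fractional) test-membership vector."""
    w = np.asarray(assignment, dtype=float)
    if np.any((w < -1e-12) | (w > 1 + 1e-12)):
        raise ValueError("assignment weights must lie in [0, 1]")
    s = w.sum()
    n = w.size
    if s <= 1e-12 or (n - s) <= 1e-12:
        raise ValueError("both sides of the split must be non-empty")
    mats, age, age_sd = _design(metadata)
    total = 0.0
    for x in mats:
        pt = x.T @ w / s
        pr = x.T @ (1.0 - w) / (n - s)
        total += float(((pt - pr) ** 2).sum())
    mt = age @ w / s
    mr = age @ (1.0 - w) / (n - s)
    total += float(((mt - mr) / age_sd) ** 2)
    return total


def _stratum_objective(
    c: np.ndarray,
    counts: np.ndarray,
    onehots: np.ndarray,
    ages: np.ndarray,
    age_sd: float,
    n_test: int,
    n: int,
) -> tuple[float, np.ndarray]:
    """Divergence (value, gradient) as a function of per-stratum test counts.

    ``onehots`` is (n_strata, K_total): stacked category indicators per
    stratum (exact aggregates, so the categorical terms equal the
    per-sample objective); ``ages`` holds within-stratum mean ages, exact
    for the mean-age gap whenever within-stratum draws hit the stratum mean
    in expectation.
    """
    s = float(n_test)
    r = float(n - n_test)
    pt = onehots.T @ c / s
    pr = onehots.T @ (counts - c) / r
    d = pt - pr
    total = float((d**2).sum())
    grad = 2.0 * onehots @ d * (1.0 / s + 1.0 / r)
    mt = ages @ c / s
    mr = ages @ (counts - c) / r
    d_age = (mt - mr) / age_sd
    total += float(d_age**2)
    grad += 2.0 * d_age / age_sd * ages * (1.0 / s + 1.0 / r)
    return total, grad


def _stratified_assignment(
    labels: np.ndarray, n_test: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary test-membership vector, label-stratified with exact total size."""
    n = labels.size
    w = np.zeros(n)
    uniq, counts = np.unique(labels, return_counts=True)
    quotas = counts * n_test / n
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n_test - int(base.sum())
    if short > 0:
        order = np.argsort(-rem, kind="stable")
        base[order[:short]] += 1
    for lab, k in zip(uniq, base):
        idx = np.flatnonzero(labels == lab)
        w[rng.choice(idx, size=min(k, idx.size), replace=False)] = 1.0
    # correct any residual mismatch from tiny strata
    diff = n_test - int(w.sum())
    if diff > 0:
        zeros = np.flatnonzero(w == 0)
        w[rng.choice(zeros, size=diff, replace=False)] = 1.0
    elif diff < 0:
        ones = np.flatnonzero(w == 1)
        w[rng.choice(ones, size=-diff, replace=False)] = 0.0
    return w


def optimize_split(
    metadata: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    n_baseline: int = 1000,
    test_n: int | None = None,
    maxiter: int = 60,
) -> SplitResult:
    """Covariate-balanced partition with exact test-set size.

    ``test_n`` overrides the default round-half-even of
    ``test_fraction * n``. The returned split is the better (lower discrete
    divergence) of the rounded SLSQP solution and the best of ``n_baseline``
    label-stratified random splits, so it is never worse than random search.
    """
    n = len(metadata)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_test = int(np.rint(test_fraction * n)) if test_n is None else int(test_n)
    if n_test < 2 or n - n_test < 2:
        raise ValueError(f"test size {n_test} leaves a degenerate side")

    rng = np.random.default_rng(seed)
    mats, age, age_sd = _design(metadata)
    labels = metadata["label"].astype(str).to_numpy()
    ids = metadata["sample_id"].astype(str).to_numpy()

    # label-stratified random baselines (vectorized objective)
    baselines = np.empty(max(n_baseline, 1))
    baseline_ws = []
    for b in range(max(n_baseline, 1)):
        wb = _stratified_assignment(labels, n_test, rng)
        baseline_ws.append(wb)
    wmat = np.asarray(baseline_ws).T  # n x R
    s = float(n_test)
    baselines = np.zeros(wmat.shape[1])
    for x in mats:
        pt = x.T @ wmat / s
        pr = x.T @ (1.0 - wmat) / (n - s)
        baselines += ((pt - pr) ** 2).sum(axis=0)
    mt = age @ wmat / s
    mr = age @ (1.0 - wmat) / (n - s)
    baselines += ((mt - mr) / age_sd) ** 2

    # stratum aggregation over the joint categorical levels
    covs = [c for c in CATEGORICAL_COVARIATES if c in metadata.columns]
    key = metadata[covs].astype(str).agg("|".join, axis=1).to_numpy() if covs else np.zeros(n, dtype=str)
    strata, stratum_of = np.unique(key, return_inverse=True)
    n_strata = strata.size
    counts = np.bincount(stratum_of, minlength=n_strata).astype(float)
    # H[s, k] = 1 iff stratum s carries category k (category blocks stacked)
    blocks = []
    for cov in covs:
        cats = pd.factorize(metadata[cov].astype(str), sort=True)[0]
        k_cov = cats.max() + 1
        h = np.zeros((n_strata, k_cov))
        h[stratum_of, cats] = 1.0
        blocks.append(h)
    onehots = np.hstack(blocks) if blocks else np.zeros((n_strata, 0))
    age_means = np.bincount(stratum_of, weights=age, minlength=n_strata) / counts

    c0 = counts * n_test / n
    res = minimize(
        lambda c: _stratum_objective(c, counts, onehots, age_means, age_sd, n_test, n),
        c0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, counts[s]) for s in range(n_strata)],
        constraints=[
            {"type": "eq", "fun": lambda c: c.sum() - n_test, "jac": lambda c: np.ones(n_strata)}
        ],
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("SLSQP did not converge (%s); falling back to best random baseline", res.message)

    # round per-stratum counts by largest remainder, then draw samples within
    # each stratum (several seeded draws; keep the best discrete divergence)
    c_frac = np.clip(res.x, 0.0, counts)
    c_int = np.floor(c_frac).astype(int)
    short = n_test - int(c_int.sum())
    if short > 0:
        room = (counts - c_int) > 0
        rem = np.where(room, c_frac - np.floor(c_frac), -1.0)
        for s in np.argsort(-rem, kind="stable")[:short]:
            c_int[s] += 1
    elif short < 0:
        rem = np.where(c_int > 0, c_frac - np.floor(c_frac), 2.0)
        for s in np.argsort(rem, kind="stable")[: -short]:
            c_int[s] -= 1

    div_opt, w_opt = np.inf, None
    for _draw in range(8):
        w = np.zeros(n)
        for s in range(n_strata):
            if c_int[s] == 0:
                continue
            idx = np.flatnonzero(stratum_of == s)
            w[rng.choice(idx, size=c_int[s], replace=False)] = 1.0
        d = divergence(metadata, w)
        if d < div_opt:
            div_opt, w_opt = d, w

    best_b = int(np.argmin(baselines))
    used_fallback = False
    if not converged or w_opt is None or div_opt > baselines[best_b]:
        w_final, div_final = baseline_ws[best_b], float(baselines[best_b])
        used_fallback = True
    else:
        w_final, div_final = w_opt, div_opt

    test_mask = w_final == 1.0
    result = SplitResult(
        train_ids=list(ids[~test_mask]),
        test_ids=list(ids[test_mask]),
        divergence=float(div_final),
        balance_table=balance_table(metadata, test_mask),
        baseline_divergences=baselines,
        converged=converged,
        used_fallback=used_fallback,
    )
    return result


def balance_table(metadata: pd.DataFrame, test_mask: np.ndarray) -> pd.DataFrame:
    """Per-covariate train vs test summary (proportions; mean/sd for age)."""
    rows = []
    tr = metadata.loc[~test_mask]
    te = metadata.loc[test_mask]
    for cov in CATEGORICAL_COVARIATES:
        if cov not in metadata.columns:
            continue
        cats = sorted(metadata[cov].astype(str).unique())
        for c in cats:
            rows.append(
                {
                    "covariate": cov,
                    "category": c,
                    "train": float((tr[cov].astype(str) == c).mean()),
                    "test": float((te[cov].astype(str) == c).mean()),
                }
            )
    if AGE_COVARIATE in metadata.columns:
        rows.append(
            {
                "covariate": "age_mean",
                "category": "",
                "train": float(tr[AGE_COVARIATE].mean()),
                "test": float(te[AGE_COVARIATE].mean()),
            }
        )
        rows.append(
            {
                "covariate": "age_sd",
                "category": "",
                "train": float(tr[AGE_COVARIATE].std()),
                "test": float(te[AGE_COVARIATE].std()),
            }
        )
    return pd.DataFrame(rows)
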