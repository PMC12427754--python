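"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: Shapley values by
subset enumeration, ANOVA/BH by direct formula evaluation, greedy pruning
by a literal scan, Youden's J by exhaustive threshold search, AUC by pair
counting, and Spearman rho by the textbook formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_shap(f, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact interventional Shapley values by enumeration over coalitions."""
    x = np.asarray(x, dtype=float)
    Z = np.asarray(background, dtype=float)
    p = x.size
    values = {}

    def v(S: frozenset) -> float:
        if S not in values:
            comp = Z.copy()
            idx = sorted(S)
            comp[:, idx] = x[idx]
            values[S] = float(np.mean(f(comp)))
        return values[S]

    phi = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for r in range(p):
            w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for S in itertools.combinations(others, r):
                S = frozenset(S)
                phi[i] += w * (v(S | {i}) - v(S))
    return phi


def anova_f_and_p(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for a single gene by the direct formula."""
    from scipy.stats import f as fdist

    uniq = np.unique(groups)
    n = values.size
    grand = values.mean()
    ssb = sum(
        (values[groups == g].size) * (values[groups == g].mean() - grand) ** 2 for g in uniq
    )
    ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in uniq)
    dfb, dfw = uniq.size - 1, n - uniq.size
    F = (ssb / dfb) / (ssw / dfw)
    return F, float(fdist.sf(F, dfb, dfw))


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, literal step-up."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def greedy_prune(corr: np.ndarray, threshold: float) -> list[int]:
    """Greedy correlation pruning over an explicit correlation matrix."""
    kept: list[int] = []
    for j in range(corr.shape[0]):
        if all(abs(corr[j, k]) <= threshold for k in kept):
            kept.append(j)
    return kept


def best_youden(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(max J, smallest achieving threshold) by exhaustive midpoint scan."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1e-6], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1e-6]])
    n1, n0 = labels.sum(), labels.size - labels.sum()
    best = (-np.inf, None)
    for t in cands:
        pred = scores >= t
        j = pred[labels == 1].mean() + (~pred[labels == 0]).mean() - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def spearman_no_ties(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook rank-correlation formula 1 - 6*sum(d^2)/(n(n^2-1))."""
    ra = np.argsort(np.argsort(a))
    rb = np.argsort(np.argsort(b))
    n = len(a)
    d2 = ((ra - rb) ** 2).sum()
    return 1 - 6 * d2 / (n * (n**2 - 1))
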