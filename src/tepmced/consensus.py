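"""AUC-weighted cross-model consensus gene ranking and agreement analysis.

Per model, the per-gene mean-absolute-attribution vector is min-max scaled
to [0, 1] (genes as the axis); the consensus score of a gene is the sum over
non-excluded models of (model test AUC) x (scaled importance). The decision
tree family is excluded from aggregation by default (its attributions are
inconsistent with the other families) but still appears in the agreement
matrix. Model agreement is pairwise Spearman rank correlation restricted to
genes with nonzero importance in both models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

DEFAULT_EXCLUDE = ("DT",)
MIN_SHARED_GENES = 3


@dataclass
class ConsensusRanking:
    per_model_scaled: pd.DataFrame  # genes x models, each column in [0, 1]
    model_weights: dict[str, float]
    scores: pd.Series  # gene -> weighted consensus score, descending
    excluded_models: list[str]
    top_k: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_model_scaled.copy()
        out["consensus"] = self.scores.reindex(out.index)
        return out.sort_values("consensus", ascending=False)


@dataclass
class AgreementMatrix:
    rho: pd.DataFrame  # models x models Spearman rho
    shared_counts: pd.DataFrame  # models x models shared-gene counts

    def validate(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        if not np.allclose(r, r.T, equal_nan=True):
            raise ValueError("agreement matrix must be symmetric")


def _minmax(v: pd.Series) -> pd.Series:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return pd.Series(np.zeros(v.size), index=v.index)
    return (v - lo) / (hi - lo)


def weighted_consensus(
    importances: dict[str, pd.Series],
    aucs: dict[str, float],
    exclude: tuple[str, ...] | list[str] = DEFAULT_EXCLUDE,
    top_k: int = 15,
) -> ConsensusRanking:
    """AUC-weighted consensus over per-model importance vectors.

    Gene sets are unified (missing genes take importance 0); each included
    model's vector is min-max scaled, multiplied by its AUC weight and
    summed. The ranking descends by score with ties broken by gene id.
    """
    included = [m for m in importances if m not in set(exclude)]
    if not included:
        raise ValueError("all models excluded from the consensus")
    genes = sorted(set().union(*[set(importances[m].index) for m in importances]))

    scaled = {}
    for m in importances:
        v = importances[m].reindex(genes).fillna(0.0)
        scaled[m] = _minmax(v)
    scaled_df = pd.DataFrame(scaled, index=genes)

    scores = pd.Series(np.zeros(len(genes)), index=genes)
    weights = {}
    for m in included:
        w = float(aucs[m])
        weights[m] = w
        scores = scores + w * scaled_df[m]

    order = sorted(genes, key=lambda g: (-scores[g], str(g)))
    scores = scores.loc[order]
    ranking = ConsensusRanking(
        per_model_scaled=scaled_df,
        model_weights=weights,
        scores=scores,
        excluded_models=[m for m in importances if m in set(exclude)],
        top_k=order[: min(top_k, len(order))],
    )
    return ranking


def agreement_matrix(importances: dict[str, pd.Series]) -> AgreementMatrix:
    """Pairwise Spearman rho on genes with nonzero importance in both models.

    Pairs sharing fewer than 3 genes are undefined (NaN). Ties receive
    average ranks (standard Spearman). The diagonal is 1 by definition.
    """
    models = list(importances)
    if len(models) < 2:
        raise ValueError("need at least two models for an agreement matrix")
    rho = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    counts = pd.DataFrame(0, index=models, columns=models, dtype=int)
    for i, a in enumerate(models):
        counts.loc[a, a] = int((importances[a] != 0).sum())
        for b in models[i + 1:]:
            va, vb = importances[a], importances[b]
            shared = sorted(set(va.index[va != 0]) & set(vb.index[vb != 0]))
            counts.loc[a, b] = counts.loc[b, a] = len(shared)
            if len(shared) < MIN_SHARED_GENES:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            r = spearmanr(va.loc[shared].to_numpy(), vb.loc[shared].to_numpy()).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    out = AgreementMatrix(rho=rho, shared_counts=counts)
    out.validate()
    return out


def topk_overlap(ranking_a: ConsensusRanking, ranking_b: ConsensusRanking, k: int = 15) -> int:
    """Size of the intersection of the two top-k gene lists."""
    if not len(ranking_a.scores) or not len(ranking_b.scores):
        raise ValueError("rankings must be non-empty")
    import warnings

    if k > len(ranking_a.scores) or k > len(ranking_b.scores):
        warnings.warn("k exceeds ranking length; using the full ranking", stacklevel=2)
    ta = list(ranking_a.scores.index[:k])
    tb = list(ranking_b.scores.index[:k])
    return len(set(ta) & set(tb))
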