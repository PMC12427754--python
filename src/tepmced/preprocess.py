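"""Cohort curation, three-stage feature selection, and external harmonization.

Curation removes flagged (symptomatic) controls and samples with missing
labels. Feature selection then proceeds in three leak-aware stages:

1. one-way ANOVA across the class groups on a stratified discovery subset
   (default 33% of samples), Benjamini-Hochberg adjusted, q < 0.001, capped
   at the 300 genes with smallest q;
2. greedy Pearson-correlation pruning at |r| > 0.8, scanning genes in
   ascending-q priority order so the statistically stronger member of a
   correlated pair is kept;
3. per-fold z-score standardization, with statistics fitted strictly on the
   training rows of the current fold.

An external cohort is harmonized by dropping overlapping sample ids,
restricting to the gene intersection (training-gene order), and applying the
training-fitted scaler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from a metadata table."""


@dataclass
class FeatureSelectionReport:
    """Record of the statistical-filtering and correlation-pruning stages."""

    discovery_sample_ids: list[str] = field(default_factory=list)
    anova_pass: pd.DataFrame | None = None  # columns: gene, F, q
    capped: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "discovery_sample_ids": list(self.discovery_sample_ids),
            "anova_pass": (
                self.anova_pass.to_dict(orient="records") if self.anova_pass is not None else None
            ),
            "capped": list(self.capped),
            "retained": list(self.retained),
            "dropped_pairs": [
                {"kept": k, "dropped": d, "r": float(r)} for k, d, r in self.dropped_pairs
            ],
        }


def exclude_flagged(metadata: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged samples and samples with a missing label; order preserved."""
    if "flagged" not in metadata.columns:
        raise SchemaError("metadata lacks a 'flagged' column")
    keep = (metadata["flagged"].astype(bool) == False) & metadata["label"].notna()  # noqa: E712
    return metadata.loc[keep].copy()


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _anova_f(values: np.ndarray, group_codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA F and p per column of ``values``.

    Columns with zero within+between variance get F = nan (handled by caller).
    """
    n, p = values.shape
    grand = values.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for g in range(n_groups):
        mask = group_codes == g
        ng = int(mask.sum())
        if ng == 0:
            continue
        mg = values[mask].mean(axis=0)
        ss_between += ng * (mg - grand) ** 2
        ss_within += ((values[mask] - mg) ** 2).sum(axis=0)
    df_b = n_groups - 1
    df_w = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    pvals = stats.f.sf(f, df_b, df_w)
    return f, pvals


def anova_select(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    discovery_fraction: float = 0.33,
    fdr: float = 0.001,
    cap: int = 300,
    seed: int = 0,
    group_col: str = "label",
) -> FeatureSelectionReport:
    """Stage-1 statistical filtering on a stratified discovery subset.

    Per-gene one-way ANOVA across the groups of ``group_col``, BH-adjusted;
    genes with q < ``fdr`` are retained, and if more than ``cap`` pass, the
    ``cap`` genes with smallest q are kept (ties broken toward larger F).
    Constant genes have an undefined F and are assigned q = 1.
    """
    meta = metadata.set_index("sample_id").loc[expr.index]
    groups = meta[group_col].astype(str)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups for ANOVA feature selection")
    if discovery_fraction < 1.0:
        disc_ids, _ = train_test_split(
            expr.index.to_numpy(),
            train_size=discovery_fraction,
            stratify=groups.to_numpy(),
            random_state=seed,
        )
    else:
        disc_ids = expr.index.to_numpy()
    disc_ids = list(disc_ids)
    sub = expr.loc[disc_ids]
    sub_groups = groups.loc[disc_ids]
    if sub_groups.nunique() < 2:
        raise ValueError("discovery subset contains a single group")
    codes, uniques = pd.factorize(sub_groups, sort=True)

    f, pvals = _anova_f(sub.to_numpy(dtype=float), codes, len(uniques))
    undefined = ~np.isfinite(f)
    f = np.where(undefined, 0.0, f)
    pvals = np.where(undefined, 1.0, pvals)
    q = bh_adjust(pvals)
    q[undefined] = 1.0

    table = pd.DataFrame({"gene": expr.columns, "F": f, "q": q})
    passed = table[table["q"] < fdr].copy()
    # smallest q first; ties broken toward larger F
    passed = passed.sort_values(["q", "F"], ascending=[True, False], kind="stable")
    capped = passed.head(cap)

    report = FeatureSelectionReport(
        discovery_sample_ids=[str(s) for s in disc_ids],
        anova_pass=passed.reset_index(drop=True),
        capped=list(capped["gene"]),
    )
    return report


def correlation_prune(
    expr: pd.DataFrame,
    genes: list[str],
    r_threshold: float = 0.8,
) -> FeatureSelectionReport:
    """Stage-2 greedy correlation pruning in priority order.

    Scanning ``genes`` in the given order, a gene is dropped iff its absolute
    Pearson correlation with any already-retained gene exceeds
    ``r_threshold``. Zero-variance genes have undefined correlation, treated
    as r = 0 (never pruned for correlation) and logged.
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    x = expr[genes].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "correlation undefined for %d zero-variance genes; treating r=0",
            int(zero_var.sum()),
        )
    xc = x - x.mean(axis=0)
    denom = np.where(sd == 0, 1.0, sd * np.sqrt(x.shape[0]))
    xn = xc / denom  # unit-norm columns (zero for constant genes)

    retained_idx: list[int] = []
    dropped_pairs: list[tuple[str, str, float]] = []
    for j in range(len(genes)):
        if retained_idx:
            r = xn[:, retained_idx].T @ xn[:, j]
            hits = np.abs(r) > r_threshold
            if hits.any():
                k = retained_idx[int(np.argmax(np.abs(r)))]
                dropped_pairs.append((genes[k], genes[j], float(r[int(np.argmax(np.abs(r)))])))
                continue
        retained_idx.append(j)

    report = FeatureSelectionReport(
        retained=[genes[j] for j in retained_idx],
        dropped_pairs=dropped_pairs,
    )
    return report


def select_features(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    discovery_fraction: float = 0.33,
    fdr: float = 0.001,
    cap: int = 300,
    r_threshold: float = 0.8,
    seed: int = 0,
) -> FeatureSelectionReport:
    """Full stage-1 + stage-2 selection; retained genes ordered by priority (ascending q)."""
    report = anova_select(expr, metadata, discovery_fraction, fdr, cap, seed)
    pruned = correlation_prune(expr.loc[report.discovery_sample_ids], report.capped, r_threshold)
    report.retained = pruned.retained
    report.dropped_pairs = pruned.dropped_pairs
    return report


class Scaler:
    """Per-gene z-score scaler fitted on fold-training rows only.

    Constant genes (sd = 0) map to 0.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.genes_: list[str] | None = None

    def fit(self, expr_train: pd.DataFrame) -> "Scaler":
        x = expr_train.to_numpy(dtype=float)
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0, ddof=0)
        self.genes_ = list(expr_train.columns)
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Scaler not fitted")
        if list(expr.columns) != self.genes_:
            expr = expr[self.genes_]
        x = expr.to_numpy(dtype=float)
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        z = (x - self.mean_) / sd
        z[:, self.sd_ == 0] = 0.0
        return pd.DataFrame(z, index=expr.index, columns=expr.columns)

    def fit_transform(self, expr_train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(expr_train).transform(expr_train)


def fit_scaler(expr_train: pd.DataFrame) -> Scaler:
    return Scaler().fit(expr_train)


def apply_scaler(params: Scaler, expr: pd.DataFrame) -> pd.DataFrame:
    return params.transform(expr)


def harmonize_external(
    train_genes: list[str],
    external_expr: pd.DataFrame,
    external_meta: pd.DataFrame,
    scaler: Scaler | None,
    overlap_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Harmonize an external cohort against the trained pipeline.

    Removes overlapping sample ids, restricts columns to the train/external
    gene intersection (in training order), and applies the training-fitted
    scaling. Returns (expression, metadata, missing_genes).
    """
    shared = [g for g in train_genes if g in external_expr.columns]
    missing = [g for g in train_genes if g not in external_expr.columns]
    if not shared:
        raise ValueError("no genes shared between training and external cohorts")
    if missing:
        warnings.warn(f"{len(missing)} training genes absent from external cohort", stacklevel=2)

    drop = set(map(str, overlap_ids))
    keep_mask = ~external_meta["sample_id"].astype(str).isin(drop)
    meta = external_meta.loc[keep_mask].copy()
    expr = external_expr.loc[meta["sample_id"].to_numpy(), shared]

    if scaler is not None:
        if scaler.genes_ is not None and list(scaler.genes_) != shared:
            sub = Scaler()
            idx = [scaler.genes_.index(g) for g in shared]
            sub.mean_ = scaler.mean_[idx]
            sub.sd_ = scaler.sd_[idx]
            sub.genes_ = shared
            expr = sub.transform(expr)
        else:
            expr = scaler.transform(expr)
    return expr, meta, missing
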