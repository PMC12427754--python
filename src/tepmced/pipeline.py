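"""End-to-end orchestration: curation -> feature selection -> balanced split
-> model zoo -> attribution -> consensus.

This is the one-call surface the analysis drivers and the reproduction
script use; each stage simply delegates to the corresponding module, so
every number it produces is recomputed from the inputs at call time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tepmced import attribution as attr_mod
from tepmced import consensus as cons_mod
from tepmced.cohort import SyntheticCohort
from tepmced.metrics import ConfusionMatrix, MetricsReport, classification_metrics
from tepmced.models import ModelConfig, TrainedModel, tune_and_fit
from tepmced.preprocess import exclude_flagged, select_features
from tepmced.split import SplitResult, optimize_split

DEFAULT_FAMILIES = ("NN", "DNN", "XGB", "SVM", "RF", "LR", "DT")


@dataclass
class PipelineResult:
    retained_meta: pd.DataFrame
    feature_report: object
    split: SplitResult
    models: dict[str, TrainedModel]
    metrics: dict[str, MetricsReport]
    attributions: dict[str, attr_mod.AttributionSet]
    importances: dict[str, pd.Series]
    consensus: cons_mod.ConsensusRanking | None
    genes: list[str] = field(default_factory=list)

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for fam, rep in self.metrics.items():
            rows.append({"model": fam, **rep.to_dict()})
        return pd.DataFrame(rows)


def prepare(
    cohort: SyntheticCohort,
    discovery_fraction: float = 0.33,
    fdr: float = 0.001,
    cap: int = 300,
    r_threshold: float = 0.8,
    test_fraction: float = 0.2,
    test_n: int | None = None,
    n_baseline: int = 200,
    seed: int = 0,
):
    """Curation, feature selection and the balanced split. Returns
    (retained metadata, feature report, split result)."""
    meta = exclude_flagged(cohort.metadata)
    expr = cohort.expression.loc[meta["sample_id"].to_numpy()]
    report = select_features(
        expr, meta, discovery_fraction=discovery_fraction, fdr=fdr, cap=cap,
        r_threshold=r_threshold, seed=seed,
    )
    split = optimize_split(
        meta, test_fraction=test_fraction, seed=seed, n_baseline=n_baseline, test_n=test_n
    )
    return meta, report, split


def run_pipeline(
    cohort: SyntheticCohort,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    n_search_iters: dict[str, int] | int | None = None,
    seed: int = 42,
    split_seed: int = 0,
    n_baseline: int = 200,
    test_n: int | None = None,
    discovery_fraction: float = 0.33,
    fdr: float = 0.001,
    cap: int = 300,
    r_threshold: float = 0.8,
    attribution_samples: int | None = None,
    kernel_coalitions: int = 1024,
    consensus_top_k: int = 15,
    exclude_from_consensus: tuple[str, ...] = cons_mod.DEFAULT_EXCLUDE,
) -> PipelineResult:
    """Full analysis on one cohort.

    ``attribution_samples`` caps the number of test samples explained for
    the non-kernel backends (the kernel family keeps its own 50-sample
    budget); ``None`` explains the whole test set.
    """
    meta, report, split = prepare(
        cohort,
        discovery_fraction=discovery_fraction,
        fdr=fdr,
        cap=cap,
        r_threshold=r_threshold,
        test_n=test_n,
        n_baseline=n_baseline,
        seed=split_seed,
    )
    genes = report.retained
    if not genes:
        raise RuntimeError("feature selection retained no genes")
    expr = cohort.expression.loc[meta["sample_id"].to_numpy(), genes]
    meta_idx = meta.set_index("sample_id")
    y_all = (meta_idx["label"] == "cancer").astype(int)

    X_train = expr.loc[split.train_ids]
    y_train = y_all.loc[split.train_ids].to_numpy()
    X_test = expr.loc[split.test_ids]
    y_test = y_all.loc[split.test_ids].to_numpy()
    meta_test = meta_idx.loc[split.test_ids].reset_index()

    models: dict[str, TrainedModel] = {}
    metrics: dict[str, MetricsReport] = {}
    attributions: dict[str, attr_mod.AttributionSet] = {}
    importances: dict[str, pd.Series] = {}

    for fam in families:
        cfg = ModelConfig(family=fam, seed=seed)
        if isinstance(n_search_iters, int):
            cfg.n_search_iters = n_search_iters
        elif isinstance(n_search_iters, dict) and fam in n_search_iters:
            cfg.n_search_iters = n_search_iters[fam]
        model = tune_and_fit(X_train.to_numpy(), y_train, cfg, genes=genes)
        models[fam] = model

        scores = model.predict_scores(X_test.to_numpy())
        preds = (scores >= model.threshold).astype(int)
        cm = ConfusionMatrix.from_predictions(y_test, preds)
        rep = classification_metrics(cm, scores=scores, labels=y_test)
        from tepmced.metrics import stratified_accuracy

        rep.per_stage = stratified_accuracy(preds, meta_test, "stage")
        rep.per_type = stratified_accuracy(preds, meta_test, "cancer_type")
        metrics[fam] = rep

        background = attr_mod.select_background(X_train, fam, seed=seed)
        X_explain = X_test
        if attribution_samples is not None and fam != attr_mod.KERNEL_FAMILY:
            X_explain = X_test.iloc[: min(attribution_samples, X_test.shape[0])]
        aset = attr_mod.compute_attributions(
            model, X_explain, background, kernel_coalitions=kernel_coalitions, seed=seed
        )
        aset = attr_mod.filter_outliers(aset)
        attributions[fam] = aset
        importances[fam] = attr_mod.global_importance(aset, use_filtered=True)

    consensus = None
    if len([f for f in families if f not in set(exclude_from_consensus)]) >= 1:
        aucs = {f: metrics[f].auc for f in families}
        consensus = cons_mod.weighted_consensus(
            importances, aucs, exclude=exclude_from_consensus, top_k=consensus_top_k
        )

    return PipelineResult(
        retained_meta=meta,
        feature_report=report,
        split=split,
        models=models,
        metrics=metrics,
        attributions=attributions,
        importances=importances,
        consensus=consensus,
        genes=genes,
    )


def explain_external(
    result: PipelineResult,
    external_expr: pd.DataFrame,
    external_meta: pd.DataFrame,
    families: tuple[str, ...] | None = None,
    attribution_samples: int | None = None,
    kernel_coalitions: int = 1024,
    consensus_top_k: int = 15,
    exclude_from_consensus: tuple[str, ...] = cons_mod.DEFAULT_EXCLUDE,
    seed: int = 42,
) -> tuple[dict[str, MetricsReport], cons_mod.ConsensusRanking]:
    """Apply trained models to a harmonized external cohort and build its
    consensus ranking (the cross-cohort reproducibility check).

    ``external_expr`` must already be restricted to the training genes (see
    :func:`tepmced.preprocess.harmonize_external` with ``scaler=None`` —
    the per-model pipeline applies its own fitted scaling).
    """
    families = families or tuple(result.models)
    y_ext = (external_meta["label"] == "cancer").astype(int).to_numpy()
    metrics: dict[str, MetricsReport] = {}
    importances: dict[str, pd.Series] = {}
    for fam in families:
        model = result.models[fam]
        X = external_expr.copy()
        absent = [g for g in model.genes if g not in X.columns]
        if absent:
            # training genes missing externally: impute at the training mean
            # (scaled value 0), keeping the model's input space intact
            means = model.pipeline.scaler_.mean_
            for g in absent:
                X[g] = float(means[model.genes.index(g)])
        X = X[model.genes]
        scores = model.predict_scores(X.to_numpy())
        preds = (scores >= model.threshold).astype(int)
        cm = ConfusionMatrix.from_predictions(y_ext, preds)
        metrics[fam] = classification_metrics(cm, scores=scores, labels=y_ext)

        background = attr_mod.select_background(
            X if fam != attr_mod.KERNEL_FAMILY else X, fam, seed=seed
        )
        X_explain = X
        if attribution_samples is not None and fam != attr_mod.KERNEL_FAMILY:
            X_explain = X.iloc[: min(attribution_samples, X.shape[0])]
        aset = attr_mod.compute_attributions(
            model, X_explain, background, kernel_coalitions=kernel_coalitions, seed=seed
        )
        aset = attr_mod.filter_outliers(aset)
        importances[fam] = attr_mod.global_importance(aset, use_filtered=True)
    aucs = {f: metrics[f].auc for f in families}
    consensus = cons_mod.weighted_consensus(
        importances, aucs, exclude=exclude_from_consensus, top_k=consensus_top_k
    )
    return metrics, consensus
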