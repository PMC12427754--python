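#!/usr/bin/env python
"""AUC-weighted consensus ranking, model agreement, and external validation.

Reads the importance table, model metrics and the external cohort; writes
results/consensus_ranking.csv, results/agreement_matrix.csv and
results/external_validation.csv.
"""

import argparse
import pickle

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs

from tepmced.cohort import read_cohort
from tepmced.consensus import agreement_matrix, topk_overlap, weighted_consensus
from tepmced.pipeline import PipelineResult, explain_external
from tepmced.preprocess import harmonize_external
from tepmced.split import SplitResult


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--top-k", type=int, default=15)
    args = ap.parse_args()
    ensure_dirs()

    importances = pd.read_csv(RESULTS / "global_importance.csv", index_col=0)
    metrics = pd.read_csv(RESULTS / "model_metrics.csv").set_index("model")
    aucs = metrics["auc"].to_dict()
    imp = {m: importances[m].dropna() for m in importances.columns}

    consensus = weighted_consensus(imp, aucs, top_k=args.top_k)
    consensus.to_frame().round(4).to_csv(RESULTS / "consensus_ranking.csv")

    agreement = agreement_matrix(imp)
    agreement.rho.round(3).to_csv(RESULTS / "agreement_matrix.csv")

    cohort = read_cohort(SCRATCH / "cohort")
    planted = cohort.informative_genes
    top = consensus.top_k
    print(f"consensus top-{args.top_k}: {sum(g in planted for g in top)}/{len(top)} planted")
    print("top genes:", ", ".join(top))

    # external validation: apply the trained models to the external cohort
    with open(SCRATCH / "models.pkl", "rb") as fh:
        bundle = pickle.load(fh)
    external = read_cohort(SCRATCH / "external")
    overlap = sorted(set(external.metadata["sample_id"]) & set(cohort.metadata["sample_id"]))
    expr, meta, missing = harmonize_external(
        bundle["genes"], external.expression, external.metadata, None, overlap
    )
    result = PipelineResult(
        retained_meta=None, feature_report=None,
        split=SplitResult([], [], 0.0, pd.DataFrame()),
        models=bundle["models"], metrics={}, attributions={}, importances={},
        consensus=consensus, genes=bundle["genes"],
    )
    ext_metrics, ext_consensus = explain_external(result, expr, meta, seed=args.seed)
    rows = [{"model": fam, **rep.to_dict()} for fam, rep in ext_metrics.items()]
    table = pd.DataFrame(rows).drop(columns=["undefined"])
    overlap_n = topk_overlap(consensus, ext_consensus, k=args.top_k)
    table.to_csv(RESULTS / "external_validation.csv", index=False)
    print(f"external cohort: {len(meta)} samples after dedup "
          f"({len(overlap)} overlapping removed, {len(missing)} training genes imputed)")
    print(f"external top-{args.top_k} overlap with primary consensus: {overlap_n}/{args.top_k}")


if __name__ == "__main__":
    main()
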