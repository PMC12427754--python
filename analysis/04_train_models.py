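#!/usr/bin/env python
"""Tune and train the seven classifier families on the balanced split.

Reads scratch/cohort, scratch/curated and scratch/split.json plus the
selected genes from results/selected_genes.csv. Writes fitted models to
scratch/models.pkl and the per-model test metrics to
results/model_metrics.csv.
"""

import argparse
import json
import pickle

import numpy as np
import pandas as pd

from common import DEFAULT_SEED, RESULTS, SCRATCH, ensure_dirs

from tepmced.cohort import read_cohort
from tepmced.metrics import ConfusionMatrix, classification_metrics, stratified_accuracy
from tepmced.models import FAMILIES, ModelConfig, tune_and_fit


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--search-iters", type=int, default=None,
                    help="override the per-family randomized-search budget")
    args = ap.parse_args()
    ensure_dirs()
    _ = DEFAULT_SEED  # split/cohort seeds are fixed upstream

    cohort = read_cohort(SCRATCH / "cohort")
    meta = pd.read_csv(SCRATCH / "curated" / "metadata.csv").set_index("sample_id")
    split = json.loads((SCRATCH / "split.json").read_text())
    genes = list(pd.read_csv(RESULTS / "selected_genes.csv")["gene"])

    y = (meta["label"] == "cancer").astype(int)
    X_train = cohort.expression.loc[split["train_ids"], genes]
    X_test = cohort.expression.loc[split["test_ids"], genes]
    y_train = y.loc[split["train_ids"]].to_numpy()
    y_test = y.loc[split["test_ids"]].to_numpy()
    meta_test = meta.loc[split["test_ids"]].reset_index()

    models, rows, per_type = {}, [], {}
    for fam in FAMILIES:
        cfg = ModelConfig(family=fam, seed=args.seed)
        if args.search_iters is not None:
            cfg.n_search_iters = args.search_iters
        model = tune_and_fit(X_train.to_numpy(), y_train, cfg, genes=genes)
        models[fam] = model
        scores = model.predict_scores(X_test.to_numpy())
        preds = (scores >= model.threshold).astype(int)
        rep = classification_metrics(
            ConfusionMatrix.from_predictions(y_test, preds), scores=scores, labels=y_test
        )
        per_type[fam] = stratified_accuracy(preds, meta_test, "cancer_type")
        rows.append({"model": fam, "cv_auc": round(model.cv_auc, 3),
                     "threshold": round(model.threshold, 3), **rep.to_dict()})
        print(f"{fam}: test AUC {rep.auc:.3f}, balanced accuracy {rep.balanced_accuracy:.3f}")

    with open(SCRATCH / "models.pkl", "wb") as fh:
        pickle.dump({"models": models, "genes": genes}, fh)
    table = pd.DataFrame(rows).drop(columns=["undefined"])
    table.to_csv(RESULTS / "model_metrics.csv", index=False)
    type_table = None
    for fam, t in per_type.items():
        cur = t.set_index("stratum")["accuracy"].rename(fam)
        type_table = cur.to_frame() if type_table is None else type_table.join(cur)
    type_table.round(3).reset_index().to_csv(RESULTS / "per_type_accuracy.csv", index=False)
    print(f"mean test AUC {np.mean([r['auc'] for r in rows]):.3f}")


if __name__ == "__main__":
    main()
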