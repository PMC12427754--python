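#!/usr/bin/env python
"""Per-model Shapley attributions with adaptive outlier filtering.

Reads scratch/models.pkl and the cohort/split intermediates; writes raw and
filtered attribution matrices to scratch/attributions/ and the per-model
global importance table to results/global_importance.csv.
"""

import argparse
import json
import pickle

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs

from tepmced.attribution import compute_attributions, filter_outliers, global_importance, select_background
from tepmced.cohort import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--max-samples", type=int, default=None,
                    help="cap on explained test samples for the non-kernel backends")
    args = ap.parse_args()
    ensure_dirs()

    cohort = read_cohort(SCRATCH / "cohort")
    split = json.loads((SCRATCH / "split.json").read_text())
    with open(SCRATCH / "models.pkl", "rb") as fh:
        bundle = pickle.load(fh)
    models, genes = bundle["models"], bundle["genes"]

    X_train = cohort.expression.loc[split["train_ids"], genes]
    X_test = cohort.expression.loc[split["test_ids"], genes]

    out_dir = SCRATCH / "attributions"
    out_dir.mkdir(exist_ok=True)
    importance_cols = {}
    attr_sets = {}
    for fam, model in models.items():
        background = select_background(X_train, fam, seed=args.seed)
        X_explain = X_test
        if args.max_samples is not None and fam != "SVM":
            X_explain = X_test.iloc[: args.max_samples]
        aset = compute_attributions(model, X_explain, background, seed=args.seed)
        aset = filter_outliers(aset)
        attr_sets[fam] = aset
        aset.values.to_csv(out_dir / f"{fam}_raw.csv")
        aset.filtered_values.to_csv(out_dir / f"{fam}_filtered.csv")
        importance_cols[fam] = global_importance(aset)
        n_iqr = sum(r.method == "iqr" for r in aset.filter_reports)
        print(f"{fam}: explained {aset.values.shape[0]} samples; "
              f"{n_iqr}/{len(aset.filter_reports)} genes filtered via the IQR branch")

    with open(SCRATCH / "attributions.pkl", "wb") as fh:
        pickle.dump(attr_sets, fh)
    table = pd.DataFrame(importance_cols).sort_index()
    table.to_csv(RESULTS / "global_importance.csv")
    print(f"wrote global importance for {table.shape[0]} genes x {table.shape[1]} models")


if __name__ == "__main__":
    main()
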