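#!/usr/bin/env python
"""Covariate-balanced 80/20 train/test split of the curated cohort.

Reads scratch/curated; writes the split assignment to scratch/split.json and
the balance diagnostics to results/split_balance.csv.
"""

import argparse
import json

import numpy as np
import pandas as pd

from common import DEFAULT_SEED, RESULTS, SCRATCH, ensure_dirs

from tepmced.split import optimize_split


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--n-baseline", type=int, default=1000)
    args = ap.parse_args()
    ensure_dirs()

    meta = pd.read_csv(SCRATCH / "curated" / "metadata.csv")
    res = optimize_split(meta, test_fraction=0.2, seed=args.seed, n_baseline=args.n_baseline)
    (SCRATCH / "split.json").write_text(json.dumps(
        {"train_ids": res.train_ids, "test_ids": res.test_ids,
         "divergence": res.divergence, "converged": res.converged,
         "used_fallback": res.used_fallback}
    ))
    res.balance_table.to_csv(RESULTS / "split_balance.csv", index=False)
    print(
        f"test size {len(res.test_ids)} / {len(meta)}; divergence {res.divergence:.3e} "
        f"(baseline median {np.median(res.baseline_divergences):.3e}, "
        f"baseline min {res.baseline_divergences.min():.3e})"
    )


if __name__ == "__main__":
    main()
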