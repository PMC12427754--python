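#!/usr/bin/env python
"""Simulate the primary and external synthetic cohorts.

Writes expression/metadata CSVs to scratch/cohort and scratch/external and a
small composition summary to results/cohort_summary.csv.
"""

import argparse

import pandas as pd

from common import DEFAULT_SEED, EXTERNAL_COHORT, MODELING_COHORT, RESULTS, SCRATCH, ensure_dirs

from tepmced.cohort import CohortConfig, generate_cohort, generate_external_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = ap.parse_args()
    ensure_dirs()

    cfg = CohortConfig(seed=args.seed, **MODELING_COHORT)
    cohort = generate_cohort(cfg)
    cohort.write(SCRATCH / "cohort")

    external = generate_external_cohort(cohort, seed=args.seed + 1, **EXTERNAL_COHORT)
    external.write(SCRATCH / "external")

    rows = []
    for name, c in (("primary", cohort), ("external", external)):
        meta = c.metadata
        rows.append(
            {
                "cohort": name,
                "n_samples": len(meta),
                "n_cancer": int((meta["label"] == "cancer").sum()),
                "n_control": int((meta["label"] == "control").sum()),
                "n_flagged": int(meta["flagged"].sum()),
                "n_genes": c.expression.shape[1],
                "n_informative": len(c.informative_genes),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
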