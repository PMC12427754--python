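#!/usr/bin/env python
"""Curate the primary cohort and run three-stage feature selection.

Reads scratch/cohort; writes the curated metadata to scratch/curated and the
selected gene table (with ANOVA statistics) to results/selected_genes.csv.
"""

import argparse

from common import DEFAULT_SEED, RESULTS, SCRATCH, ensure_dirs

from tepmced.cohort import read_cohort
from tepmced.preprocess import exclude_flagged, select_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = ap.parse_args()
    ensure_dirs()

    cohort = read_cohort(SCRATCH / "cohort")
    meta = exclude_flagged(cohort.metadata)
    expr = cohort.expression.loc[meta["sample_id"].to_numpy()]
    print(f"curated: {len(meta)} of {len(cohort.metadata)} samples retained")

    report = select_features(expr, meta, seed=args.seed)
    (SCRATCH / "curated").mkdir(exist_ok=True)
    meta.to_csv(SCRATCH / "curated" / "metadata.csv", index=False)

    stats = report.anova_pass.set_index("gene")
    table = stats.loc[[g for g in report.retained]].reset_index()
    table["planted"] = table["gene"].isin(cohort.informative_genes)
    table.to_csv(RESULTS / "selected_genes.csv", index=False)
    print(
        f"selected {len(report.retained)} genes "
        f"({table['planted'].sum()} planted, {len(report.dropped_pairs)} pruned for correlation)"
    )


if __name__ == "__main__":
    main()
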