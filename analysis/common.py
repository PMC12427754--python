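"""Shared paths and defaults for the numbered analysis drivers.

The drivers run the pipeline end to end at a reduced scale (a few hundred
samples, 600 genes) so the whole sequence completes in minutes on one CPU.
Large or binary intermediates (expression matrices, fitted models,
attribution matrices) go to ``scratch/``; small result tables go to
``results/``.
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

sys.path.insert(0, str(ROOT / "src"))

# reduced-scale modeling cohort (the package's own choice of problem size)
MODELING_COHORT = dict(
    n_cancer=260,
    n_control=140,
    n_flagged_controls=60,
    n_genes=600,
    n_informative=20,
    effect_size=1.5,
)
EXTERNAL_COHORT = dict(n_samples=180, n_overlap=20, gene_subset_fraction=0.9)

DEFAULT_SEED = 0


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
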