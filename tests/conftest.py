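import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tepmced.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort used across the suite."""
    cfg = CohortConfig(
        n_cancer=220,
        n_control=120,
        n_flagged_controls=60,
        n_genes=300,
        n_informative=12,
        effect_size=1.5,
        n_types=6,
        n_institutions=3,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_xy():
    """Small separable binary problem with 6 features (2 informative)."""
    rng = np.random.default_rng(0)
    n = 240
    y = (rng.random(n) < 0.65).astype(int)
    X = rng.standard_normal((n, 6))
    X[:, 0] += 1.8 * y
    X[:, 1] -= 1.2 * y
    return X, y
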