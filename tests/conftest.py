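import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160127)


@pytest.fixture
def small_cohort():
    from subtypekit import CohortConfig, simulate_expression_cohort
    return simulate_expression_cohort(
        CohortConfig(n_genes=60, n_marker_per_class=10, n_luminal=8, n_basal=8,
                     n_nontype=4, effect_size=2.0, noise_sd=0.5, seed=7))


@pytest.fixture
def toy_pwm():
    from subtypekit import PWM
    counts = np.array([
        [9, 0, 0, 9, 0, 0],
        [0, 9, 0, 0, 9, 0],
        [0, 0, 9, 0, 0, 0],
        [0, 0, 0, 0, 0, 9],
    ], dtype=float)
    return PWM("TOY", counts)   # consensus ACGACT
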