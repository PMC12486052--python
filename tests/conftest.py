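import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300/200 confounded cohort with elevated prevalence for power."""
    from orncausal.synthetic import SimConfig, generate
    return generate(SimConfig(n_vmat=300, n_pbspt=200, base_rate=0.05,
                              effect=1.5, seed=42))


@pytest.fixture(scope="session")
def rct_arrays():
    """Randomized-treatment binary-outcome arrays with tau = 0.25."""
    rng = np.random.default_rng(7)
    n = 2000
    X = rng.standard_normal((n, 8))
    T = rng.integers(0, 2, n)
    Y = (rng.random(n) < 0.2 + 0.25 * T).astype(float)
    return X, T, Y
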