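import numpy as np
import pytest

from medhaz import SimScenario, calibrate_censoring, generate


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down cohort: n=300 subjects, p=400 mediators, ~15% censoring."""
    scen = SimScenario(n=300, p=400, target_censoring=0.15, seed=42)
    from dataclasses import replace

    return replace(scen, censor_upper=calibrate_censoring(scen))


@pytest.fixture(scope="session")
def small_data(small_scenario):
    data, truth = generate(small_scenario)
    return data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n=12, m=2, tie_fraction=0.3):
    """Small random survival data with ties, for oracle comparisons."""
    t = rng.integers(1, 6, n) / 2.0 + rng.random(n) * (rng.random(n) > tie_fraction)
    status = (rng.random(n) < 0.7).astype(int)
    if status.sum() == 0:
        status[0] = 1
    Q = rng.standard_normal((n, m))
    return Q, t, status
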