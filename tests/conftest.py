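import numpy as np
import pytest

from drscore import SurvivalData, canonical_config, simulate_cohort


def random_cohort(rng, n, censor_scale=40.0, time_scale=40.0):
    """Null survival cohort: exponential event and censoring times."""
    t = np.round(rng.exponential(time_scale, n), 1) + 0.1
    c = np.round(rng.exponential(censor_scale, n), 1) + 0.1
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return SurvivalData.from_arrays(times, events)


@pytest.fixture(scope="session")
def canonical_cohort():
    """The packaged study-shaped simulation (n=300, seed 1), shared."""
    return simulate_cohort(canonical_config(n_patients=300, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140224)
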