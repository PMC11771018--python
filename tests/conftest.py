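import numpy as np
import pandas as pd
import pytest

from landmarker import Cohort, LandmarkGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_cohort(rng, n=50, n_causes=1, n_meas=3, t_scale=4.0):
    """Small random longitudinal cohort used across test modules."""
    ids = np.arange(n)
    T = rng.exponential(t_scale, n)
    status = np.where(rng.random(n) < 0.7, rng.integers(1, n_causes + 1, n), 0)
    rows = []
    for i in ids:
        times = np.sort(rng.uniform(0, max(T[i], 1e-6), n_meas - 1))
        times = np.concatenate([[0.0], times[times < T[i]]])
        for t in times:
            rows.append({"id": i, "obs_time": t, "x1": rng.normal(), "x2": rng.normal()})
    outcomes = pd.DataFrame({"id": ids, "time": T, "status": status})
    return Cohort(outcomes, pd.DataFrame(rows), n_causes=n_causes)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng, n=40)


@pytest.fixture
def grid():
    return LandmarkGrid((0.0, 1.0, 2.0), 5.0)
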