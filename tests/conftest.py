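import numpy as np
import pandas as pd
import pytest

from koaprog.cohort import Cohort, CovariateSchema
from koaprog.synthetic import default_causal_spec, default_transition_matrix, simulate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_causal_spec()


@pytest.fixture(scope="session")
def tm():
    return default_transition_matrix()


@pytest.fixture(scope="session")
def small_cohort(spec, tm):
    """518 patients x 5 visits under the default study conditions."""
    return simulate_cohort(spec, tm, n_patients=518, n_visits=5, seed=7)


def planted_signal_cohort(seed: int, n: int = 200, n_visits: int = 4) -> Cohort:
    """Cohort where exactly one feature ('jsn') determines the
    next-visit grade and three others are pure noise."""
    rng = np.random.default_rng(seed)
    jsn = rng.normal(size=(n, n_visits))
    noise = rng.normal(size=(n, n_visits, 3))
    kl = np.zeros((n, n_visits))
    kl[:, 0] = rng.integers(0, 5, size=n)
    for t in range(1, n_visits):
        kl[:, t] = np.clip(np.round(1.5 * jsn[:, t - 1] + 2), 0, 4)
    rows = []
    for i in range(n):
        for t in range(n_visits):
            rows.append(
                {
                    "patient_id": f"P{i:04d}",
                    "visit": t,
                    "kl": kl[i, t],
                    "jsn": jsn[i, t],
                    "noise_a": noise[i, t, 0],
                    "noise_b": noise[i, t, 1],
                    "noise_c": noise[i, t, 2],
                }
            )
    schema = {
        c: CovariateSchema(c, "continuous")
        for c in ["jsn", "noise_a", "noise_b", "noise_c"]
    }
    return Cohort(pd.DataFrame(rows), schema)


@pytest.fixture
def planted_cohort():
    return planted_signal_cohort(0)


def tiny_cohort(frame_rows, schema=None):
    df = pd.DataFrame(frame_rows)
    return Cohort(df, schema or {})
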