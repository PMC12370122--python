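import numpy as np
import pandas as pd
import pytest

from ciafmsm import CohortConfig, MultiStateMarkovModel, generate_cohort
from ciafmsm.cohort import DEFAULT_BASELINE_INTENSITIES

# Published survey estimates used as worked-example inputs: the per-month
# baseline transition intensities of the covariate-adjusted model.
WITHCOV_INTENSITIES = {
    (1, 2): 0.014625,
    (1, 3): 0.008735,
    (2, 1): 0.020298,
    (2, 3): 0.008244,
    (3, 1): 0.046233,
    (3, 2): 0.063825,
}


@pytest.fixture(scope="session")
def baseline_rates():
    """The generator's default truth: no-covariate baseline intensities."""
    return dict(DEFAULT_BASELINE_INTENSITIES)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic panel with its generating truth (shared, read-only)."""
    panel, truth = generate_cohort(CohortConfig(n_children=250, seed=42))
    return panel, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    panel, _ = small_cohort
    with pytest.warns(UserWarning):
        return MultiStateMarkovModel().fit(panel)


def toy_panel():
    """Three children, hand-enumerable observation pairs."""
    return pd.DataFrame(
        {
            "child_id": [1, 1, 1, 2, 2, 3, 3],
            "time_months": [0.0, 18.0, 36.0, 0.0, 18.0, 0.0, 20.0],
            "state": [1, 2, 2, 2, 3, 3, 1],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
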