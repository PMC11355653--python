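import numpy as np
import pytest

from pessaryfit import (
    CohortTable,
    DesignMatrix,
    default_effect_profile,
    generate_cohort,
    variable_grid,
)


def make_design(X, y) -> DesignMatrix:
    """Wrap raw arrays into a DesignMatrix using the first p grid keys."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    keys = list(variable_grid())[: X.shape[1]]
    return DesignMatrix(
        X=X,
        y=y,
        column_keys=keys,
        column_means=np.zeros(X.shape[1]),
        column_sds=np.ones(X.shape[1]),
        missing_mask=np.zeros_like(X, dtype=bool),
    )


@pytest.fixture(scope="session")
def default_profile():
    return default_effect_profile()


@pytest.fixture(scope="session")
def small_cohort(default_profile) -> CohortTable:
    """A 9/6 synthetic cohort with the default informative profile."""
    return generate_cohort(9, 6, default_profile, seed=11)


@pytest.fixture(scope="session")
def complete_cohort() -> CohortTable:
    """A 9/6 cohort with no missing cells (easier exact bookkeeping)."""
    profile = default_effect_profile(missing_rate=0.0)
    return generate_cohort(9, 6, profile, seed=5)
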