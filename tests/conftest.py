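import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metafunc import FunctionalProfile
from metafunc.synthetic import example_config, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_profile(values, groups, fids=None, unit="counts") -> FunctionalProfile:
    """Small helper: build a profile from a plain nested list."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sids = [f"S{i+1}" for i in range(n)]
    fids = fids or [f"F{j+1}" for j in range(m)]
    return FunctionalProfile(
        pd.DataFrame(values, index=sids, columns=fids),
        pd.Series(list(groups), index=sids, name="group"),
        unit,
    )


def two_column_profile(values, groups) -> FunctionalProfile:
    """Relative-unit profile whose first column carries ``values``.

    Scales values into (0,1) and adds the complementary column, so the
    permutation distribution of the first column's F statistic equals that
    of the raw values (F is affine-invariant).
    """
    v = np.asarray(values, dtype=float)
    x = (v - v.min() + 1) / (2 * (v.max() - v.min() + 1))
    return make_profile(np.column_stack([x, 1 - x]), groups, unit="relative")


@pytest.fixture(scope="session")
def example_dataset():
    """One cohort from the default study-shaped configuration."""
    return generate_dataset(example_config(seed=11, n_functions=60))
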