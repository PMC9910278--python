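import numpy as np
import pandas as pd
import pytest

from selfreg.cohort import generate_cohort
from selfreg.types import CohortConfig


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=6, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_ratings(rng, n_htlh=80, n_lthh=30, n_hthh=40, n_ltlh=30, n_neutral=0):
    """Hand-rolled rating table with known quadrant counts."""
    rows = []
    specs = [
        (n_htlh, 1, -1),
        (n_lthh, -1, 1),
        (n_hthh, 1, 1),
        (n_ltlh, -1, -1),
    ]
    for count, st, sh in specs:
        for _ in range(count):
            rows.append(
                (st * rng.uniform(0.6, 5.0), sh * rng.uniform(0.6, 5.0))
            )
    for _ in range(n_neutral):
        rows.append((rng.uniform(-0.5, 0.5), rng.uniform(-5, 5)))
    df = pd.DataFrame(rows, columns=["tr", "hr"])
    df.insert(0, "food_id", [f"f{i:03d}" for i in range(len(df))])
    return df
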