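import numpy as np
import pandas as pd
import pytest

import dietsleep as ds


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-participant synthetic cohort shared across tests."""
    return ds.generate_cohort(ds.GeneratorConfig(n_participants=400, seed=7))


@pytest.fixture(scope="session")
def exposures(small_cohort) -> pd.DataFrame:
    return ds.derive_exposures(small_cohort)


def random_compositions(rng: np.random.Generator, n: int, d: int = 5) -> np.ndarray:
    """Strictly positive random compositions via closed lognormal draws."""
    return ds.closure(rng.lognormal(0.0, 0.7, size=(n, d)))
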