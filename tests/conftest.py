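import numpy as np
import pytest

import cabanet as cb


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=660) with its planted graph."""
    return cb.generate_cohort(cb.default_config(), seed=0)


@pytest.fixture(scope="session")
def encoded_cohort(default_cohort):
    table, _ = default_cohort
    encoded, report = cb.encode_table(table, cb.variable_dictionary(cb.default_config()))
    return encoded, report


@pytest.fixture(scope="session")
def cohort_batch():
    """Twenty default cohorts under distinct seeds, for calibration checks."""
    cfg = cb.default_config()
    return [cb.generate_cohort(cfg, seed=s) for s in range(20)]


def gaussian_chain(n: int, rng: np.random.Generator, coef: float = 0.8) -> np.ndarray:
    """X -> Y -> Z with strong linear effects; true skeleton {X-Y, Y-Z}."""
    x = rng.normal(size=n)
    y = coef * x + rng.normal(size=n)
    z = coef * y + rng.normal(size=n)
    return np.column_stack([x, y, z])
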