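import numpy as np
import pandas as pd
import pytest

SUBTYPE_SIZES = {"PD-NC": 41, "PD-FS": 16, "PD-PC": 25, "PD-MS": 32}


@pytest.fixture
def labels114():
    return np.repeat(list(SUBTYPE_SIZES), list(SUBTYPE_SIZES.values()))


@pytest.fixture
def covariates114(labels114):
    """Random but fixed age/sex/education/center table for 114 subjects."""
    rng = np.random.default_rng(7)
    n = len(labels114)
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": rng.normal(65, 8, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.normal(12, 3, n),
        "center": rng.integers(0, 2, n),
    })


def covariate_block(rng, n):
    """Plain ndarray covariate block (age, sex, education, center)."""
    return np.column_stack([
        rng.normal(65, 8, n), rng.integers(0, 2, n),
        rng.normal(12, 3, n), rng.integers(0, 2, n),
    ])
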