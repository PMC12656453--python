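import numpy as np
import pandas as pd
import pytest

import soilrisk as sr


@pytest.fixture(scope="session")
def registry():
    return sr.default_registry()


@pytest.fixture(scope="session")
def survey48():
    """One default synthetic survey (48 samples, calibrated spec)."""
    return sr.generate(sr.default_spec(seed=0))


def make_table(n=6, seed=0, **overrides):
    """A small valid survey table; per-element columns overridable."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
        }
    )
    base = {
        "Pb": 26.0, "Cd": 0.29, "As": 13.0, "Hg": 0.05,
        "Cr": 61.0, "Zn": 73.0, "Cu": 27.0, "Ni": 32.0,
    }
    for el, mean in base.items():
        df[el] = overrides.get(el, mean * rng.uniform(0.8, 1.2, n))
    return df


@pytest.fixture
def small_samples():
    return sr.from_dataframe(make_table())
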