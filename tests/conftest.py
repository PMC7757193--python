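import numpy as np
import pandas as pd
import pytest

from metaspom import landscape as lsc
from metaspom import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_bundle():
    """20 patches x 5 years; the smoke-test profile."""
    return sd.make_fixture("tiny", seed=4)


@pytest.fixture(scope="session")
def mid_bundle():
    """150 patches x 10 years; big enough for stable model fits."""
    land = sd.generate_landscape(150, years=range(2000, 2010), seed=11)
    precip = sd.generate_covariates(10, seed=12)
    truth = sd.default_truth()
    hist = sd.generate_history(land, precip, truth, 10, seed=13)
    return land, hist, precip, truth


@pytest.fixture(scope="session")
def default_bundle():
    """The study-scale profile (500 patches x 19 years)."""
    return sd.make_fixture("default", seed=1)


@pytest.fixture()
def square_landscape():
    """Four patches on a unit square with simple attributes."""
    table = pd.DataFrame({
        "patch_id": ["a", "b", "c", "d"],
        "x_km": [0.0, 1.0, 0.0, 1.0],
        "y_km": [0.0, 0.0, 1.0, 1.0],
        "area_m2": [10.0, 20.0, 30.0, 40.0],
        "road": [0, 1, 0, 1],
        "vs_score": [0, 1, 2, 3],
        "cover_pl_2000": [1.0, 2.0, 3.0, 4.0],
        "cover_pl_2001": [3.0, 2.0, np.nan, 4.0],
    })
    return lsc.Landscape(table)
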