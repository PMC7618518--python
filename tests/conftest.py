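import numpy as np
import pandas as pd
import pytest

from nanodomain.localization import LOC_COLUMNS
from nanodomain.simulate import ClusterFieldSpec, generate_cluster_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """3x3 um clustered field (~100 clusters worth of structure scaled
    down to ~80), shared across read-only tests."""
    spec = ClusterFieldSpec(field_width=3000.0, field_height=3000.0, seed=7)
    return generate_cluster_field(spec)


def make_loc_table(xy, frames=None, sigma=150.0, intensity=2000.0,
                   uncertainty=10.0):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    return pd.DataFrame({
        "frame": np.arange(1, n + 1) if frames is None else frames,
        "x_nm": xy[:, 0],
        "y_nm": xy[:, 1],
        "sigma_nm": np.full(n, sigma),
        "intensity_photon": np.full(n, intensity),
        "offset_photon": np.zeros(n),
        "uncertainty_nm": np.full(n, uncertainty),
    }, columns=LOC_COLUMNS)


@pytest.fixture
def loc_table_factory():
    return make_loc_table
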