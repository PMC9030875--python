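import os

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

os.environ.setdefault("MPLBACKEND", "Agg")

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def builtin_community():
    from rosphere import load_builtin_table

    return load_builtin_table()


@pytest.fixture()
def default_params():
    from rosphere import H2O2Params

    return H2O2Params()


def brute_force_nearest_neighbours(positions, extent=None):
    """All-pairs nearest-neighbour distances; minimum image when extent given."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    diff = positions[:, None, :] - positions[None, :, :]
    if extent is not None:
        box = np.asarray(extent, dtype=float)
        diff = diff - box * np.round(diff / box)
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
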