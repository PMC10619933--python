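import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from calipr.epg import SequenceParams
from calipr.phantom import default_phantom_spec, make_coil_maps, make_phantom
from calipr.t2fit import FitConfig, T2Grid


@pytest.fixture(scope="session")
def seq32() -> SequenceParams:
    """Desk-scale echo train: 32 echoes at 10 ms spacing."""
    return SequenceParams(n_echoes=32, delta_te=10.0)


@pytest.fixture(scope="session")
def small_truth(seq32):
    """32x32 concentric WM/GM/CSF phantom ground truth."""
    return make_phantom(default_phantom_spec((32, 32), seq=seq32, seed=0))


@pytest.fixture(scope="session")
def small_maps():
    return make_coil_maps(4, (32, 32), seed=1)


@pytest.fixture(scope="session")
def fit_config(seq32) -> FitConfig:
    return FitConfig(grid=T2Grid.default(), seq=seq32)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
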