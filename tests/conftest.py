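import numpy as np
import pytest

from mmconnect.netio import Parcellation
from mmconnect.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def parc6() -> Parcellation:
    return Parcellation.generic(6)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Smallest practical cohort: 6 ROIs, 4 subjects."""
    return SyntheticConfig(n_rois=6, n_patients=2, n_controls=2, t_points=40, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
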