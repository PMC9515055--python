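import numpy as np
import pytest

from bemseg.synthetic import AnatomyParams, generate_skeleton, generate_tissue_hull, generate_volume
from bemseg.volumes import LabelVolume


@pytest.fixture(scope="session")
def mini_params():
    return AnatomyParams.mini(seed=7)


@pytest.fixture(scope="session")
def mini_skeleton(mini_params):
    return generate_skeleton(mini_params)


@pytest.fixture(scope="session")
def mini_hull(mini_params, mini_skeleton):
    return generate_tissue_hull(mini_skeleton, mini_params.compartments)


@pytest.fixture(scope="session")
def mini_pair(mini_params):
    """One (CT, labels) mini phantom pair."""
    return generate_volume(mini_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_labels(rng):
    """A small random label volume with 6 classes."""
    return LabelVolume(rng.integers(0, 6, size=(9, 10, 11)), n_classes=6)
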