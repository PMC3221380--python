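import numpy as np
import pytest

import ctstream as cs
from ctstream.volume_core import ImageVolume


@pytest.fixture(scope="session")
def ncct_small():
    """Noise-free noncontrast head phantom at test scale."""
    return cs.generate_ncct(cs.default_ncct_spec(grid=(12, 64, 64)))


@pytest.fixture(scope="session")
def ncct_medium():
    """Higher-resolution noise-free phantom for codec/session checks."""
    return cs.generate_ncct(cs.default_ncct_spec(grid=(12, 128, 128)))


@pytest.fixture(scope="session")
def cta_occluded():
    return cs.generate_cta(cs.default_cta_spec(grid=(20, 64, 64)))


@pytest.fixture(scope="session")
def cta_patent():
    return cs.generate_cta(cs.default_cta_spec(grid=(20, 64, 64), occluded=False))


@pytest.fixture()
def registry(ncct_small, cta_occluded):
    reg = cs.ServerRegistry()
    server = cs.Server({"ncct1": ncct_small[0], "cta1": cta_occluded[0]})
    reg.register(server)
    return reg, server


def make_volume(voxels, spacing=(1.0, 1.0, 1.0)):
    voxels = np.asarray(voxels)
    return ImageVolume(voxels, spacing, np.zeros(3), np.eye(3))
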