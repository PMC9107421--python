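import numpy as np
import pytest

from tractlesion import (
    BinaryMask,
    PhantomConfig,
    make_aslant_bundle,
    make_roi_masks,
    make_tumor_mask,
)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def phantom_bundle(phantom_config):
    return make_aslant_bundle(phantom_config)


@pytest.fixture(scope="session")
def phantom_rois(phantom_config):
    return make_roi_masks(phantom_config)


@pytest.fixture(scope="session")
def phantom_tumor(phantom_config):
    return make_tumor_mask(phantom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(12, 12, 12), n_set=30, affine=None):
    """Helper: random binary mask with roughly n_set voxels."""
    if affine is None:
        affine = np.eye(4)
    data = np.zeros(shape, dtype=np.uint8)
    idx = rng.integers(0, np.array(shape), size=(n_set, 3))
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return BinaryMask(data=data, affine=affine)
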