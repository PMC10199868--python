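import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pvcbrain import (
    IYConfig,
    PhantomSpec,
    PSFModel,
    VolumeImage,
    make_atlas,
    make_dataset,
    make_probability_maps,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """48^3 phantom recipe used by most structural tests."""
    return PhantomSpec(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                       n_sectors=8, seed=7, noise_level=0.02)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return make_atlas(small_spec)


@pytest.fixture(scope="session")
def small_probmaps(small_spec, small_atlas):
    return make_probability_maps(small_atlas, 0.0, small_spec.spacing)


@pytest.fixture(scope="session")
def paired_dataset(small_spec):
    """Three reproducible paired samples with the default IY reference."""
    return make_dataset(3, small_spec, IYConfig(), seed=11)


@pytest.fixture(scope="session")
def gan_dataset():
    """64^3 samples for translator tests (the training slice source)."""
    spec = PhantomSpec(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0),
                       n_sectors=8, seed=3, noise_level=0.02,
                       sim_psf_fwhm_mm=6.0)
    return make_dataset(4, spec, IYConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_volume(shape=(16, 16, 16), seed=0, spacing=(1.0, 1.0, 1.0)) -> VolumeImage:
    gen = np.random.default_rng(seed)
    return VolumeImage(gen.uniform(0.0, 10.0, size=shape), spacing)
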