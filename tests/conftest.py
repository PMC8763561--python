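import numpy as np
import pytest

from vesselseg import network, patches, preprocessing, synthetic
from vesselseg.io import FundusSample

#: small synthetic geometry used throughout the tests; vessel widths and
#: tree counts are scaled down with the frame so that vessel density
#: stays fundus-like (~5-10% of the FOV).
SMALL_SPEC = synthetic.SyntheticSpec(dims=(128, 128), n_trees=3,
                                     width_range=(1.0, 2.5), generations=4)

#: reduced network used wherever weights must actually be trained.
TINY_KWARGS = dict(levels=3, widths=(8, 16, 32), ms_widths=(8, 16),
                   mdaspp_branch=16, mdaspp_growth_high=8, mdaspp_growth_low=8,
                   bottleneck_width=64, patch_size=32)


@pytest.fixture(scope="session")
def small_samples():
    import dataclasses

    return [synthetic.generate_sample(dataclasses.replace(SMALL_SPEC, seed=s))
            for s in range(3)]


@pytest.fixture(scope="session")
def preprocessed_small(small_samples):
    return [FundusSample(image=preprocessing.preprocess(s), label=s.label,
                         fov=s.fov, identifier=s.identifier)
            for s in small_samples]


@pytest.fixture(scope="session")
def tiny_patches(preprocessed_small):
    return patches.sample_patches(preprocessed_small[:2], per_image=4,
                                  size=32, seed=1)


@pytest.fixture
def tiny_model():
    return network.build_model(network.preset("a5", **TINY_KWARGS), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
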