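import numpy as np
import pytest

from hogseg import nn
from hogseg.config import desk_scale_config
from hogseg.hog import HOGConfig, descriptor_length
from hogseg.models import MultiTaskModelSpec
from hogseg.synthetic import SceneConfig, generate_samples
from hogseg.training import TrainConfig, attach_pseudo_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_nn():
    """Run the autograd in float64 for numerical gradient validation."""
    nn.set_dtype(np.float64)
    yield
    nn.set_dtype(np.float32)


@pytest.fixture(scope="session")
def tiny_scene_config():
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def tiny_hog_config():
    return HOGConfig()


def tiny_model_spec(**overrides) -> MultiTaskModelSpec:
    base = dict(backbone="unet", n_classes=6, input_size=(64, 128),
                hog_dim=descriptor_length(HOGConfig()),
                width_scale=0.125, n_stages=3, seed=3)
    base.update(overrides)
    return MultiTaskModelSpec(**base)


def tiny_train_config(**overrides) -> TrainConfig:
    base = dict(max_iters=60, validate_every=30, batch_size=2, seed=3)
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture(scope="session")
def tiny_samples(tiny_scene_config, tiny_hog_config):
    """Four synthetic triplets with pseudo-labels attached."""
    samples = generate_samples(tiny_scene_config, 4)
    attach_pseudo_labels(samples, tiny_hog_config)
    return samples
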