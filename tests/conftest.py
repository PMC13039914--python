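import numpy as np
import pytest

from metacam import TinyConvNet, gen_scene, train_tiny_model


@pytest.fixture(scope="session")
def fixture_model():
    """Tiny classifier trained once per session on the glyph-texture task."""
    model, accuracy = train_tiny_model(seed=0)
    return model, accuracy


@pytest.fixture(scope="session")
def scene():
    return gen_scene(seed=42)


@pytest.fixture(scope="session")
def decoy_scene():
    return gen_scene(seed=43, with_decoy=True)


@pytest.fixture()
def toy_model():
    """Untrained 8x8 two-class net: fast, deterministic, differentiable."""
    return TinyConvNet(image_size=8, in_channels=1, n_classes=2, seed=3)


@pytest.fixture()
def toy_image():
    return np.random.default_rng(7).random((8, 8, 1))
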