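import numpy as np
import pytest

from brainrecon.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def small_config(**overrides) -> SyntheticConfig:
    """A fast desk-scale configuration for unit tests."""
    base = dict(
        n_train=120,
        n_classes_train=30,
        images_per_class=4,
        n_test=8,
        n_test_repeats=3,
        n_voxels=100,
        latent_dim=16,
        visual_dim=24,
        text_dim=8,
        snr=5.0,
        seed=7,
        image_size=32,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small linear noiseless dataset: decoding is exactly solvable."""
    cfg = small_config(snr=np.inf, seed=1)
    train, test, truth = generate_dataset(cfg)
    return cfg, train, test, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    cfg = small_config(snr=5.0, seed=2)
    train, test, truth = generate_dataset(cfg)
    return cfg, train, test, truth


# expose the factory for tests that need custom shapes
@pytest.fixture
def make_config():
    return small_config
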