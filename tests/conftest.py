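import numpy as np
import pytest

from amyloid_latent_dyn import (
    GanConfig,
    GanModel,
    GroundTruthDynamics,
    PhantomSpec,
    build_phantom,
    region_masks,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """Noise-free 16^3 phantom spec used across unit tests."""
    return PhantomSpec(grid_shape=(16, 16, 16), noise_sigma=0.0)


@pytest.fixture(scope="session")
def tiny_masks(tiny_spec):
    return region_masks(tiny_spec)


@pytest.fixture(scope="session")
def dynamics():
    return GroundTruthDynamics()


@pytest.fixture(scope="session")
def tiny_gan_config():
    return GanConfig(volume_shape=(16, 16, 16), z_dim=8, w_dim=8,
                     mapping_depth=2, channels=(8, 8, 4), total_steps=8,
                     batch_size=2, seed=11)


@pytest.fixture(scope="session")
def tiny_gan(tiny_gan_config):
    """Untrained tiny GAN (deterministic initialization)."""
    return GanModel(tiny_gan_config)


@pytest.fixture(scope="session")
def phantom_stack(tiny_spec, dynamics):
    """Sixteen noise-free phantoms across the load range."""
    loads = np.linspace(0.0, 1.0, 16)
    return np.stack([build_phantom(tiny_spec, lo, dynamics, seed=i)
                     for i, lo in enumerate(loads)]), loads
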