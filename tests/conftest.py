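import numpy as np
import pytest

from ivdseg import (NetworkSpec, PhantomDomainConfig, TransformParams,
                    generate_domain_dataset)


@pytest.fixture(scope="session")
def tiny_config():
    """Small phantom domain: quick to generate, still multi-disc."""
    return PhantomDomainConfig(
        n_discs=3, volume_shape=(16, 16, 8), disc_radii=(2.0, 3.0),
        disc_thickness=(1.5, 2.5), spine_curvature=1.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_domain_dataset(tiny_config, 12, base_seed=1)


@pytest.fixture(scope="session")
def default_config():
    return PhantomDomainConfig()


@pytest.fixture(scope="session")
def transform_params():
    return TransformParams(rng_seed=5)


@pytest.fixture()
def tiny_net_spec():
    """Two-block net on 16x16x8 inputs (pool factor 4)."""
    return NetworkSpec(
        base_channels=4, n_encoder_blocks=2, width_scale=1.0,
        pretext_heads=({"name": "intensity", "n_classes": 4,
                        "start_filters": 8},))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
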