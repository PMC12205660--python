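import numpy as np
import pytest

import sti_response as sr


@pytest.fixture(scope="session")
def tiny_phantom_config() -> sr.PhantomConfig:
    """A small, fast phantom configuration for unit tests."""
    return sr.PhantomConfig(
        n_patients=6,
        grid_shape=(32, 32, 16),
        voxel_spacing_mm=(1.0, 1.0, 2.0),
        tumor_radius_mm=(6.0, 9.0),
        seed=1234,
    )


@pytest.fixture(scope="session")
def tiny_preproc() -> sr.PreprocConfig:
    return sr.PreprocConfig(patch_shape=(16, 16, 16), mask_margin_mm=2.0)


@pytest.fixture(scope="session")
def tiny_case(tiny_phantom_config) -> sr.LongitudinalCase:
    return sr.generate_case(tiny_phantom_config, 0)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_phantom_config, tiny_preproc) -> sr.PhantomDataset:
    """Six preprocessed cases shared across unit tests."""
    return sr.build_dataset(tiny_phantom_config, tiny_preproc, k=3, seed=0)


@pytest.fixture(scope="session")
def tiny_sti_config(tiny_preproc) -> sr.StiConfig:
    return sr.StiConfig(
        patch_shape=tiny_preproc.patch_shape,
        embed_dim=32,
        encoder_channels=(4, 8),
        n_heads_spatial=2,
        n_heads_temporal=2,
        training=sr.TrainingConfig(epochs=2, batch_size=4, learning_rate=3e-3,
                                   folds=2),
        seed=3,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
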