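"""Shared fixtures: one micro dataset, session-scoped trained generators
and cached inversion latents, reused across module and acceptance tests."""

import numpy as np
import pytest

from genscreen.gan import GanTrainConfig, train_gan
from genscreen.inversion import InversionConfig, invert_dataset
from genscreen.preprocess import RadiographPreprocessor
from genscreen.synthdata import DatasetConfig, generate_dataset

# The desk-scale study conditions: diseased-only upstream split, 1:1
# balanced downstream split (n=256), imbalanced held-out test split,
# severity uniform 20-45 deg (scoliosis) vs 0-9 deg (normal), ~12.5% levo.
MICRO_DATASET_CONFIG = DatasetConfig(
    upstream_n=192,
    downstream_per_class=128,
    test_pos=40,
    test_neg=80,
    image_size=32,
)

MICRO_GAN_CONFIG = dict(total_steps=1000, fid_interval=200)
MICRO_INVERSION_CONFIG = dict(iterations=150, batch_size=64, seed=0)

DATASET_SEED = 2026


@pytest.fixture(scope="session")
def micro_manifest():
    return generate_dataset(MICRO_DATASET_CONFIG, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def preprocessor():
    return RadiographPreprocessor(
        target_resolution=MICRO_DATASET_CONFIG.image_size
    )


@pytest.fixture(scope="session")
def upstream_images(micro_manifest, preprocessor):
    up = micro_manifest.split("upstream")
    return preprocessor.transform([up.images[i] for i in up.frame.image_id])


def _train(micro_manifest, upstream_images, seed):
    up = micro_manifest.split("upstream")
    cfg = GanTrainConfig(seed=seed, **MICRO_GAN_CONFIG)
    return train_gan(up, cfg, images=upstream_images)


@pytest.fixture(scope="session")
def gan_result(micro_manifest, upstream_images):
    """FID-selected micro generator trained on the diseased-only split."""
    return _train(micro_manifest, upstream_images, seed=0)


@pytest.fixture(scope="session")
def gan_results_three_seeds(micro_manifest, upstream_images, gan_result):
    """Three independently seeded trainings (seed 0 shared with gan_result)."""
    return {
        0: gan_result,
        1: _train(micro_manifest, upstream_images, seed=1),
        2: _train(micro_manifest, upstream_images, seed=2),
    }


@pytest.fixture(scope="session")
def micro_latents(micro_manifest, gan_result, preprocessor):
    """Inversion latent tables (downstream, test) for the seed-0 generator."""
    cfg = InversionConfig(**MICRO_INVERSION_CONFIG)
    gen = gan_result.generator
    down = invert_dataset(micro_manifest.split("downstream"), gen, cfg,
                          preprocessor=preprocessor)
    test = invert_dataset(micro_manifest.split("test"), gen, cfg,
                          preprocessor=preprocessor)
    return down, test
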