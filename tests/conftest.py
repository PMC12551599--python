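"""Shared fixtures: the fixed simulation suite and desk-scale trained models.

Everything is generated programmatically from fixed seeds; the expensive
fixtures (phantom-pair suite, codec + diffusion + segmentation training) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ldmar.codec import train_codec
from ldmar.diffusion import train_ldm
from ldmar.phantom import default_geometry, default_spectrum, generate_pairs
from ldmar.segmentation import synthesize_seg_dataset, train_seg

SUITE_SEED = 0
N_PAIRS = 24
N_TRAIN = 20  # remaining pairs are held out for model evaluation


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()

@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def pair_suite():
    """24 paired clean/corrupted slices at the package's study conditions."""
    return generate_pairs(N_PAIRS, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def train_pairs(pair_suite):
    return pair_suite[:N_TRAIN]


@pytest.fixture(scope="session")
def holdout_pairs(pair_suite):
    return pair_suite[N_TRAIN:]


@pytest.fixture(scope="session")
def trained_codec(train_pairs):
    """Desk-scale codec trained on corrupted + clean slices of the train split."""
    images = [p.corrupted.values for p in train_pairs] + [p.clean.values for p in train_pairs]
    return train_codec(
        images, n_steps=400, batch_size=4, lr=2e-3, channels=(16, 32), k=64, seed=SUITE_SEED
    )


@pytest.fixture(scope="session")
def trained_ldm(trained_codec, train_pairs):
    """Conditional latent diffusion model over the trained codec's latents."""
    return train_ldm(
        trained_codec,
        [p.clean.values for p in train_pairs],
        [p.corrupted.values for p in train_pairs],
        t_total=200,
        n_steps=1500,
        batch_size=8,
        lr=2e-3,
        seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def trained_seg(train_pairs):
    """Segmentation U-Net trained on artifact-map-transfer samples."""
    clean_slices = [p.clean for p in train_pairs]
    samples = synthesize_seg_dataset(train_pairs, clean_slices, 1000, rng_seed=SUITE_SEED)
    return train_seg(samples, n_steps=400, batch_size=8, lr=2e-3, seed=SUITE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
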