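"""Shared fixtures: small synthetic scenes used across the test modules."""

import numpy as np
import pytest

from locreset.synthetic import NCProgram, SceneConfig, generate_monolayer_movie


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 6-cell scene with programmed N/C = 2, no nucleoli."""
    cfg = SceneConfig(shape=(6, 1, 192, 192), n_cells=6,
                      nucleolus_fraction=0.0, read_noise_sd=0.0,
                      step_sigma_px=0.8, seed=11)
    movie, gt = generate_monolayer_movie(cfg, NCProgram.constant(6, 2.0))
    return cfg, movie, gt


@pytest.fixture(scope="session")
def noisy_scene():
    """Scene at realistic SNR (read noise sd 6 on ~300-count nuclei)."""
    cfg = SceneConfig(shape=(8, 1, 192, 192), n_cells=6,
                      nucleolus_fraction=0.10, read_noise_sd=6.0,
                      step_sigma_px=1.0, seed=5)
    movie, gt = generate_monolayer_movie(cfg, NCProgram.constant(6, 2.0))
    return cfg, movie, gt


@pytest.fixture
def rng():
    return np.random.default_rng(42)
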