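"""Shared fixtures: small kernels, simple scenes and gaze configurations."""

import numpy as np
import pytest

from multisal.heatmap_builder import GaussianKernelSpec
from multisal.synthetic_data import (
    Attractor,
    GazeSimConfig,
    Region,
    SceneSpec,
)

#: means in [0,1] for 8 bands with NIR (bands 7-8) elevated
VEG_MEANS = (0.15, 0.2, 0.25, 0.2, 0.2, 0.15, 0.8, 0.85)
FLAT_MEANS = (0.5,) * 8


@pytest.fixture
def small_kernel() -> GaussianKernelSpec:
    """Unit-sum Gaussian small enough for fast tests (R >= 3 sigma holds)."""
    return GaussianKernelSpec(radius=15, sigma=5.0)


@pytest.fixture
def paper_kernel() -> GaussianKernelSpec:
    """The production smoothing kernel: R = 100 px, sigma = 20 px."""
    return GaussianKernelSpec(radius=100, sigma=20.0)


@pytest.fixture
def flat_scene_spec() -> SceneSpec:
    """One full-frame noiseless region of 0.5 in every band."""
    return SceneSpec(
        seed=7, width=64, height=48, regions=[Region(0, 0, 64, 48, FLAT_MEANS, 0.0)]
    )


@pytest.fixture
def veg_scene_spec() -> SceneSpec:
    """Background plus an NIR-bright 'vegetation' region."""
    return SceneSpec(
        seed=11,
        width=96,
        height=96,
        regions=[
            Region(0, 0, 96, 96, FLAT_MEANS, 0.02),
            Region(48, 48, 90, 90, VEG_MEANS, 0.02),
        ],
    )


@pytest.fixture
def single_attractor_cfg() -> GazeSimConfig:
    """Deterministic gaze: one attractor, zero spread, zero noise, no dropout."""
    return GazeSimConfig(
        seed=3,
        attractors=[Attractor(40.0, 30.0, 1.0, spread=0.0)],
        n_observers=1,
        image_duration=2.0,
        binocular_offset_sd=0.0,
        validity_dropout_rate=0.0,
    )


@pytest.fixture
def three_attractor_cfg() -> GazeSimConfig:
    return GazeSimConfig(
        seed=5,
        attractors=[
            Attractor(60.0, 60.0, 0.6, spread=10.0),
            Attractor(150.0, 50.0, 0.25, spread=10.0),
            Attractor(100.0, 150.0, 0.15, spread=10.0),
        ],
        n_observers=4,
        image_duration=4.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
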