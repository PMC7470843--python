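import numpy as np
import pytest

from spbquant.config import (AsymmetryConfig, GeometryConfig, NoiseConfig,
                             OpticsConfig)
from spbquant import spotfit, synth


@pytest.fixture
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture
def noise() -> NoiseConfig:
    return NoiseConfig()


@pytest.fixture
def in_plane_geometry() -> GeometryConfig:
    """Geometry without top-view scenes, for recovery tests."""
    return GeometryConfig(top_view_fraction=0.0)


@pytest.fixture
def pair_scene_factory(optics, in_plane_geometry):
    """Render a two-SPB scene and return (stack, truth, seed points)."""

    def make(seed=0, stage="short_spindle_lt1", asymmetry=None, noise=None,
             noise_seed=None):
        truth = synth.build_scene(
            stage, asymmetry=asymmetry or AsymmetryConfig(),
            geometry=in_plane_geometry, seed=seed)
        stack = synth.render(truth, optics, noise=noise,
                             seed=seed + 1 if noise_seed is None
                             else noise_seed)
        a = stack.to_stack_coords(truth.old_position)
        b = stack.to_stack_coords(truth.new_position)
        return stack, truth, (a, b)

    return make


@pytest.fixture
def fit_pair(optics):
    """Dual-fit the reference channel of a rendered pair scene."""

    def fit(stack, a, b):
        roi = spotfit.default_roi(stack, [a, b], optics.psf_sigma_xy,
                                  optics.psf_sigma_z)
        return spotfit.fit_double(stack, 0, roi, a, b,
                                  init_sigma_xy=optics.psf_sigma_xy,
                                  init_sigma_z=optics.psf_sigma_z)

    return fit
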