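"""Spot-fit recovery against the forward-model ground truth."""

import numpy as np
import pytest

from spbquant import realign, spotfit, synth
from spbquant.config import AsymmetryConfig, NoiseConfig, OpticsConfig
from spbquant.synth import QUERY_CHANNEL


def _single_emitter_stack(optics, flux=10000.0, noise=None, seed=0,
                          origin_shift=None):
    t = synth.build_scene("unduplicated", seed=5)
    t.emitters = [synth.Emitter(np.array([300.0, 280.0, 450.0]), flux,
                                0, "outer_plaque")]
    kwargs = {}
    if origin_shift is not None:
        base = synth.render(t, optics, noise=None)
        kwargs = {"shape_zyx": base.shape_zyx,
                  "origin_nm": base.origin_nm + origin_shift}
    return t, synth.render(t, optics, noise=noise, seed=seed, **kwargs)


def test_noiseless_single_recovery_within_1nm(optics):
    t, stack = _single_emitter_stack(optics)
    pos = stack.to_stack_coords(t.emitters[0].position)
    roi = spotfit.roi_around(stack, [pos], 250, 500)
    fit = spotfit.fit_single(stack, 0, roi, pos + [15, -10, 30],
                             init_sigma_xy=optics.psf_sigma_xy,
                             init_sigma_z=optics.psf_sigma_z)
    assert np.linalg.norm(fit.center - pos) < 1.0
    assert fit.amplitude == pytest.approx(10000.0, rel=0.01)
    assert fit.converged


def test_constant_roi_is_degenerate(optics):
    stack = synth.ImageStack(pixels=np.full((1, 6, 10, 10), 3.0),
                             channels=["c"], voxel_xy=40.0, voxel_z=125.0)
    roi = spotfit.Roi(z=(0, 6), y=(0, 10), x=(0, 10))
    with pytest.raises(spotfit.DegenerateRoiError):
        spotfit.fit_single(stack, 0, roi, np.array([200.0, 200.0, 375.0]))


def test_translation_equivariance(optics):
    shift = np.array([optics.voxel_xy, 0.0, -optics.voxel_z])
    t, s0 = _single_emitter_stack(optics)
    _, s1 = _single_emitter_stack(optics, origin_shift=shift)
    fits = []
    for stack in (s0, s1):
        pos = stack.to_stack_coords(t.emitters[0].position)
        roi = spotfit.roi_around(stack, [pos], 250, 500)
        fits.append(spotfit.fit_single(stack, 0, roi, pos,
                                       init_sigma_xy=optics.psf_sigma_xy,
                                       init_sigma_z=optics.psf_sigma_z))
    np.testing.assert_allclose(fits[0].center - fits[1].center, shift,
                               atol=1e-3)


class TestFitDouble:
    def test_noiseless_pair_recovery(self, optics, pair_scene_factory,
                                     fit_pair):
        stack, truth, (a, b) = pair_scene_factory(seed=12)
        fa, fb = fit_pair(stack, a, b)
        assert np.linalg.norm(fa.center - a) < 2.0
        assert np.linalg.norm(fb.center - b) < 2.0
        assert abs(fa.distance_to(fb) - truth.inter_distance) < 3.0

    def test_amplitude_ratio_recovery(self, optics, pair_scene_factory,
                                      fit_pair):
        asym = AsymmetryConfig(ref_old_new_fold=3.0)
        stack, truth, (a, b) = pair_scene_factory(seed=8, asymmetry=asym)
        fa, fb = fit_pair(stack, a, b)
        assert fa.amplitude / fb.amplitude == pytest.approx(3.0, rel=0.02)

    def test_identical_inits_rejected(self, optics, pair_scene_factory):
        stack, truth, (a, b) = pair_scene_factory(seed=1)
        roi = spotfit.default_roi(stack, [a, b], 50, 140)
        with pytest.raises(ValueError, match="distinct"):
            spotfit.fit_double(stack, 0, roi, a, a)

    def test_double_residual_not_worse_than_single(self, optics,
                                                   pair_scene_factory,
                                                   fit_pair):
        stack, truth, (a, b) = pair_scene_factory(seed=3,
                                                  noise=NoiseConfig())
        roi = spotfit.default_roi(stack, [a, b], optics.psf_sigma_xy,
                                  optics.psf_sigma_z)
        fa, _ = spotfit.fit_double(stack, 0, roi, a, b,
                                   init_sigma_xy=50, init_sigma_z=140)
        singles = [spotfit.fit_single(stack, 0, roi, c, init_sigma_xy=50,
                                      init_sigma_z=140) for c in (a, b)]
        assert fa.rss <= min(s.rss for s in singles) * (1 + 1e-9)


class TestEdgeSliceExclusion:
    def _pair_at_z(self, optics, z_ref, z_query):
        """Both SPB channels rendered with controllable emitter z."""
        emitters = [
            synth.Emitter(np.array([300.0, 300.0, z_ref]), 10000.0, 0,
                          "inner_plaque"),
            synth.Emitter(np.array([700.0, 300.0, z_ref]), 8000.0, 0,
                          "inner_plaque"),
            synth.Emitter(np.array([300.0, 300.0, z_query]), 9000.0, 1,
                          "outer_plaque"),
            synth.Emitter(np.array([700.0, 300.0, z_query]), 9000.0, 1,
                          "outer_plaque"),
        ]
        t = synth.build_scene("side_by_side", seed=0)
        t.emitters = emitters
        stack = synth.render(t, OpticsConfig(), noise=None,
                             shape_zyx=(8, 16, 26),
                             origin_nm=np.zeros(3))
        fits = []
        for e in emitters[:2]:
            fits.append(spotfit.SpotFit(
                center=e.position, sigma_xy=50.0, sigma_z=140.0,
                amplitude=e.amplitude, background=2.0, rss=0.0,
                converged=True))
        return stack, spotfit.SPBPair(fit_old=fits[0], fit_new=fits[1])

    def test_max_in_first_slice_excluded(self, optics):
        stack, pair = self._pair_at_z(optics, z_ref=62.5, z_query=500.0)
        out = spotfit.edge_slice_exclusion(stack, [0, 1], pair)
        assert out.excluded and out.reason == "edge_slice"

    def test_mid_stack_retained(self, optics):
        stack, pair = self._pair_at_z(optics, z_ref=500.0, z_query=500.0)
        assert not spotfit.edge_slice_exclusion(stack, [0, 1], pair).excluded

    def test_query_channel_alone_triggers_exclusion(self, optics):
        nz = 8
        z_last = (nz - 0.5) * 125.0
        stack, pair = self._pair_at_z(optics, z_ref=500.0, z_query=z_last)
        out = spotfit.edge_slice_exclusion(stack, [0, 1], pair)
        assert out.excluded and out.reason == "edge_slice"


def test_find_seeds_locates_pair(optics, pair_scene_factory):
    stack, truth, (a, b) = pair_scene_factory(seed=21, noise=NoiseConfig())
    seeds = spotfit.find_seeds(stack, 0, min_distance_nm=150.0)
    assert len(seeds) == 2
    errs = [min(np.linalg.norm(s - a), np.linalg.norm(s - b)) for s in seeds]
    assert max(errs) < 1.5 * optics.voxel_xy * np.sqrt(3)
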