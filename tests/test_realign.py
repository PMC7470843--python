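"""Old/new assignment and realignment geometry contracts."""

import numpy as np
import pytest

from spbquant import metrics, realign, spotfit, synth
from spbquant.config import OpticsConfig


def _spot(x, y, z, amp, sxy=50.0, sz=140.0, bg=2.0):
    return spotfit.SpotFit(center=np.array([x, y, z], dtype=float),
                           sigma_xy=sxy, sigma_z=sz, amplitude=amp,
                           background=bg, rss=0.0, converged=True)


class TestAssignOldNew:
    def test_brighter_is_old(self):
        a, b = _spot(0, 0, 0, 100.0), _spot(300, 0, 0, 40.0)
        old, new, tie = realign.assign_old_new(a, b)
        assert old is a and new is b and not tie

    def test_order_independent(self):
        a, b = _spot(0, 0, 0, 40.0), _spot(300, 0, 0, 100.0)
        old, new, tie = realign.assign_old_new(a, b)
        assert old is b and new is a and not tie

    def test_equal_amplitudes_tie_break_on_x(self):
        a, b = _spot(500, 0, 0, 70.0), _spot(100, 0, 0, 70.0)
        old, new, tie = realign.assign_old_new(a, b)
        assert tie
        assert old is b  # smaller x wins the tie


def _refit_pair(img, optics):
    stack = img.to_stack()
    o, n = img.old_center_out, img.new_center_out
    roi = spotfit.default_roi(stack, [o, n], optics.psf_sigma_xy,
                              optics.psf_sigma_z)
    return spotfit.fit_double(stack, 0, roi, o, n,
                              init_sigma_xy=optics.psf_sigma_xy,
                              init_sigma_z=optics.psf_sigma_z)


class TestRealignStack:
    def test_axis_already_on_x_is_identity(self, optics):
        """A pair on +x through the grid centre resamples onto itself."""
        t = synth.build_scene("unduplicated", seed=0)
        shape = (10, 40, 40)
        extent = np.array([shape[2] * 40.0, shape[1] * 40.0,
                           shape[0] * 125.0])
        mid = extent / 2
        d = 400.0
        t.emitters = [
            synth.Emitter(mid - [d / 2, 0, 0], 10000.0, 0, "inner_plaque"),
            synth.Emitter(mid + [d / 2, 0, 0], 6000.0, 0, "inner_plaque"),
        ]
        stack = synth.render(t, optics, noise=None, shape_zyx=shape,
                             origin_nm=np.zeros(3))
        old = _spot(*(mid - [d / 2, 0, 0]), 10000.0, bg=optics.background)
        new = _spot(*(mid + [d / 2, 0, 0]), 6000.0, bg=optics.background)
        img = realign.realign_stack(stack, old, new,
                                    field_nm=tuple(extent))
        scale = stack.pixels.max()
        np.testing.assert_allclose(img.pixels, stack.pixels,
                                   atol=1e-6 * scale)

    def test_pair_along_y_lands_on_x_axis(self, optics, fit_pair,
                                          pair_scene_factory):
        stack, truth, (a, b) = pair_scene_factory(seed=7)
        fa, fb = fit_pair(stack, a, b)
        old, new, _ = realign.assign_old_new(fa, fb)
        img = realign.realign_stack(stack, old, new)
        f1, f2 = _refit_pair(img, optics)
        for f, c in ((f1, img.old_center_out), (f2, img.new_center_out)):
            assert abs(f.center[1] - c[1]) < 1.0
            assert abs(f.center[2] - c[2]) < 1.0
        assert abs(f1.distance_to(f2) - old.distance_to(new)) < 2.0
        # old (brighter) on the left
        assert f1.center[0] < f2.center[0]
        assert f1.amplitude > f2.amplitude

    def test_intensity_conserved(self, optics, fit_pair, pair_scene_factory):
        stack, truth, (a, b) = pair_scene_factory(seed=9)
        fa, fb = fit_pair(stack, a, b)
        old, new, _ = realign.assign_old_new(fa, fb)
        img = realign.realign_stack(stack, old, new)
        bg = optics.background
        sig_in = (stack.pixels[0] - bg).sum()
        sig_out = (img.pixels[0] - bg).sum()
        assert sig_out == pytest.approx(sig_in, rel=0.01)

    def test_idempotent_within_1nm(self, optics, fit_pair,
                                   pair_scene_factory):
        stack, truth, (a, b) = pair_scene_factory(seed=4)
        fa, fb = fit_pair(stack, a, b)
        old, new, _ = realign.assign_old_new(fa, fb)
        img1 = realign.realign_stack(stack, old, new)
        f1, f2 = _refit_pair(img1, optics)
        o2, n2, _ = realign.assign_old_new(f1, f2)
        img2 = realign.realign_stack(img1.to_stack(), o2, n2)
        g1, g2 = _refit_pair(img2, optics)
        d1 = g1.center - img2.old_center_out
        d0 = f1.center - img1.old_center_out
        assert np.linalg.norm(d1 - d0) < 1.0

    def test_coincident_centres_rejected(self):
        s = _spot(100, 100, 100, 10.0)
        stack = synth.ImageStack(pixels=np.zeros((1, 4, 8, 8)) + 1.0,
                                 channels=["c"], voxel_xy=40, voxel_z=125)
        with pytest.raises(ValueError, match="coincident"):
            realign.realign_stack(stack, s, s)

    def test_asymmetry_index_rotation_invariant(self, optics, fit_pair,
                                                pair_scene_factory):
        """The index measured before and after realignment agrees to 2%."""
        from spbquant.config import AsymmetryConfig

        asym = AsymmetryConfig(ref_old_new_fold=2.0)
        stack, truth, (a, b) = pair_scene_factory(seed=6, asymmetry=asym)
        fa, fb = fit_pair(stack, a, b)
        idx_before = metrics.asymmetry_index(fa.amplitude, fb.amplitude)
        old, new, _ = realign.assign_old_new(fa, fb)
        img = realign.realign_stack(stack, old, new)
        f1, f2 = _refit_pair(img, optics)
        idx_after = metrics.asymmetry_index(f1.amplitude, f2.amplitude)
        assert idx_after == pytest.approx(idx_before, abs=0.02)


class TestMaxProject:
    def test_single_slice_range(self):
        arr = np.random.default_rng(0).random((1, 5, 6, 6))
        proj = realign.max_project(arr, z_range=(2, 3))
        np.testing.assert_array_equal(proj, arr[:, 2])

    def test_constant_stack(self):
        proj = realign.max_project(np.full((4, 5, 5), 7.0))
        np.testing.assert_array_equal(proj, np.full((5, 5), 7.0))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            realign.max_project(np.zeros((1, 4, 4, 4)), z_range=(3, 3))

    def test_projection_peaks_at_lateral_emitter_positions(self, optics):
        t = synth.build_scene("unduplicated", seed=0)
        t.emitters = [
            synth.Emitter(np.array([260.0, 620.0, 500.0]), 10000.0, 0,
                          "inner_plaque"),
            synth.Emitter(np.array([860.0, 620.0, 700.0]), 8000.0, 0,
                          "outer_plaque"),
        ]
        stack = synth.render(t, OpticsConfig(background=0.0), noise=None,
                             shape_zyx=(10, 30, 28), origin_nm=np.zeros(3))
        proj = realign.max_project(stack.pixels)[0]
        # two brightest separated lateral maxima at the emitter (y, x) voxels
        from skimage.feature import peak_local_max
        peaks = peak_local_max(proj, min_distance=3, num_peaks=2)
        got = {tuple(p) for p in peaks}
        want = {(15, 6), (15, 21)}
        assert got == want
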