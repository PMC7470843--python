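"""Wide-field projection, windowed intensities, reference normalisation."""

import numpy as np
import pytest
from scipy import stats

from spbquant import spotfit, synth, widefield as wf
from spbquant.config import (AsymmetryConfig, GeometryConfig, NoiseConfig,
                             OpticsConfig, widefield_optics)
from spbquant.image_io import ImageStack


def _flat_stack(value=5.0, planes=5, side=41):
    return ImageStack(pixels=np.full((1, planes, side, side), value),
                      channels=["q"], voxel_xy=129.0, voxel_z=800.0)


class TestProjectStack:
    def test_single_plane_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.random((2, 1, 8, 8))
        stack = ImageStack(pixels=arr, channels=["a", "b"], voxel_xy=129,
                           voxel_z=800)
        np.testing.assert_array_equal(wf.project_stack(stack), arr[:, 0])

    def test_projection_dominates_single_planes(self, noise):
        t = synth.build_scene("unduplicated", seed=2)
        stack = synth.render(t, widefield_optics(), noise=noise, seed=1)
        proj = wf.project_stack(stack)
        for z in range(stack.pixels.shape[1]):
            assert np.all(proj >= stack.pixels[:, z])


class TestWindowIntensity:
    def test_constant_image_fully_background_corrected(self):
        m = wf.window_intensity(np.full((41, 41), 6.0), (20, 20), side=7,
                                background_per_px=6.0)
        assert m.corrected == pytest.approx(0.0)
        assert m.raw_sum == pytest.approx(49 * 6.0)

    def test_spot_flux_recovered_within_2pc(self):
        """A diffraction-limited spot inside the window integrates to its
        flux (analytic Gaussian integral oracle)."""
        opt = widefield_optics()
        t = synth.build_scene("unduplicated", seed=0)
        t.emitters = [synth.Emitter(np.array([2580.0, 2580.0, 2000.0]),
                                    20000.0, 0, "outer_plaque")]
        opt0 = OpticsConfig(**{**opt.model_dump(), "background": 0.0})
        stack = synth.render(t, opt0, noise=None, shape_zyx=(5, 40, 40),
                             origin_nm=np.zeros(3))
        proj = stack.pixels.sum(axis=1)[0]  # integrate z, not max-project
        px = (int(2580.0 // 129.0), int(2580.0 // 129.0))
        m = wf.window_intensity(proj, px, side=7, background_per_px=0.0)
        assert m.corrected == pytest.approx(20000.0, rel=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        img = rng.random((41, 41))
        m1 = wf.window_intensity(img, (20, 20), 7, background_per_px=0.1)
        m2 = wf.window_intensity(2 * img, (20, 20), 7, background_per_px=0.2)
        assert m2.corrected == pytest.approx(2 * m1.corrected)

    def test_clipped_window_rejected(self):
        with pytest.raises(ValueError, match="border"):
            wf.window_intensity(np.zeros((20, 20)), (2, 10), side=7,
                                background_per_px=0.0)

    def test_annulus_background_estimate(self):
        img = np.full((61, 61), 3.0)
        img[28:33, 28:33] = 100.0  # bright spot inside the window
        assert wf.annulus_background(img, (30, 30), side=7) == 3.0


class TestRelativeLabel:
    def test_equal_query_and_reference(self):
        m = wf.WindowMeasurement((0, 0), 7, 10.0, 0.0, 10.0)
        assert wf.relative_label(m, m) == 1.0

    def test_equal_ratios_give_zero_index(self):
        rec = wf.widefield_asymmetry(0.8, 0.8)
        assert rec.index == 0.0
        assert rec.basis == "widefield_ref_normalized"

    def test_fourfold_query_at_equal_reference(self):
        assert wf.widefield_asymmetry(4.0, 1.0).index == pytest.approx(0.6)

    def test_nonpositive_reference_rejected(self):
        q = wf.WindowMeasurement((0, 0), 7, 10.0, 0.0, 10.0)
        r = wf.WindowMeasurement((0, 0), 7, 10.0, 10.0 / 49, 0.0)
        with pytest.raises(ValueError):
            wf.relative_label(q, r)

    def test_illumination_scaling_cancels(self):
        q = wf.WindowMeasurement((0, 0), 7, 12.0, 0.0, 12.0)
        r = wf.WindowMeasurement((0, 0), 7, 4.0, 0.0, 4.0)
        k = 3.7
        qk = wf.WindowMeasurement((0, 0), 7, k * 12.0, 0.0, k * 12.0)
        rk = wf.WindowMeasurement((0, 0), 7, k * 4.0, 0.0, k * 4.0)
        assert wf.relative_label(qk, rk) == pytest.approx(
            wf.relative_label(q, r))


def _wf_index(truth, noise, seed):
    stack = synth.render(truth, widefield_optics(), noise=noise, seed=seed)
    proj = wf.project_stack(stack)
    rels = []
    for pos in (truth.old_position, truth.new_position):
        p = stack.to_stack_coords(pos)
        px = wf.locate_spb(proj[0], (int(p[0] / stack.voxel_xy),
                                     int(p[1] / stack.voxel_xy)))
        mref = wf.window_intensity(proj[0], px, 7)
        mq = wf.window_intensity(proj[1], px, 7)
        rels.append(max(mq.corrected, 0.0) / max(mref.corrected, 1e-9))
    return abs(rels[0] - rels[1]) / (rels[0] + rels[1])


def _sim_index(truth, optics, noise, seed):
    stack = synth.render(truth, optics, noise=noise, seed=seed)
    ops = []
    for pos, sgn in ((truth.old_position, -1), (truth.new_position, 1)):
        c = stack.to_stack_coords(pos + sgn * 150.0 * truth.spb_axis)
        roi = spotfit.roi_around(stack, [c], 200, 420)
        f = spotfit.fit_single(stack, 1, roi, c, init_sigma_xy=50,
                               init_sigma_z=140, sigma_bounds=(0.7, 1.4),
                               center_halfwidth_nm=80)
        ops.append(f.amplitude)
    return abs(ops[0] - ops[1]) / (ops[0] + ops[1] + 1e-12)


def test_widefield_and_sim_rank_asymmetry_identically(optics, noise,
                                                      in_plane_geometry):
    """Matched synthetic spindles measured by both pipelines give rank
    correlation > 0.9 across a 100-scene fold sweep."""
    rng = np.random.default_rng(0)
    wf_idx, sim_idx = [], []
    for i in range(100):
        fold = float(np.exp(rng.uniform(0.0, np.log(12.0))))
        asym = AsymmetryConfig(ip_op_ratio=0.0, old_new_fold=fold,
                               ref_old_new_fold=1.0)
        t = synth.build_scene("spindle_1_2p5", asymmetry=asym,
                              geometry=in_plane_geometry, seed=1000 + i)
        wf_idx.append(_wf_index(t, noise, seed=i))
        sim_idx.append(_sim_index(t, optics, noise, seed=50000 + i))
    rho = stats.spearmanr(wf_idx, sim_idx).statistic
    assert rho > 0.9
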