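"""Asymmetry index, mode classifier, staging, top-view rule, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spbquant import metrics, spotfit, synth
from spbquant.config import GeometryConfig
from spbquant.metrics import (NoLabelError, PlaqueMeasurement,
                              UndefinedIndexError, asymmetry_index,
                              classify_mode, ip_op_ratio, is_top_view,
                              stage_by_distance, summarize_distribution)


class TestAsymmetryIndex:
    def test_direct_values(self):
        assert asymmetry_index(0.7, 0.7) == 0.0
        assert asymmetry_index(0.7, 0.0) == 1.0
        assert asymmetry_index(9.0, 1.0) == pytest.approx(0.8)

    def test_undefined_for_zero_total(self):
        with pytest.raises(UndefinedIndexError):
            asymmetry_index(0.0, 0.0)
        with pytest.raises(ValueError):
            asymmetry_index(-1.0, 2.0)

    @settings(derandomize=True)
    @given(a=st.floats(0.0, 1e6), b=st.floats(0.0, 1e6),
           k=st.floats(1e-3, 1e3))
    def test_symmetry_scale_invariance_and_bounds(self, a, b, k):
        if a + b == 0 or k * (a + b) == 0:
            return
        idx = asymmetry_index(a, b)
        assert 0.0 <= idx <= 1.0
        assert idx == asymmetry_index(b, a)
        assert asymmetry_index(k * a, k * b) == pytest.approx(idx, abs=1e-9)


class TestIpOpRatio:
    def test_unit_ratio(self):
        assert ip_op_ratio(PlaqueMeasurement(5.0, 5.0, "old")) == 1.0

    def test_one_sided_flagged_without_ratio(self):
        m = PlaqueMeasurement(5.0, 0.0, "new")
        assert m.one_sided
        assert ip_op_ratio(m) is None

    def test_noisy_population_recovers_generating_ratio(
            self, optics, in_plane_geometry):
        """Mean fitted IP:OP over noisy single-SPB scenes ~ truth 2.5."""
        from spbquant.config import AsymmetryConfig, NoiseConfig

        ratios = []
        for seed in range(30):
            t = synth.build_scene(
                "unduplicated", asymmetry=AsymmetryConfig(ip_op_ratio=2.5),
                geometry=in_plane_geometry, seed=seed)
            stack = synth.render(t, optics, noise=NoiseConfig(), seed=seed)
            ip = stack.to_stack_coords(t.old_position)
            op = stack.to_stack_coords(
                t.old_position + 150.0 * t.plaque_axis)
            roi = spotfit.default_roi(stack, [ip, op], 50, 140)
            fi, fo = spotfit.fit_double(stack, 1, roi, ip, op,
                                        init_sigma_xy=50, init_sigma_z=140)
            m = PlaqueMeasurement(fi.amplitude, fo.amplitude, "old")
            ratios.append(ip_op_ratio(m))
        assert np.mean(ratios) == pytest.approx(2.5, abs=0.2)


class TestClassifyMode:
    @pytest.mark.parametrize("i_old,i_new,expected", [
        (10.0, 1.0, "strongly_asymmetric"),   # 10-fold
        (8.0, 1.0, "strongly_asymmetric"),    # boundary: at least 8-fold
        (7.99, 1.0, "asymmetric"),
        (1.3, 1.0, "asymmetric"),             # boundary belongs to A
        (1.1, 1.0, "symmetric"),              # under 1.3-fold
        (1.0, 1.0, "symmetric"),
        (1.0, 2.0, "asymmetric"),             # order-free
    ])
    def test_fold_boundaries(self, i_old, i_new, expected):
        assert classify_mode(i_old, i_new, detect_floor=0.1) == expected

    def test_dim_pole_below_floor_is_one_pole(self):
        assert classify_mode(10.0, 0.05, detect_floor=0.1) == "one_pole"

    def test_no_label_raises(self):
        with pytest.raises(NoLabelError):
            classify_mode(0.01, 0.02, detect_floor=0.1)

    @settings(derandomize=True)
    @given(r=st.floats(1.0, 100.0), scale=st.floats(0.1, 10.0))
    def test_monotone_in_fold_ratio(self, r, scale):
        """Increasing the fold never moves the class toward symmetric."""
        rank = {"symmetric": 0, "asymmetric": 1, "strongly_asymmetric": 2}
        lo = classify_mode(scale * r, scale, detect_floor=0.0)
        hi = classify_mode(scale * (r + 1.0), scale, detect_floor=0.0)
        assert rank[hi] >= rank[lo]


class TestStaging:
    @pytest.mark.parametrize("d,label", [
        (0.0, "unseparated"),
        (0.2, "unseparated"),
        (0.35, "spindle_lt_1um"),     # boundary assigned rightward
        (0.99, "spindle_lt_1um"),
        (1.0, "spindle_1_2p5um"),
        (2.5, "spindle_1_2p5um"),
        (2.51, "elongated_gt_2p5um"),
        (3.0, "elongated_gt_2p5um"),
    ])
    def test_boundaries(self, d, label):
        assert stage_by_distance(d).label == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stage_by_distance(-0.1)

    @settings(derandomize=True)
    @given(d=st.floats(0.0, 50.0, allow_nan=False))
    def test_partition_is_exact(self, d):
        assert stage_by_distance(d).label in metrics.STAGE_LABELS


def _fit_at(pos):
    return spotfit.SpotFit(center=np.asarray(pos, dtype=float), sigma_xy=50.0,
                           sigma_z=140.0, amplitude=1.0, background=0.0,
                           rss=0.0, converged=True)


class TestTopView:
    def test_axis_along_z_is_top_view(self):
        assert is_top_view(_fit_at([0, 0, 0]), _fit_at([0, 0, 150.0]),
                           sigma_xy=50.0)

    def test_axis_in_plane_is_not(self):
        assert not is_top_view(_fit_at([0, 0, 0]), _fit_at([150.0, 0, 0]),
                               sigma_xy=50.0)

    def test_flagged_fraction_tracks_generated_top_view_fraction(self):
        """Scenes generated with 12% plaque-axis-vertical orientations are
        flagged at ~12% by the lateral-overlap rule."""
        geom = GeometryConfig(top_view_fraction=0.12)
        hits, truths = [], []
        for i in range(400):
            top = (i % 100) < 12  # exact 12% by construction
            t = synth.build_scene("unduplicated", geometry=geom, seed=i,
                                  top_view=top)
            ip = _fit_at(t.old_position)
            op = _fit_at(t.old_position + 150.0 * t.plaque_axis)
            hits.append(is_top_view(ip, op, sigma_xy=50.0))
            truths.append(top)
        assert np.mean(hits) == pytest.approx(0.12, abs=0.02)
        assert hits == truths


class TestSummaries:
    def test_centiles_of_1_to_100(self):
        s = summarize_distribution(np.arange(1.0, 101.0))
        assert s["p5"] == pytest.approx(5.95)
        assert s["median"] == pytest.approx(50.5)
        assert s["p95"] == pytest.approx(95.05)
        assert s["notch_high"] - s["notch_low"] == pytest.approx(
            2 * 1.58 * (s["p75"] - s["p25"]) / 10.0)

    def test_constant_sample(self):
        s = summarize_distribution([7.0] * 5)
        assert s["p5"] == s["p95"] == 7.0
        assert s["notch_low"] == s["notch_high"] == 7.0

    def test_single_value(self):
        s = summarize_distribution([3.0])
        assert s["median"] == 3.0 and s["n"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([])
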