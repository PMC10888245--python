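"""Synthetic movie generator: OU dynamics, WLC arms, rendering, ground truth."""

import math

import numpy as np
import pytest

from lamhinge.core_io import TipModel
from lamhinge.synth_movie import (
    HingedRodParams,
    generate_movie,
    ou_angle_series,
    render_frame,
    s_shape_backbone,
    sample_backbone,
)
from lamhinge.trace_analysis import contour_length, end_to_end


class TestOuAngleSeries:
    def test_zero_sd_is_constant(self):
        series = ou_angle_series(63.0, 0.0, 2.0, 1 / 3, 50, rng=1)
        assert np.all(series == 63.0)

    def test_stationary_moments_and_lag1_autocorrelation(self):
        # closed-form OU: mean 63, lag-1 autocorr exp(-dt/tau) = exp(-1/6)
        series = ou_angle_series(63.0, 25.0, 2.0, 1 / 3, 10_000, rng=42)
        assert series.mean() == pytest.approx(63.0, abs=1.0)
        lag1 = np.corrcoef(series[:-1], series[1:])[0, 1]
        assert lag1 == pytest.approx(math.exp(-1 / 6), abs=0.02)

    def test_same_seed_same_series(self):
        a = ou_angle_series(63.0, 25.0, 2.0, 1 / 3, 100, rng=7)
        b = ou_angle_series(63.0, 25.0, 2.0, 1 / 3, 100, rng=7)
        assert np.array_equal(a, b)

    def test_clamped_to_fold_magnitude_range(self):
        series = ou_angle_series(10.0, 40.0, 1.0, 1 / 3, 2000, rng=3)
        assert series.min() >= 0.0 and series.max() <= 180.0


class TestSampleBackbone:
    def test_stiff_limit_straight(self, stiff_straight_params, rng):
        pts, hinge_idx = sample_backbone(stiff_straight_params, 180.0, rng)
        total = stiff_straight_params.arm1_length + stiff_straight_params.arm2_length
        assert end_to_end(pts) == pytest.approx(total, rel=1e-3)
        assert contour_length(pts) == pytest.approx(total, rel=1e-3)

    def test_stiff_limit_right_angle(self, stiff_straight_params, rng):
        p = stiff_straight_params
        pts, _ = sample_backbone(p, 90.0, rng)
        expect = math.hypot(p.arm1_length, p.arm2_length)
        assert end_to_end(pts) == pytest.approx(expect, rel=1e-3)

    def test_hinge_index_splits_arms_at_requested_lengths(self, default_params, rng):
        pts, hinge_idx = sample_backbone(default_params, 63.0, rng)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc1 = seg[:hinge_idx].sum()
        assert arc1 == pytest.approx(default_params.arm1_length, rel=0.02)

    def test_wlc_mean_squared_end_to_end_matches_increment_oracle(self):
        # independent Monte-Carlo oracle built directly from the increment
        # model (tangent-angle Gaussian steps of variance step/Lp)
        lp, length, step = 200.0, 33.0, 0.5
        n_seg = int(round(length / step))
        rng = np.random.default_rng(123)

        def oracle_sample():
            theta = np.concatenate([
                [0.0],
                np.cumsum(rng.normal(0, math.sqrt(step / lp), n_seg - 1)),
            ])
            xy = step * np.column_stack([np.cos(theta), np.sin(theta)])
            return np.linalg.norm(xy.sum(axis=0))

        oracle_r2 = np.mean([oracle_sample() ** 2 for _ in range(4000)])

        params = HingedRodParams(arm1_length=33.0, arm2_length=34.0,
                                 persistence_length=lp, pixel_size=1.0)
        rng2 = np.random.default_rng(321)
        r1_sq = []
        for _ in range(1000):
            pts, hinge_idx = sample_backbone(params, 180.0, rng2)
            r1_sq.append(np.linalg.norm(pts[hinge_idx] - pts[0]) ** 2)
        assert np.mean(r1_sq) == pytest.approx(oracle_r2, rel=0.05)

    def test_s_shape_reproduces_printed_scale(self, rng):
        pts = s_shape_backbone(rng=rng)
        assert contour_length(pts) == pytest.approx(66.0, abs=2.0)
        assert contour_length(pts) >= end_to_end(pts)


class TestRenderFrame:
    def test_noise_free_max_height_is_rod_height_and_width_broadened(
            self, stiff_straight_params, rng):
        p = HingedRodParams(mean_angle=180.0, angle_sd=0.0,
                            persistence_length=1e6, noise_sd=0.0)
        pts, _ = sample_backbone(p, 180.0, rng)
        pts = pts - pts.mean(axis=0) + 50.0
        topo, _ = render_frame(pts, p, TipModel(2.0, 5.0), rng, (100, 100),
                               with_lg=False)
        # dilation preserves the crest height exactly; only the raster
        # sampling of the crest line leaves sub-nm-scale quantization
        assert topo.heights.max() == pytest.approx(p.rod_height, abs=1e-4)
        mid_col = topo.heights[:, 50]
        apparent_width = (mid_col > 1e-9).sum() * p.pixel_size
        assert apparent_width > p.rod_width

    def test_empty_backbone_gives_noise_only_frame(self, default_params, rng):
        topo, lg = render_frame(np.empty((0, 2)), default_params,
                                TipModel(2.0, 5.0), rng, (32, 32))
        assert lg is None
        assert abs(float(topo.heights.mean())) < 0.1
        assert topo.heights.std() == pytest.approx(default_params.noise_sd, rel=0.2)

    def test_rod_halfwidth_matches_1d_dilation_oracle(self, rng):
        # ideal rod cross-section (semi-ellipse) dilated in 1-D on a dense
        # grid is the oracle for the apparent half-width at base
        p = HingedRodParams(mean_angle=180.0, angle_sd=0.0,
                            persistence_length=1e6, noise_sd=0.0,
                            pixel_size=0.25)
        tip = TipModel(2.0, 5.0)
        pts = np.array([[20.0, 30.0], [40.0, 30.0]])
        topo, _ = render_frame(pts, p, tip, rng, (240, 240), with_lg=False)
        col = int(30.0 / p.pixel_size)
        profile = topo.heights[:, int(120)]
        apparent_half = (profile > 1e-9).sum() * p.pixel_size / 2.0

        from lamhinge.afm_simulate import tip_apex_profile

        s = np.arange(-8.0, 8.0, 0.002)
        half_w = p.rod_width / 2.0
        cross = np.where(np.abs(s) <= half_w,
                         p.rod_height * np.sqrt(np.clip(1 - (s / half_w) ** 2, 0, None)),
                         0.0)
        dil = np.array([
            np.max(cross - tip_apex_profile(tip, np.abs(s - x))) for x in s
        ])
        oracle_half = s[dil > 1e-9].max()
        assert apparent_half == pytest.approx(oracle_half, abs=2 * p.pixel_size)

    def test_out_of_frame_backbone_reports_bounding_box(self, default_params, rng):
        pts = np.array([[1.0, 1.0], [90.0, 1.0]])
        with pytest.raises(ValueError, match="bounding box"):
            render_frame(pts, default_params, TipModel(2.0, 5.0), rng, (64, 64))


class TestGenerateMovie:
    def test_same_seed_bitwise_identical(self, default_params):
        m1, t1 = generate_movie(default_params, 3, seed=9)
        m2, t2 = generate_movie(default_params, 3, seed=9)
        for a, b in zip(m1.frames, m2.frames):
            assert np.array_equal(a.heights, b.heights)
        assert t1.hinge_angle == t2.hinge_angle

    def test_single_frame_movie(self, default_params):
        movie, truth = generate_movie(default_params, 1, seed=2)
        assert len(movie) == 1 and len(truth) == 1

    def test_ground_truth_angle_population_mean(self):
        # a short relaxation time makes the frames nearly independent, so
        # the sample mean concentrates on the stationary mean (the default
        # tau = 2 s at 3 fps leaves only ~n/12 effective samples)
        p = HingedRodParams(angle_relax_time=0.1)
        movie, truth = generate_movie(p, 1000, seed=4)
        assert np.nanmean(truth.hinge_angle) == pytest.approx(63.0, abs=2.0)

    def test_contour_never_below_end_to_end(self, bent_movie):
        _, truth = bent_movie
        for cl, e2e in zip(truth.contour_length, truth.end_to_end):
            assert cl >= e2e

    def test_noise_free_image_dominates_true_surface(self):
        p = HingedRodParams(noise_sd=0.0)
        movie, truth = generate_movie(p, 1, seed=6)
        # dilation property: image >= 0 everywhere, crest equals rod height
        img = movie.frames[0].heights
        assert img.min() >= -1e-12
        assert img.max() >= p.rod_height - 1e-9
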