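"""Morphometry: segmentation, tracing, circle fits, kink detection, tracking."""

import math

import numpy as np
import pytest

from lamhinge.core_io import Topograph
from lamhinge.synth_movie import HingedRodParams, generate_movie
from lamhinge import trace_analysis as ta


class TestSegmentation:
    def test_flat_noise_has_no_molecules(self):
        rng = np.random.default_rng(0)
        topo = Topograph(rng.normal(0.0, 0.15, (64, 64)), 1.0)
        assert ta.segment_molecules(topo).max() == 0

    def test_single_molecule_single_component(self, bent_movie):
        movie, _ = bent_movie
        labels = ta.segment_molecules(movie.frames[0])
        assert labels.max() == 1

    def test_two_distant_molecules_two_components(self, default_params):
        movie, _ = generate_movie(default_params, 1, seed=9,
                                  frame_shape=(160, 160),
                                  positions=[(45.0, 45.0), (115.0, 115.0)])
        labels = ta.segment_molecules(movie.frames[0])
        assert labels.max() == 2


class TestBackboneTracing:
    def test_straight_rod_contour_recovered(self, straight_movie):
        movie, truth = straight_movie
        lengths = []
        for f, topo in enumerate(movie):
            labels = ta.segment_molecules(topo)
            trace = ta.trace_backbone(topo, labels == 1)
            assert trace is not None
            lengths.append(ta.contour_length(trace))
        assert np.mean(lengths) == pytest.approx(truth.contour_length[0], abs=2.0)

    def test_bent_molecule_close_to_ground_truth_backbone(self, default_params):
        from scipy.spatial.distance import directed_hausdorff

        p = HingedRodParams(angle_sd=0.0)  # hold the hinge at 63 deg
        movie, truth = generate_movie(p, 2, seed=21)
        topo = movie.frames[0]
        trace = ta.trace_backbone(topo, ta.segment_molecules(topo) == 1)
        assert trace is not None
        d = directed_hausdorff(trace.points, truth.backbones[0])[0]
        assert d <= 2.0 * topo.pixel_size

    def test_globular_component_flagged_no_trace(self):
        yy, xx = np.mgrid[0:48, 0:48]
        blob = 3.0 * np.exp(-(((xx - 24) ** 2 + (yy - 24) ** 2) / 60.0))
        topo = Topograph(blob, 1.0)
        mask = blob > 0.6
        assert ta.trace_backbone(topo, mask) is None

    def test_endpoint_labels_identify_lg_end(self, bent_movie):
        movie, truth = bent_movie
        topo = movie.frames[0]
        trace = ta.trace_backbone(topo, ta.segment_molecules(topo) == 1)
        assert "lg_end" in trace.endpoint_labels
        lg_point = trace.points[0 if trace.lg_index == 0 else -1]
        # the LG-labelled endpoint is the one near the ground-truth globule
        assert np.linalg.norm(lg_point - truth.lg_centroid[0]) < 8.0

    @pytest.mark.parametrize("seed", [31, 41, 51])
    def test_rotation_and_translation_invariance(self, seed):
        p = HingedRodParams(angle_sd=0.0, noise_sd=0.0)
        movie, _ = generate_movie(p, 1, seed=seed)
        topo = movie.frames[0]
        trace = ta.trace_backbone(topo, ta.segment_molecules(topo) == 1)
        kink = ta.detect_kink(trace)

        rot = Topograph(np.rot90(topo.heights).copy(), topo.pixel_size)
        trace_r = ta.trace_backbone(rot, ta.segment_molecules(rot) == 1)
        kink_r = ta.detect_kink(trace_r)
        # pixel-grid anisotropy of skeleton + refinement and the discrete
        # path through the LG blob leave a small orientation dependence
        assert ta.contour_length(trace_r) == pytest.approx(
            ta.contour_length(trace), abs=1.5 * topo.pixel_size)
        assert kink_r.angle == pytest.approx(kink.angle, abs=3.0)


class TestLengths:
    @pytest.mark.parametrize("pts,contour,e2e", [
        ([(0, 0), (10, 0), (20, 0)], 20.0, 20.0),
        ([(0, 0), (10, 0), (10, 10)], 20.0, math.sqrt(200.0)),
    ])
    def test_polyline_geometry(self, pts, contour, e2e):
        arr = np.asarray(pts, dtype=float)
        assert ta.contour_length(arr) == pytest.approx(contour)
        assert ta.end_to_end(arr) == pytest.approx(e2e)

    def test_contour_at_least_end_to_end_on_pipeline_output(self, bent_movie):
        movie, _ = bent_movie
        for topo in movie:
            trace = ta.trace_backbone(topo, ta.segment_molecules(topo) == 1)
            if trace is None:
                continue
            assert ta.contour_length(trace) >= ta.end_to_end(trace)


class TestCircleFit:
    def test_exact_points_on_circle(self):
        t = np.linspace(0.0, 1.8 * math.pi, 12, endpoint=False)
        pts = 9.2 * np.column_stack([np.cos(t), np.sin(t)]) + [3.0, -2.0]
        fit = ta.fit_circle(pts)
        assert fit.radius == pytest.approx(9.2, abs=1e-6)
        assert fit.rms_residual < 1e-9

    def test_three_points_give_circumscribed_circle(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        # closed-form circumradius oracle: R = abc / (4 * area)
        a = np.linalg.norm(pts[1] - pts[2])
        b = np.linalg.norm(pts[0] - pts[2])
        c = np.linalg.norm(pts[0] - pts[1])
        s = (a + b + c) / 2.0
        area = math.sqrt(s * (s - a) * (s - b) * (s - c))
        oracle = a * b * c / (4.0 * area)
        fit = ta.fit_circle(pts)
        assert fit.radius == pytest.approx(oracle, rel=1e-9)

    def test_noisy_circle_mean_radius_within_5_percent(self):
        rng = np.random.default_rng(5)
        radii = []
        for _ in range(100):
            t = np.sort(rng.uniform(0.0, 1.5 * math.pi, 40))
            pts = 9.5 * np.column_stack([np.cos(t), np.sin(t)])
            pts += rng.normal(0.0, 0.3, pts.shape)
            radii.append(ta.fit_circle(pts).radius)
        assert np.mean(radii) == pytest.approx(9.5, rel=0.05)

    def test_collinear_points_radius_unbounded(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8)])
        with pytest.raises(ValueError, match="unbounded"):
            ta.fit_circle(pts)

    def test_s_shape_bend_radii_recovered(self, rng):
        from lamhinge.synth_movie import s_shape_backbone

        pts = s_shape_backbone(jitter_sd=0.0, rng=rng)
        f1, f2 = ta.fit_bend_circles(pts)
        radii = sorted([f1.radius, f2.radius])
        assert radii[0] == pytest.approx(9.2, rel=0.10)
        assert radii[1] == pytest.approx(9.7, rel=0.10)


def brute_force_breakpoint(pts: np.ndarray, end_exclusion: int = 3) -> int:
    """Independent oracle: exhaustive search with its own line-fit routine
    (orthogonal residuals via the smallest eigenvalue of the scatter)."""
    def line_sse(p):
        c = p.mean(axis=0)
        w = np.linalg.eigvalsh((p - c).T @ (p - c))
        return w[0]

    n = len(pts)
    best_i, best = None, np.inf
    for i in range(end_exclusion, n - end_exclusion):
        sse = line_sse(pts[: i + 1]) + line_sse(pts[i:])
        if sse < best:
            best, best_i = sse, i
    return best_i


class TestKinkDetection:
    def test_exact_v_recovers_vertex_and_angle(self):
        angle = 63.0
        half = math.radians(angle / 2.0)
        u1 = np.array([math.sin(half), math.cos(half)])
        u2 = np.array([-math.sin(half), math.cos(half)])
        arm1 = np.outer(np.linspace(30, 0, 16, endpoint=False), u1)
        arm2 = np.outer(np.linspace(0, 30, 16), u2)
        pts = np.vstack([arm1, arm2])
        kink = ta.detect_kink(pts)
        assert abs(kink.breakpoint_index - 16) <= 1
        assert kink.angle == pytest.approx(63.0, abs=1.0)
        assert kink.called

    def test_straight_line_improvement_near_one_no_call(self):
        pts = np.column_stack([np.linspace(0, 40, 30), np.zeros(30)])
        kink = ta.detect_kink(pts)
        assert kink.improvement == pytest.approx(1.0, abs=0.01)
        assert kink.angle == pytest.approx(180.0, abs=1.0)
        assert not kink.called

    @pytest.mark.parametrize("seed", range(6))
    def test_breakpoint_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 31))
        angle = rng.uniform(40.0, 160.0)
        half = math.radians(angle / 2.0)
        u1 = np.array([math.sin(half), math.cos(half)])
        u2 = np.array([-math.sin(half), math.cos(half)])
        k = int(rng.integers(4, n - 4))
        arm1 = np.outer(np.linspace(12, 0, k, endpoint=False), u1)
        arm2 = np.outer(np.linspace(0, 12, n - k), u2)
        pts = np.vstack([arm1, arm2]) + rng.normal(0, 0.15, (n, 2))
        assert ta.detect_kink(pts).breakpoint_index == brute_force_breakpoint(pts)


class TestKinkDistance:
    def test_midpoint_kink_of_straight_trace(self):
        pts = np.column_stack([np.linspace(0, 60, 61), np.zeros(61)])
        trace = ta.MoleculeTrace(
            frame_index=0, points=pts, endpoint_labels=("lg_end", "arm_end"),
            mean_height=2.0, mean_width=4.0, pixel_size=1.0,
            heights_along=np.full(61, 2.0),
        )
        kink = ta.KinkResult(
            position_from_lg=30.0, angle=90.0, improvement=3.0,
            arm_directions=(np.array([1.0, 0]), np.array([-1.0, 0])),
            breakpoint_index=30, called=True,
        )
        # flat height profile: no blob, exit stays at the LG endpoint
        assert ta.kink_distance_from_lg(trace, kink) == pytest.approx(30.0, abs=1.0)

    def test_unlabelled_endpoints_error(self):
        pts = np.column_stack([np.linspace(0, 20, 21), np.zeros(21)])
        trace = ta.MoleculeTrace(
            frame_index=0, points=pts, endpoint_labels=("unknown", "unknown"),
            mean_height=2.0, mean_width=4.0, pixel_size=1.0,
            heights_along=np.full(21, 2.0),
        )
        kink = ta.detect_kink(trace)
        with pytest.raises(ValueError, match="unlabelled"):
            ta.kink_distance_from_lg(trace, kink)

    def test_synthetic_recovery_of_planted_kink_position(self, default_params):
        from lamhinge.core_io import TipModel
        from lamhinge.hinge_map import ObscurationModel, obscured_length

        p = default_params
        om = ObscurationModel.from_cap(
            footprint_radius=p.lg_radius, cap_height=p.lg_height,
            tip=TipModel(2.0, 5.0), rod_height=p.rod_height,
        )
        obscured = obscured_length(om).obscured
        dists, expects = [], []
        for seed in range(40):
            movie, truth = generate_movie(p, 1, seed=4000 + seed)
            topo = movie.frames[0]
            trace = ta.trace_backbone(topo, ta.segment_molecules(topo) == 1)
            if trace is None or len(trace.points) < 9:
                continue
            kink = ta.detect_kink(trace)
            if not kink.called:
                continue
            try:
                dists.append(ta.kink_distance_from_lg(trace, kink))
            except ValueError:
                continue
            expects.append(truth.hinge_arc_from_lg[0] - obscured)
        assert len(dists) >= 25
        assert np.mean(dists) == pytest.approx(np.mean(expects), abs=2.0)


class TestTracking:
    def test_single_molecule_yields_single_full_track(self):
        p = HingedRodParams(angle_sd=5.0)  # stays well resolved
        movie, _ = generate_movie(p, 12, seed=13)
        tracks = ta.angle_time_trace(movie)
        assert len(tracks) == 1
        assert len(tracks[0]) == 12

    def test_two_distant_molecules_two_tracks_no_swap(self, default_params):
        p = HingedRodParams(angle_sd=5.0)
        movie, _ = generate_movie(p, 8, seed=17, frame_shape=(160, 160),
                                  positions=[(45.0, 45.0), (115.0, 115.0)])
        tracks = ta.angle_time_trace(movie)
        assert len(tracks) == 2
        for track in tracks:
            centroids = np.array([t.centroid for t in track.traces])
            # a swap would jump ~100 nm between consecutive frames
            assert np.linalg.norm(np.diff(centroids, axis=0), axis=1).max() < 15.0

    def test_ou_parameter_recovery_from_time_series(self):
        # keep the hinge in the resolvable range so the series is unbroken
        p = HingedRodParams(mean_angle=80.0, angle_sd=12.0)
        movie, truth = generate_movie(p, 60, seed=19)
        tracks = ta.angle_time_trace(movie)
        angles = np.concatenate([t.angles for t in tracks])
        assert len(angles) >= 50
        gt = np.array([a for a in truth.hinge_angle])
        assert angles.mean() == pytest.approx(gt.mean(), abs=3.0)
        assert angles.std() == pytest.approx(gt.std(), rel=0.35)


class TestGaussianFit:
    def test_tiny_sample(self):
        fit = ta.fit_gaussian([1.0, 2.0, 3.0])
        assert fit.mean == pytest.approx(2.0)
        assert fit.sd == pytest.approx(1.0)

    def test_sampling_oracle(self):
        rng = np.random.default_rng(8)
        fit = ta.fit_gaussian(rng.normal(63.0, 25.0, 10_000))
        assert fit.mean == pytest.approx(63.0, abs=0.8)
        assert fit.sd == pytest.approx(25.0, abs=0.6)

    def test_constant_values_sd_zero(self):
        fit = ta.fit_gaussian([5.0] * 10)
        assert fit.sd == 0.0

    def test_fewer_than_three_values_error(self):
        with pytest.raises(ValueError):
            ta.fit_gaussian([1.0, 2.0])


class TestCensoredAngleEstimation:
    def test_censored_fit_corrects_selection_bias(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(63.0, 25.0, 3000)
        measured = sample[sample >= 40.0]
        n_censored = int((sample < 40.0).sum())
        naive = measured.mean()
        mu, sd = ta.censored_normal_fit(measured, n_censored, 40.0)
        assert naive > 68.0  # the bias the correction removes
        assert mu == pytest.approx(63.0, abs=1.5)
        assert sd == pytest.approx(25.0, rel=0.10)

    def test_no_censoring_reduces_to_sample_moments(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mu, sd = ta.censored_normal_fit(x, 0, 0.0)
        assert mu == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std(ddof=1))
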