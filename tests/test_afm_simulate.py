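"""Tip geometry, gray-scale dilation and pseudo-AFM rendering."""

import math

import numpy as np
import pytest

from lamhinge.core_io import TipModel, Topograph
from lamhinge.afm_simulate import (
    dilate_with_tip,
    simulate_afm,
    surface_from_structure,
    tip_apex_profile,
    tip_reach,
)
from lamhinge.synthetic_structures import ideal_coiled_coil, ideal_helix


def brute_force_dilation(heights: np.ndarray, pixel_size: float,
                         tip: TipModel) -> np.ndarray:
    """O(N²·M²) oracle: out(x,y) = max over all pixels of h(u,v) − f(dist)."""
    ny, nx = heights.shape
    out = np.empty_like(heights)
    for i in range(ny):
        for j in range(nx):
            best = -np.inf
            for u in range(ny):
                for v in range(nx):
                    d = math.hypot(i - u, j - v) * pixel_size
                    best = max(best, heights[u, v] - float(tip_apex_profile(tip, d)))
            out[i, j] = best
    return out


class TestTipProfile:
    def test_apex_is_zero_and_profile_non_decreasing(self):
        tip = TipModel(1.0, 5.0)
        d = np.linspace(0.0, 5.0, 200)
        f = tip_apex_profile(tip, d)
        assert f[0] == 0.0
        assert np.all(np.diff(f) >= 0.0)

    def test_sphere_cone_tangency_continuous_in_value_and_slope(self):
        tip = TipModel(2.0, 10.0)
        d_star = tip.sphere_radius * math.cos(math.radians(10.0))
        eps = 1e-6
        f = tip_apex_profile(tip, np.array([d_star - eps, d_star + eps]))
        assert abs(f[1] - f[0]) < 1e-4
        # slope on both sides approaches cot(alpha)
        slope_in = (tip_apex_profile(tip, d_star - eps)
                    - tip_apex_profile(tip, d_star - 2 * eps)) / eps
        slope_out = (tip_apex_profile(tip, d_star + 2 * eps)
                     - tip_apex_profile(tip, d_star + eps)) / eps
        assert slope_in == pytest.approx(slope_out, rel=1e-2)

    def test_reach_inverts_profile(self):
        tip = TipModel(1.0, 5.0)
        for depth in (0.1, 0.9, 2.0, 10.0):
            d = tip_reach(tip, depth)
            assert float(tip_apex_profile(tip, d)) == pytest.approx(depth, abs=1e-9)


class TestDilation:
    def test_flat_image_unchanged(self):
        topo = Topograph(np.full((12, 12), 1.5), 0.5)
        out = dilate_with_tip(topo, TipModel(1.0, 5.0))
        assert np.array_equal(out.heights, topo.heights)

    @pytest.mark.parametrize("seed,shape", [(0, (16, 16)), (1, (12, 20)), (2, (32, 32))])
    def test_matches_brute_force_oracle(self, seed, shape):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0.0, 3.0, shape)
        topo = Topograph(h, 0.5)
        tip = TipModel(1.0, 5.0)
        out = dilate_with_tip(topo, tip).heights
        assert np.abs(out - brute_force_dilation(h, 0.5, tip)).max() < 1e-12

    def test_delta_spike_images_the_inverted_tip(self):
        h = np.zeros((21, 21))
        h[10, 10] = 2.0
        out = dilate_with_tip(Topograph(h, 0.1), TipModel(1.0, 5.0)).heights
        r = 1.0
        for k in (2, 5, 8):
            d = k * 0.1
            expect = 2.0 - (r - math.sqrt(r * r - d * d))
            assert out[10, 10 + k] == pytest.approx(expect, abs=1e-9)

    def test_hemisphere_base_half_width_closed_form(self):
        # hemispherical bump radius a on a plane, spherical tip radius R:
        # apparent base half-width sqrt(a^2 + 2 a R)
        a, r, px = 2.0, 2.0, 0.05
        n = 201
        yy, xx = np.mgrid[0:n, 0:n]
        d2 = ((xx - 100) ** 2 + (yy - 100) ** 2) * px * px
        hemi = np.sqrt(np.clip(a * a - d2, 0.0, None))
        out = dilate_with_tip(Topograph(hemi, px), TipModel(r, 5.0)).heights
        row = out[100]
        half_width = (np.nonzero(row > 1e-9)[0].max() - 100) * px
        assert half_width == pytest.approx(math.sqrt(a * a + 2 * a * r), abs=2 * px)

    def test_output_dominates_input_and_grows_with_tip(self, rng):
        h = rng.uniform(0.0, 2.0, (24, 24))
        topo = Topograph(h, 0.5)
        out1 = dilate_with_tip(topo, TipModel(1.0, 5.0)).heights
        out2 = dilate_with_tip(topo, TipModel(2.0, 5.0)).heights
        assert np.all(out1 >= h - 1e-12)
        assert np.all(out2 >= out1 - 1e-12)


class TestSurfaceFromStructure:
    def test_single_atom_peak_is_sphere_diameter(self):
        from lamhinge.core_io import AtomisticStructure

        st = AtomisticStructure(
            np.array(["A"]), np.array([1]), np.array(["ALA"]),
            np.array(["CA"]), np.array(["C"]), np.array([[0.0, 0.0, 0.0]]),
            np.array([1.7]),
        )
        topo = surface_from_structure(st, pixel_size=0.05)
        assert topo.heights.max() == pytest.approx(0.34, abs=1e-3)

    def test_stacked_atoms_keep_only_top_sphere(self):
        from lamhinge.core_io import AtomisticStructure

        st = AtomisticStructure(
            np.array(["A", "A"]), np.array([1, 2]), np.array(["ALA"] * 2),
            np.array(["CA"] * 2), np.array(["C"] * 2),
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 3.4]]),
            np.array([1.7, 1.7]),
        )
        topo = surface_from_structure(st, pixel_size=0.05)
        # bottom sphere rests at 0; top sphere apex = 3.4 + 1.7 + 1.7 in A
        assert topo.heights.max() == pytest.approx(0.68, abs=1e-3)

    def test_helix_crest_matches_coordinate_oracle(self):
        helix = ideal_helix(40, lying_down=True)
        topo = surface_from_structure(helix, pixel_size=0.05)
        # oracle straight from the coordinates: top of the highest sphere
        oracle = (helix.coords[:, 2] + helix.vdw_radii).max() / 10.0
        assert topo.heights.max() == pytest.approx(oracle, rel=0.10)


class TestSimulateAfm:
    def test_bundle_crest_height_matches_coordinates(self):
        cc = ideal_coiled_coil(n_res=48)
        img = simulate_afm(cc, TipModel(1.0, 5.0), scan_step=1.0)
        oracle = (cc.coords[:, 2] + cc.vdw_radii).max() / 10.0
        assert img.heights.max() == pytest.approx(oracle, rel=0.15)

    def test_vanishing_tip_recovers_hard_sphere_surface(self):
        cc = ideal_coiled_coil(n_res=30)
        tiny = simulate_afm(cc, TipModel(0.01, 5.0), scan_step=0.5)
        ref = simulate_afm(cc, TipModel(1e-6, 5.0), scan_step=0.5)
        assert np.abs(tiny.heights - ref.heights).max() < 0.05

    def test_monotone_in_tip_radius(self):
        cc = ideal_coiled_coil(n_res=30)
        img1 = simulate_afm(cc, TipModel(1.0, 5.0), scan_step=1.0)
        img2 = simulate_afm(cc, TipModel(2.0, 5.0), scan_step=1.0)
        assert np.all(img2.heights >= img1.heights - 1e-9)

    def test_inverse_rotation_restores_image(self):
        from scipy.spatial.transform import Rotation

        helix = ideal_helix(30, lying_down=True)
        base = simulate_afm(helix, TipModel(1.0, 5.0), scan_step=0.5)
        spun = helix.transformed(
            rotation=Rotation.from_euler("z", 35, degrees=True).as_matrix()
        )
        img = simulate_afm(spun, TipModel(1.0, 5.0), scan_step=0.5,
                           rotation=(-35.0, 0.0, 0.0))
        assert img.heights.shape == base.heights.shape
        assert np.abs(img.heights - base.heights).max() < 0.1
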