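import numpy as np
import pytest

from rgcspatial.checkerboard import (
    ContrastPairSurface,
    design_contrast_space,
    convexity_index,
    half_axis_weights,
    interpolate_response,
    iso_response_contours,
    rectification_index,
    relative_sensitivity,
    select_local_patch,
)
from rgcspatial.synthetic import simulate_checkerboard_surface

from .conftest import small_cell, small_rf


def surface_from(fn, design=None):
    """Build a surface by evaluating a closed-form response field."""
    if design is None:
        design = design_contrast_space()
    counts = np.array([fn(a, b) for a, b in design])
    return ContrastPairSurface(design, counts)


class TestDesign:
    def test_default_count_includes_origin(self):
        pts = design_contrast_space(24, 10, 0.03, 1.0)
        assert pts.shape == (241, 2)
        assert np.any(np.all(pts == 0.0, axis=1))

    def test_four_angles_lie_on_half_axes(self):
        pts = design_contrast_space(4, 5, 0.1, 1.0)[:-1]
        on_axis = (np.abs(pts[:, 0]) < 1e-9) | (np.abs(pts[:, 1]) < 1e-9)
        assert on_axis.all()

    def test_radii_in_range(self):
        pts = design_contrast_space(24, 10, 0.03, 1.0)[:-1]
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert r.min() == pytest.approx(0.03)
        assert r.max() == pytest.approx(1.0)


class TestInterpolation:
    def test_exact_at_sample_points(self):
        rng = np.random.default_rng(0)
        design = design_contrast_space()
        counts = rng.uniform(0, 10, len(design))
        s = ContrastPairSurface(design, counts)
        for i in rng.choice(len(design), 10, replace=False):
            got = interpolate_response(s, design[i, 0], design[i, 1])
            assert got == pytest.approx(counts[i], abs=1e-9)

    def test_reproduces_linear_field(self):
        s = surface_from(lambda a, b: 2.0 + 3.0 * a - 1.5 * b)
        rng = np.random.default_rng(1)
        th = rng.uniform(0, 2 * np.pi, 50)
        r = rng.uniform(0, 0.9, 50)
        qa, qb = r * np.cos(th), r * np.sin(th)
        got = interpolate_response(s, qa, qb)
        assert np.allclose(got, 2.0 + 3.0 * qa - 1.5 * qb, atol=1e-6)

    def test_origin_gives_background(self):
        s = surface_from(lambda a, b: 1.0 + a + b)
        assert s.background_count == pytest.approx(1.0)

    def test_outside_hull_falls_back_with_warning(self):
        s = surface_from(lambda a, b: a + b)
        with pytest.warns(UserWarning):
            interpolate_response(s, 1.5, 1.5)


class TestHalfAxisWeights:
    def test_exact_slope(self):
        s = surface_from(lambda a, b: 5.0 * max(a, 0.0))
        w = half_axis_weights(s)
        assert w["+A"] == pytest.approx(5.0)
        assert w["-A"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_cell_balanced(self):
        s = surface_from(lambda a, b: max(a, 0) + max(b, 0))
        w = half_axis_weights(s)
        assert w["+A"] == pytest.approx(w["+B"])


class TestIndices:
    def test_linear_cell_ri_zero(self, linear_cell):
        design, mu = simulate_checkerboard_surface(linear_cell, noiseless=True)
        s = ContrastPairSurface(design, mu)
        assert rectification_index(s) == pytest.approx(0.0, abs=0.05)

    def test_rectified_cell_ri_one(self, rectified_cell):
        design, mu = simulate_checkerboard_surface(rectified_cell, noiseless=True)
        s = ContrastPairSurface(design, mu)
        assert rectification_index(s) == pytest.approx(1.0, abs=0.05)

    def test_linear_cell_ci_zero(self, linear_cell):
        design, mu = simulate_checkerboard_surface(linear_cell, noiseless=True)
        s = ContrastPairSurface(design, mu)
        assert convexity_index(s) == pytest.approx(0.0, abs=0.05)

    def test_partial_rectifier_matches_closed_form(self):
        # r = max(sA,0) + max(sB,0) + lam_c*(max(-sA,0) + max(-sB,0))
        lam_c = 0.4
        fn = lambda a, b: max(a, 0) + max(b, 0) + lam_c * (max(-a, 0) + max(-b, 0))
        s = surface_from(fn)
        c = 0.6
        # closed-form: all four weights equal... slopes: +A,+B -> 1; -A,-B -> lam_c
        w = {"+A": 1.0, "+B": 1.0, "-A": lam_c, "-B": lam_c}
        r_half = {"+A": c, "+B": c, "-A": lam_c * c, "-B": lam_c * c}
        opp = c + lam_c * c
        num = (w["+A"] + w["-B"] + w["-A"] + w["+B"]) * opp
        den = sum(w[k] * r_half[k] for k in w)
        expected = num / den
        assert rectification_index(s) == pytest.approx(expected, rel=1e-3)

    def test_quadratic_integrator_ci_half(self):
        s = surface_from(lambda a, b: a**2 + b**2)
        assert convexity_index(s) == pytest.approx(0.5, rel=1e-3)

    def test_homogeneity_preference_negative_ci(self):
        cell = small_cell("homogeneity_detector")
        design, mu = simulate_checkerboard_surface(cell, noiseless=True)
        s = ContrastPairSurface(design, mu)
        assert convexity_index(s) < -0.05

    def test_indices_invariant_to_response_rescaling(self, rectified_cell):
        design, mu = simulate_checkerboard_surface(rectified_cell, noiseless=True)
        a = ContrastPairSurface(design, mu)
        b = ContrastPairSurface(design, 4.0 * mu + 2.0)
        assert rectification_index(a) == pytest.approx(
            rectification_index(b), rel=1e-6
        )
        assert convexity_index(a) == pytest.approx(convexity_index(b), rel=1e-6)

    def test_ab_exchange_symmetry(self):
        fn = lambda a, b: max(a, 0) ** 2 + max(b, 0) ** 2 + 0.2 * abs(a * b)
        design = design_contrast_space()
        s = surface_from(fn, design)
        swapped = ContrastPairSurface(
            design[:, ::-1].copy(), np.array([fn(a, b) for a, b in design])
        )
        assert rectification_index(s) == pytest.approx(
            rectification_index(swapped), rel=1e-3
        )


class TestRelativeSensitivity:
    def test_balanced_is_zero(self):
        s = surface_from(lambda a, b: max(a, 0) + max(b, 0))
        assert relative_sensitivity(s) == pytest.approx(0.0, abs=0.05)

    def test_single_sided_is_one(self):
        s = surface_from(lambda a, b: max(b, 0))
        assert relative_sensitivity(s) == pytest.approx(1.0, abs=0.02)

    def test_three_to_one_ratio(self):
        s = surface_from(lambda a, b: 3.0 * max(a, 0) + 1.0 * max(b, 0))
        assert relative_sensitivity(s) == pytest.approx(-0.5, abs=0.02)


class TestContours:
    def test_linear_cell_contours_straight(self, linear_cell):
        design, mu = simulate_checkerboard_surface(linear_cell, noiseless=True)
        s = ContrastPairSurface(design, mu)
        contours = iso_response_contours(s, levels=(0.5,))
        polys = contours[0.5]
        assert polys
        grid_spacing = 2.0 / 200
        for poly in polys:
            if len(poly) < 10:
                continue
            # residual of best-fit line through the polyline
            xy = poly - poly.mean(axis=0)
            _, sv, _ = np.linalg.svd(xy, full_matrices=False)
            resid = sv[1] / np.sqrt(len(poly))
            assert resid < grid_spacing

    def test_quadratic_contours_circular(self):
        s = surface_from(lambda a, b: a**2 + b**2)
        contours = iso_response_contours(s, levels=(0.3, 0.5))
        for polys in contours.values():
            assert polys
            for poly in polys:
                r = np.hypot(poly[:, 0], poly[:, 1])
                assert r.std() / r.mean() < 0.02

    def test_monotone_output_transform_leaves_geometry(self):
        base = lambda a, b: max(a, 0) + max(b, 0)
        T = lambda v: 10.0 / (1.0 + np.exp(-3.0 * v))
        s1 = surface_from(base)
        s2 = surface_from(lambda a, b: T(base(a, b)))
        # an iso-response level of s1 maps to the transformed level of s2
        v1 = s1.background_count + 0.5 * (s1.counts.max() - s1.background_count)
        frac2 = (T(v1) - s2.background_count) / (
            s2.counts.max() - s2.background_count
        )
        c1 = iso_response_contours(s1, levels=(0.5,))[0.5]
        c2 = iso_response_contours(s2, levels=(frac2,))[frac2]

        # same geometry: compare the best-fit line of the longest polyline
        def line(polys):
            poly = max(polys, key=len)
            xy = poly - poly.mean(axis=0)
            _, _, vt = np.linalg.svd(xy, full_matrices=False)
            v = vt[0] * np.sign(vt[0, 0] or 1.0)
            return poly.mean(axis=0), v

        m1, v1d = line(c1)
        m2, v2d = line(c2)
        assert abs(abs(v1d @ v2d) - 1.0) < 0.01  # parallel
        # both lie on the same iso-g line: midpoints agree along the normal
        normal = np.array([-v1d[1], v1d[0]])
        assert abs((m1 - m2) @ normal) < 0.05

    def test_level_above_max_empty(self):
        s = surface_from(lambda a, b: a + b)
        out = iso_response_contours(s, levels=(5.0,))
        assert out[5.0] == []


class TestLocalPatch:
    def test_patch_on_center_distance_zero(self):
        rf = small_rf(60.0)
        idx, d = select_local_patch(np.array([[480.0, 480.0]]), rf)
        assert idx == 0 and d == pytest.approx(0.0)

    def test_nearer_patch_chosen(self):
        rf = small_rf(60.0)
        centers = np.array([[480.0 + 400.0, 480.0], [480.0 + 100.0, 480.0]])
        idx, d = select_local_patch(centers, rf)
        assert idx == 1
        assert d == pytest.approx(100.0 / 120.0)

    def test_union_of_layouts_mostly_within_one_rf_radius(self):
        # each presentation places sparse patches (>= 630 um apart); the
        # analysis picks the nearest patch over the union of all layouts,
        # which is dense enough to land within one RF radius for 300 um RFs
        rng = np.random.default_rng(2)
        hits = []
        for _ in range(10):
            union = []
            for _layout in range(30):
                pts = []
                while len(pts) < 20:
                    cand = rng.uniform(0, 4000, 2)
                    if all(np.hypot(*(cand - p)) >= 630.0 for p in pts):
                        pts.append(cand)
                union.extend(pts)
            rf_shift = ParametricRF_at(rng.uniform(1000, 3000, 2))
            _, d = select_local_patch(np.array(union), rf_shift)
            hits.append(d <= 1.0)
        assert np.mean(hits) > 0.7


def ParametricRF_at(mu):
    from rgcspatial.rf_estimation import ParametricRF

    return ParametricRF(np.asarray(mu), np.diag([75.0**2, 75.0**2]), 0.0, 2.0)
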