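import itertools
import math

import numpy as np
import pytest

from concavekit.convexity import (
    CONCAVE,
    CONVEX,
    FitFailureError,
    GeometryError,
    IndeterminateSignError,
    _spheres_from_quads,
    fit_sphere_lsq,
    fit_sphere_ransac,
    profile_interface,
    signed_convexity,
    surface_sign,
)
from concavekit.structure_io import AtomRecord, model_from_atoms
from concavekit.surface import golden_spiral_points

OCTAHEDRON = np.array(
    [[10, 0, 0], [-10, 0, 0], [0, 10, 0], [0, -10, 0], [0, 0, 10], [0, 0, -10]],
    dtype=float,
)


def sphere_cap_points(radius, n, half_angle_deg=70.0, center=(0, 0, 0), seed=0):
    """Points on a spherical cap around +z (radius exact unless noised)."""
    rng = np.random.default_rng(seed)
    cos_min = math.cos(math.radians(half_angle_deg))
    z = rng.uniform(cos_min, 1.0, n)
    phi = rng.uniform(0, 2 * math.pi, n)
    s = np.sqrt(1 - z**2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return np.asarray(center) + radius * dirs


class TestLeastSquaresSphere:
    def test_octahedron_exact(self):
        fit = fit_sphere_lsq(OCTAHEDRON)
        np.testing.assert_allclose(fit.center, 0.0, atol=1e-9)
        assert fit.radius == pytest.approx(10.0, abs=1e-9)

    def test_translation_equivariance(self):
        t = np.array([5.0, -3.0, 2.0])
        fit = fit_sphere_lsq(OCTAHEDRON + t)
        np.testing.assert_allclose(fit.center, t, atol=1e-9)
        assert fit.radius == pytest.approx(10.0, abs=1e-9)

    def test_coplanar_points_degenerate(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(GeometryError):
            fit_sphere_lsq(square)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            fit_sphere_lsq(OCTAHEDRON[:3])


class TestRansacSphere:
    def test_exact_sphere_all_inliers(self):
        pts = golden_spiral_points(100) * 10.0
        fit = fit_sphere_ransac(pts, seed=0)
        assert fit.radius == pytest.approx(10.0, abs=1e-6)
        assert len(fit.inlier_indices) == 100

    def test_noisy_sphere_with_outliers_classified_exhaustively(self):
        """80 radially-noised sphere points are all inliers; 20 far outliers
        are all excluded; radius lands within the noise band."""
        rng = np.random.default_rng(5)
        dirs = golden_spiral_points(80)
        signal = dirs * (10.0 + rng.uniform(-0.5, 0.5, 80))[:, None]
        out_dirs = golden_spiral_points(20)
        outliers = out_dirs * (16.0 + rng.uniform(0, 4.0, 20))[:, None]
        pts = np.vstack([signal, outliers])
        fit = fit_sphere_ransac(pts, threshold=1.0, max_iterations=20_000, seed=0)
        assert 9.5 <= fit.radius <= 10.5
        inl = set(fit.inlier_indices.tolist())
        assert set(range(80)) <= inl
        assert inl.isdisjoint(range(80, 100))

    def test_agrees_with_brute_force_enumeration_on_small_instance(self):
        """On <= 12 points, exhaustive enumeration of all 4-point hypotheses
        (the brute-force oracle) and seeded RANSAC select the same inliers."""
        exact = sphere_cap_points(5.0, 8, half_angle_deg=80, seed=1)
        rng = np.random.default_rng(2)
        noise = rng.uniform(10, 20, size=(4, 3)) * np.array([1, -1, 1])
        pts = np.vstack([exact, noise])
        threshold = 1.0

        best_key, best_model = None, None
        for it, quad in enumerate(itertools.combinations(range(len(pts)), 4)):
            centers, radii, valid = _spheres_from_quads(pts[list(quad)][None, :, :])
            if not valid[0]:
                continue
            resid = np.abs(np.linalg.norm(pts - centers[0], axis=1) - radii[0])
            inl = resid <= threshold
            rmse = float(np.sqrt(np.mean(resid[inl] ** 2))) if inl.any() else np.inf
            key = (int(inl.sum()), -rmse, -it)
            if best_key is None or key > best_key:
                best_key, best_model = key, (centers[0], radii[0])
        d = np.linalg.norm(pts - best_model[0], axis=1)
        oracle_inliers = np.flatnonzero(np.abs(d - best_model[1]) <= threshold)
        refit = fit_sphere_lsq(pts[oracle_inliers])
        d = np.linalg.norm(pts - refit.center, axis=1)
        oracle_inliers = np.flatnonzero(np.abs(d - refit.radius) <= threshold)

        fit = fit_sphere_ransac(pts, threshold=threshold, max_iterations=100_000, seed=0)
        np.testing.assert_array_equal(fit.inlier_indices, oracle_inliers)

    def test_rigid_motion_invariance(self):
        pts = sphere_cap_points(12.0, 40, seed=3)
        theta = 1.1
        R = np.array(
            [[math.cos(theta), 0, math.sin(theta)],
             [0, 1, 0],
             [-math.sin(theta), 0, math.cos(theta)]]
        )
        moved = pts @ R.T + np.array([7.0, -4.0, 11.0])
        f1 = fit_sphere_ransac(pts, seed=9, max_iterations=5000)
        f2 = fit_sphere_ransac(moved, seed=9, max_iterations=5000)
        assert f1.radius == pytest.approx(f2.radius, abs=1e-6)
        np.testing.assert_array_equal(f1.inlier_indices, f2.inlier_indices)

    def test_similarity_scaling(self):
        pts = sphere_cap_points(12.0, 40, seed=4)
        f1 = fit_sphere_ransac(pts, threshold=1.0, max_iterations=5000, seed=2)
        f2 = fit_sphere_ransac(2.0 * pts, threshold=2.0, max_iterations=5000, seed=2)
        assert f2.radius == pytest.approx(2.0 * f1.radius, rel=1e-9)
        np.testing.assert_array_equal(f1.inlier_indices, f2.inlier_indices)

    def test_bitwise_reproducibility(self):
        pts = sphere_cap_points(15.0, 50, seed=6)
        f1 = fit_sphere_ransac(pts, seed=123, max_iterations=5000)
        f2 = fit_sphere_ransac(pts, seed=123, max_iterations=5000)
        assert f1.radius == f2.radius
        assert (f1.center == f2.center).all()
        np.testing.assert_array_equal(f1.inlier_indices, f2.inlier_indices)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            fit_sphere_ransac(np.zeros((3, 3)))

    def test_all_degenerate_samples_fail(self):
        # strictly collinear points never admit a sphere hypothesis
        pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)])
        with pytest.raises(FitFailureError):
            fit_sphere_ransac(pts, max_iterations=200, seed=0)

    def test_recovers_curvature_across_radii(self):
        """Noised cap patches: recovered 1/radius within 10% of truth in
        >= 95% of seeded trials across radii 10-40 A."""
        ok = total = 0
        for radius in (10.0, 15.0, 25.0, 40.0):
            for seed in range(50):
                rng = np.random.default_rng(1000 + seed)
                pts = sphere_cap_points(radius, 60, half_angle_deg=55, seed=seed)
                pts *= (1.0 + rng.uniform(-0.3, 0.3, 60) / radius)[:, None]
                fit = fit_sphere_ransac(pts, threshold=1.0, max_iterations=3000, seed=seed)
                total += 1
                ok += abs(1.0 / fit.radius - 1.0 / radius) <= 0.1 / radius
        assert ok / total >= 0.95


class TestSurfaceSign:
    def test_pocket_wall_is_concave(self):
        # body occupies z < 0; pocket wall points lie on a sphere whose
        # center sits above the mouth, outside the body
        body = np.array([[x, y, z] for x in (-3, 0, 3) for y in (-3, 0, 3)
                         for z in (-6, -3, 0)], float)
        patch = sphere_cap_points(4.0, 30, half_angle_deg=60, center=(0, 0, 4), seed=0)
        patch[:, 2] = 4.0 - (patch[:, 2] - 4.0)  # lower cap of that sphere
        sign, dot = surface_sign(body, patch, np.array([0.0, 0, 4.0]))
        assert sign == CONCAVE and dot < 0

    def test_mirrored_bulge_is_convex(self):
        body = np.array([[x, y, z] for x in (-3, 0, 3) for y in (-3, 0, 3)
                         for z in (-6, -3, 0)], float)
        patch = sphere_cap_points(4.0, 30, half_angle_deg=60, center=(0, 0, -4), seed=0)
        sign, dot = surface_sign(body, patch, np.array([0.0, 0, -4.0]))
        assert sign == CONVEX and dot > 0

    def test_coincident_centroids_indeterminate(self):
        pts = OCTAHEDRON.copy()
        with pytest.raises(IndeterminateSignError):
            surface_sign(pts, pts, np.array([1.0, 2.0, 3.0]))


def _patch_model(patch, extra_body):
    coords = np.vstack([patch, extra_body])
    atoms = [
        AtomRecord(i + 1, "CA", "C", "GLY", i + 1, "A", c, True, False, 1.87)
        for i, c in enumerate(coords)
    ]
    return model_from_atoms(atoms)


class TestSignedConvexity:
    def test_concave_patch_radius_20(self):
        patch = sphere_cap_points(20.0, 40, half_angle_deg=35, center=(0, 0, 20), seed=1)
        patch[:, 2] = 20.0 - (patch[:, 2] - 20.0)  # inner wall (lower cap)
        body = np.array([[x, y, -6.0] for x in (-8, 0, 8) for y in (-8, 0, 8)], float)
        model = _patch_model(patch, body)
        res = signed_convexity(model, {"A"}, patch, max_iterations=5000, seed=0)
        assert res.sign == CONCAVE
        assert res.signed_convexity == pytest.approx(-0.05, rel=0.02)

    def test_scaling_halves_convexity(self):
        patch = sphere_cap_points(20.0, 40, half_angle_deg=35, center=(0, 0, 20), seed=1)
        patch[:, 2] = 20.0 - (patch[:, 2] - 20.0)
        body = np.array([[x, y, -6.0] for x in (-8, 0, 8) for y in (-8, 0, 8)], float)
        r1 = signed_convexity(_patch_model(patch, body), {"A"}, patch,
                              max_iterations=5000, seed=0)
        r2 = signed_convexity(_patch_model(2 * patch, 2 * body), {"A"}, 2 * patch,
                              ransac_threshold=2.0, max_iterations=5000, seed=0)
        assert r2.signed_convexity == pytest.approx(r1.signed_convexity / 2, rel=1e-6)

    def test_requires_four_interfacial_atoms(self, ball_socket):
        with pytest.raises(GeometryError):
            signed_convexity(ball_socket, {"A"}, np.zeros((3, 3)))


class TestProfileInterface:
    def test_distant_chains_yield_null_convexities(self, pseudo_model_factory):
        atoms = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", np.array([0.0, 0, 0]), True, False, 1.87),
            AtomRecord(2, "CA", "C", "GLY", 1, "B", np.array([40.0, 0, 0]), True, False, 1.87),
        ]
        model = model_from_atoms(atoms)
        with pytest.warns(UserWarning):
            prof = profile_interface(model, {"A"}, {"B"}, max_iterations=100, seed=0)
        assert prof.convexity_a is None and prof.convexity_b is None
        assert prof.buried.total == 0.0

    def test_ball_in_socket_signs(self, ball_socket):
        prof = profile_interface(ball_socket, {"A"}, {"B"}, max_iterations=20_000, seed=0)
        assert prof.convexity_a.sign == CONVEX
        assert prof.convexity_b.sign == CONCAVE
        # fitted radii reflect the generator geometry (ball 6 A, socket 11 A)
        assert prof.convexity_a.radius == pytest.approx(6.0, rel=0.1)
        assert prof.convexity_b.radius == pytest.approx(11.0, rel=0.1)
        assert prof.buried.total > 0
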