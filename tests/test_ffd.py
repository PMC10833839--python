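"""FFD transformation model: evaluation, derivatives, lattices, affine fit."""

import numpy as np
import pytest

from craniomorph.ffd import (
    AffineTransform,
    FFDTransform,
    GridSchedule,
    bending_energy,
    build_symmetric_grid,
    cubic_bspline_weights,
    fit_affine_landmarks,
)
from craniomorph.volumes import LandmarkSet, MaskVolume, VolumeImage


def _b3(t: float) -> float:
    """Scalar cubic B-spline (independent oracle)."""
    t = abs(t)
    if t < 1:
        return (4 - 6 * t**2 + 3 * t**3) / 6
    if t < 2:
        return (2 - t) ** 3 / 6
    return 0.0


@pytest.fixture()
def random_ffd(rng):
    return FFDTransform(
        control_origin=[-10, -10, -10],
        control_spacing=[5.0, 6.0, 7.0],
        coefficients=rng.normal(size=(6, 6, 6, 3)),
        pre_affine=AffineTransform.from_rotation_scale(
            [0.1, 0.2, 0.3], [1.1, 0.9, 1.2], [1, 2, 3]
        ),
    )


class TestApply:
    def test_identity_when_zero_coefficients(self, rng):
        T = FFDTransform([-10, -10, -10], [5, 5, 5], np.zeros((6, 6, 6, 3)))
        pts = rng.uniform(-4, 8, (50, 3))
        np.testing.assert_allclose(T.apply(pts), pts, atol=1e-14)

    def test_partition_of_unity_gives_translation(self, rng):
        """Constant coefficients reproduce a pure translation (weights sum to 1)."""
        d = np.array([1.0, -2.0, 3.0])
        T = FFDTransform([-10, -10, -10], [5, 6, 7], np.tile(d, (6, 6, 6, 1)))
        pts = rng.uniform(-2, 8, (1000, 3))
        np.testing.assert_allclose(T.apply(pts), pts + d, atol=1e-10)

    def test_matches_full_lattice_summation_oracle(self, random_ffd, rng):
        """20 random points vs naive summation over every control point."""
        pts = rng.uniform(-2, 8, (20, 3))
        got = random_ffd.apply(pts)
        h = random_ffd.control_spacing
        o = random_ffd.control_origin
        for p, g in zip(pts, got):
            disp = np.zeros(3)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        c = o + np.array([i, j, k]) * h
                        w = (
                            _b3((p[0] - c[0]) / h[0])
                            * _b3((p[1] - c[1]) / h[1])
                            * _b3((p[2] - c[2]) / h[2])
                        )
                        disp += w * random_ffd.coefficients[i, j, k]
            expected = random_ffd.pre_affine.apply(p)[0] + disp
            np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_outside_support_raises(self, random_ffd):
        with pytest.raises(ValueError, match="outside"):
            random_ffd.apply(np.array([1e3, 0, 0]))

    def test_weights_sum_to_one(self, rng):
        u = rng.uniform(0, 1, 100)
        np.testing.assert_allclose(cubic_bspline_weights(u).sum(axis=1), 1.0, atol=1e-14)


class TestDerivatives:
    def test_jacobian_identity(self, rng):
        T = FFDTransform([-10, -10, -10], [5, 5, 5], np.zeros((6, 6, 6, 3)))
        np.testing.assert_allclose(T.jacobian_det(rng.uniform(-4, 8, (20, 3))), 1.0, atol=1e-14)

    def test_jacobian_affine_scale_closed_form(self, rng):
        s = (1.3, 0.7, 1.1)
        T = FFDTransform(
            [-10, -10, -10], [5, 5, 5], np.zeros((6, 6, 6, 3)),
            pre_affine=AffineTransform.from_rotation_scale(scale=s),
        )
        np.testing.assert_allclose(
            T.jacobian_det(rng.uniform(-4, 8, (20, 3))), np.prod(s), atol=1e-12
        )

    def test_jacobian_matches_finite_differences(self, random_ffd, rng):
        pts = rng.uniform(0, 6, (10, 3))
        J = random_ffd.jacobian_det(pts)
        h = 1e-3 * 5.0
        for p, j in zip(pts, J):
            G = np.zeros((3, 3))
            for a in range(3):
                e = np.zeros(3)
                e[a] = h
                G[:, a] = (random_ffd.apply(p + e)[0] - random_ffd.apply(p - e)[0]) / (2 * h)
            assert abs(j - np.linalg.det(G)) <= 1e-4 * abs(np.linalg.det(G))

    def test_bending_energy_affine_exact_zero(self):
        mask = MaskVolume(np.ones((6, 6, 6), bool), [2, 2, 2], [-5, -5, -5])
        T = FFDTransform(
            [-30, -30, -30], [12, 12, 12], np.zeros((6, 6, 6, 3)),
            pre_affine=AffineTransform.from_rotation_scale([0.3, 0, 0], [1.4, 0.8, 1.0], [5, 5, 5]),
        )
        assert bending_energy(T, mask) == 0.0

    def test_bending_energy_translation_field_zero(self):
        mask = MaskVolume(np.ones((6, 6, 6), bool), [2, 2, 2], [-5, -5, -5])
        T = FFDTransform([-30, -30, -30], [12, 12, 12], np.tile([3.0, -2.0, 1.0], (6, 6, 6, 1)))
        assert bending_energy(T, mask) < 1e-30

    def test_bending_energy_matches_finite_difference_hessian(self, rng):
        """Single perturbed control point vs second-order central differences."""
        coef = np.zeros((6, 6, 6, 3))
        coef[2, 3, 2, 1] = 4.0
        T = FFDTransform([-10, -10, -10], [5, 6, 7], coef)
        mask = MaskVolume(np.ones((4, 4, 4), bool), [2.5, 3, 3.5], [0, 0, 0])
        got = bending_energy(T, mask)
        pts = mask.world_points()
        h = 1e-3
        total = 0.0
        for p in pts:
            H = np.zeros((3, 3, 3))
            for a in range(3):
                for b in range(3):
                    ea, eb = np.zeros(3), np.zeros(3)
                    ea[a], eb[b] = h, h
                    H[:, a, b] = (
                        T.apply(p + ea + eb)[0]
                        - T.apply(p + ea - eb)[0]
                        - T.apply(p - ea + eb)[0]
                        + T.apply(p - ea - eb)[0]
                    ) / (4 * h * h)
            total += np.sum(H * H)
        expected = total / len(pts)
        assert abs(got - expected) <= 1e-3 * expected


class TestLattice:
    def test_symmetric_grid_mirror_symmetry(self):
        """Control coordinates mirror about the plane at a realistic spacing."""
        vol = VolumeImage(np.zeros((41, 41, 41)), [2.5, 2.5, 2.5], [-50, -50, -50])
        T = build_symmetric_grid(vol, 26.21, plane_axis=0)
        cx = T.control_coords(0)
        np.testing.assert_allclose(cx, -cx[::-1], atol=1e-12)

    def test_mirror_of_every_control_coord_is_a_control_coord(self):
        vol = VolumeImage(np.zeros((21, 21, 21)), [3, 3, 3], [-30, -30, -30])
        T = build_symmetric_grid(vol, 11.0, plane_axis=1)
        cy = T.control_coords(1)
        plane = 0.0
        mirrored = np.sort(2 * plane - cy)
        np.testing.assert_allclose(np.sort(cy), mirrored, atol=1e-12)

    def test_zero_coefficient_grid_is_identity_on_domain(self, rng):
        vol = VolumeImage(np.zeros((17, 17, 17)), [4, 4, 4], [-32, -32, -32])
        T = build_symmetric_grid(vol, 20.0)
        lo, hi = vol.world_bounds()
        pts = rng.uniform(lo, hi, (200, 3))
        np.testing.assert_allclose(T.apply(pts), pts, atol=1e-13)

    def test_spacing_larger_than_domain_still_valid(self, rng):
        vol = VolumeImage(np.zeros((9, 9, 9)), [2, 2, 2], [-8, -8, -8])
        T = build_symmetric_grid(vol, 100.0)
        np.testing.assert_allclose(T.apply(np.zeros((1, 3))), np.zeros((1, 3)), atol=1e-13)

    def test_subdivision_reproduces_coarse_field(self, rng):
        """Coarse-to-fine B-spline subdivision is exact (multi-resolution contract)."""
        T = FFDTransform([-40, -40, -40], [16, 16, 16], rng.normal(size=(7, 7, 7, 3)))
        fine = T.subdivide()
        pts = rng.uniform(-20, 20, (300, 3))
        np.testing.assert_allclose(fine.apply(pts), T.apply(pts), atol=1e-10)
        assert fine.control_shape == (11, 11, 11)

    def test_schedule_spacings(self):
        s = GridSchedule(finest_spacing=10.0)
        assert [s.spacing_at(l) for l in range(3)] == [40.0, 20.0, 10.0]
        assert [s.image_factor_at(l) for l in range(3)] == [4, 2, 1]


class TestSerialization:
    def test_round_trip_bit_exact(self, random_ffd, tmp_path, rng):
        path = tmp_path / "transform.json"
        random_ffd.save(path)
        back = FFDTransform.load(path)
        np.testing.assert_array_equal(back.coefficients, random_ffd.coefficients)
        np.testing.assert_array_equal(back.control_origin, random_ffd.control_origin)
        np.testing.assert_array_equal(back.pre_affine.matrix, random_ffd.pre_affine.matrix)
        pts = rng.uniform(0, 5, (10, 3))
        np.testing.assert_array_equal(back.apply(pts), random_ffd.apply(pts))


class TestAffineFit:
    def _landmarks(self, pts):
        return LandmarkSet(np.arange(1, len(pts) + 1), [f"l{i}" for i in range(len(pts))], pts)

    def test_identity_recovery(self, rng):
        P = rng.uniform(-50, 50, (6, 3))
        T, resid = fit_affine_landmarks(self._landmarks(P), self._landmarks(P))
        assert resid < 1e-9
        np.testing.assert_allclose(T.matrix, np.eye(3), atol=1e-6)

    def test_similarity_recovery(self, rng):
        P = rng.uniform(-50, 50, (7, 3))
        gt = AffineTransform.from_rotation_scale([0.2, -0.1, 0.3], [1.2, 0.8, 1.05], [5, -3, 2])
        T, resid = fit_affine_landmarks(self._landmarks(P), self._landmarks(gt.apply(P)))
        assert resid < 1e-9
        np.testing.assert_allclose(T.matrix, gt.matrix, atol=1e-6)

    def test_noisy_fit_matches_independent_optimizer(self, rng):
        """Residual agrees with a generic optimizer on the same objective."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        P = rng.uniform(-50, 50, (8, 3))
        gt = AffineTransform.from_rotation_scale([0.1, 0.2, -0.1], [1.1, 0.9, 1.0], [2, 1, -4])
        Q = gt.apply(P) + rng.normal(0, 0.5, (8, 3))
        _, resid = fit_affine_landmarks(self._landmarks(P), self._landmarks(Q))

        def objective(x):
            R = Rotation.from_rotvec(x[3:6]).as_matrix()
            M = R @ np.diag(np.exp(x[6:9]))
            return np.mean(np.linalg.norm(P @ M.T + x[:3] - Q, axis=1))

        x0 = np.concatenate([[2, 1, -4], [0.1, 0.2, -0.1], np.log([1.1, 0.9, 1.0])])
        oracle = minimize(objective, x0, method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000})
        assert resid <= oracle.fun + 1e-6

    def test_too_few_points_raise(self):
        lm = self._landmarks(np.eye(3)[:2])
        with pytest.raises(ValueError):
            fit_affine_landmarks(lm, lm)

    def test_coplanar_points_warn(self, rng):
        P = rng.uniform(-20, 20, (6, 3))
        P[:, 2] = 0.0
        with pytest.warns(UserWarning, match="coplanar"):
            fit_affine_landmarks(self._landmarks(P), self._landmarks(P))
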