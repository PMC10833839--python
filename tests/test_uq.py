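"""Simplex stochastic collocation: pdfs, metamodel, metric, refinement, adaptivity."""

import numpy as np
import pytest
from scipy.integrate import dblquad, quad

from craniomorph.phantom import analytic_qoi
from craniomorph.uq import (
    AdaptConfig,
    MetricField,
    ParameterSpace,
    PdfSpec,
    SimplexTessellation,
    adapt,
    default_registration_space,
    error_on_metric,
    estimate_qoi_hessian,
    initial_tessellation,
    interpolation_error_l1,
    metamodel_eval,
    optimal_metric,
    pdf_eval,
    refine,
    unit_square_space,
)


@pytest.fixture()
def space():
    return unit_square_space()


class TestPdfs:
    def test_uniform_density_value(self):
        spec = PdfSpec("uniform", 0.0, 1000.0)
        np.testing.assert_allclose(pdf_eval(spec, np.array([0.0, 500.0, 1000.0])), 0.001)
        assert pdf_eval(spec, np.array([-1.0]))[0] == 0.0

    def test_truncated_gaussian_unimodal(self):
        spec = PdfSpec("truncated_gaussian", 8.0, 32.0, mean=20.0, sd=4.0)
        assert pdf_eval(spec, np.array([20.0]))[0] > pdf_eval(spec, np.array([8.0]))[0]

    @pytest.mark.parametrize(
        "spec",
        [
            PdfSpec("uniform", 0.0, 1000.0),
            PdfSpec("truncated_gaussian", 8.0, 32.0, mean=20.0, sd=4.0),
        ],
    )
    def test_integrates_to_one(self, spec):
        total, _ = quad(lambda x: pdf_eval(spec, np.array([x]))[0], spec.lo, spec.hi)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_registration_space_bounds(self):
        sp = default_registration_space()
        np.testing.assert_array_equal(sp.bounds, [[8.0, 32.0], [0.0, 1000.0]])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PdfSpec("lognormal", 0, 1)
        with pytest.raises(ValueError):
            PdfSpec("uniform", 1, 0)


class TestTessellation:
    def test_three_points_one_triangle(self):
        tess = SimplexTessellation([[0, 0], [1, 0], [0, 1]], [1.0, 2.0, 3.0])
        assert len(tess.triangles) == 1

    def test_four_corners_cover_unit_square(self, space):
        tess = SimplexTessellation(space.corners, np.zeros(4))
        assert len(tess.triangles) == 2
        assert tess.triangle_areas().sum() == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            SimplexTessellation([[0, 0], [1, 1], [2, 2]], [0, 0, 0])

    def test_initial_tessellation_deterministic(self, space):
        q = analytic_qoi("quadratic")
        a = initial_tessellation(space, 8, q, seed=5)
        b = initial_tessellation(space, 8, q, seed=5)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.values, b.values)

    def test_corners_always_included(self, space):
        tess = initial_tessellation(space, 5, analytic_qoi("affine"), seed=1)
        for corner in space.corners:
            assert np.min(np.linalg.norm(tess.vertices - corner, axis=1)) < 1e-12


class TestMetamodel:
    def test_vertex_values_exact(self, space):
        q = analytic_qoi("gaussian_bump")
        tess = initial_tessellation(space, 10, q, seed=0)
        got = metamodel_eval(tess, tess.vertices[5])
        assert got[0] == pytest.approx(tess.values[5], abs=1e-12)

    def test_linear_reproduction(self, space, rng):
        q = analytic_qoi("affine")
        tess = initial_tessellation(space, 10, q, seed=0)
        pts = rng.uniform(0.05, 0.95, (50, 2))
        np.testing.assert_allclose(metamodel_eval(tess, pts), q(pts), atol=1e-12)

    def test_centroid_barycentric_average(self):
        q = analytic_qoi("quadratic")
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        tess = SimplexTessellation(verts, q(verts))
        centroid = verts.mean(axis=0)
        assert metamodel_eval(tess, centroid)[0] == pytest.approx(q(verts).mean(), abs=1e-12)

    def test_outside_hull_raises(self, space):
        tess = SimplexTessellation(space.corners, np.zeros(4))
        with pytest.raises(ValueError, match="outside"):
            metamodel_eval(tess, np.array([2.0, 2.0]))


class TestInterpolationError:
    def test_affine_error_vanishes(self, space):
        q = analytic_qoi("affine")
        tess = initial_tessellation(space, 6, q, seed=0)
        assert interpolation_error_l1(tess, q, space) < 1e-12

    def test_quadratic_on_single_triangle_matches_closed_form(self):
        """L1 error of the linear interpolant of x^2 on the right unit triangle."""
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])

        def q(l):
            l = np.asarray(l)
            return l[..., 0] ** 2

        tess = SimplexTessellation(verts, q(verts))
        # interpolant on this triangle is x (values 0, 1, 0); integrand |x^2 - x|
        exact_integral, _ = dblquad(
            lambda y, x: abs(x**2 - x), 0, 1, lambda x: 0, lambda x: 1 - x
        )
        # MC quadrature samples pi = uniform on the unit square; restrict to the
        # triangle by comparing expectations over the triangle only
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (40000, 2))
        inside = pts.sum(axis=1) <= 1.0
        mc = np.mean(np.abs(q(pts[inside]) - tess.eval(pts[inside])))
        assert mc == pytest.approx(exact_integral / 0.5, rel=0.05)

    def test_nested_refinement_never_increases_error(self, space):
        q = analytic_qoi("quadratic")
        tess = initial_tessellation(space, 8, q, seed=4)
        errors = [interpolation_error_l1(tess, q, space, seed=7)]
        for r in range(3):
            hess = np.stack(
                [estimate_qoi_hessian(tess, v) for v in range(tess.n_vertices)]
            )
            metric = optimal_metric(tess, space, 200, hessians=hess)
            tess = refine(tess, metric, 15, q, seed=r)
            errors.append(interpolation_error_l1(tess, q, space, seed=7))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))


class TestHessianEstimate:
    def test_general_quadratic_recovered(self, space):
        A = np.array([[2.0, 1.0], [1.0, 3.0]])

        def q(l):
            l = np.asarray(l)
            if l.ndim == 1:
                return float(l @ A @ l)
            return np.einsum("ni,ij,nj->n", l, A, l)

        tess = initial_tessellation(space, 12, q, seed=2)
        H = estimate_qoi_hessian(tess, 0)
        np.testing.assert_allclose(H, 2 * A, atol=1e-6)

    def test_affine_and_constant_give_zero(self, space):
        for q in (analytic_qoi("affine"), lambda l: 7.0):
            tess = initial_tessellation(space, 10, q, seed=3)
            H = estimate_qoi_hessian(tess, 2)
            np.testing.assert_allclose(H, np.zeros((2, 2)), atol=1e-8)

    def test_too_few_samples_raise(self):
        tess = SimplexTessellation([[0, 0], [1, 0], [0, 1]], [0, 0, 0])
        with pytest.raises(ValueError):
            estimate_qoi_hessian(tess, 0)

    def test_pdf_weighted_variant(self, space):
        q = analytic_qoi("quadratic")
        tess = initial_tessellation(space, 10, q, seed=1)
        H = estimate_qoi_hessian(tess, 0)
        Hw = estimate_qoi_hessian(tess, 0, weighted=True, space=space)
        np.testing.assert_allclose(Hw, H * space.pdf(tess.vertices[0])[0], atol=1e-10)


class TestOptimalMetric:
    @pytest.fixture()
    def quad_tess(self, space):
        q = analytic_qoi("quadratic")
        return initial_tessellation(space, 12, q, seed=2)

    def test_constant_hessian_gives_constant_isotropic_metric(self, space, quad_tess):
        hess = np.broadcast_to(2 * np.eye(2), (quad_tess.n_vertices, 2, 2)).copy()
        metric = optimal_metric(quad_tess, space, 100, hessians=hess)
        first = metric.matrices[0]
        np.testing.assert_allclose(
            metric.matrices, np.broadcast_to(first, metric.matrices.shape), atol=1e-10
        )
        vals = np.linalg.eigvalsh(first)
        assert vals[0] == pytest.approx(vals[1], rel=1e-10)

    def test_budget_doubling_doubles_metric(self, space, quad_tess):
        hess = np.broadcast_to(2 * np.eye(2), (quad_tess.n_vertices, 2, 2)).copy()
        m1 = optimal_metric(quad_tess, space, 100, hessians=hess)
        m2 = optimal_metric(quad_tess, space, 200, hessians=hess)
        np.testing.assert_allclose(m2.matrices, 2.0 * m1.matrices, atol=1e-10)

    def test_zero_hessian_isotropic_fallback(self, space, quad_tess):
        hess = np.zeros((quad_tess.n_vertices, 2, 2))
        with pytest.warns(UserWarning, match="isotropic"):
            metric = optimal_metric(quad_tess, space, 100, hessians=hess)
        assert np.all(np.linalg.eigvalsh(metric.matrices) > 0)

    def test_metric_spd_after_flooring(self, space):
        """Indefinite Hessians (saddle) still give SPD metrics."""
        q = analytic_qoi("gaussian_bump")
        tess = initial_tessellation(space, 15, q, seed=6)
        metric = optimal_metric(tess, space, 100)
        assert np.all(np.linalg.eigvalsh(metric.matrices) > 0)

    def test_metric_field_validation(self):
        with pytest.raises(ValueError):
            MetricField(np.array([[[1.0, 2.0], [0.0, 1.0]]]))  # asymmetric
        with pytest.raises(ValueError):
            MetricField(np.array([[[1.0, 0.0], [0.0, -1.0]]]))  # indefinite


class TestErrorOnMetric:
    def test_budget_doubling_halves_error(self, space):
        q = analytic_qoi("quadratic")
        tess = initial_tessellation(space, 12, q, seed=2)
        hess = np.broadcast_to(2 * np.eye(2), (tess.n_vertices, 2, 2)).copy()
        e1 = error_on_metric(tess, space, 100, hessians=hess)
        e2 = error_on_metric(tess, space, 200, hessians=hess)
        assert e1 / e2 == pytest.approx(2.0, abs=1e-12)

    def test_zero_hessian_zero_error(self, space):
        tess = initial_tessellation(space, 8, analytic_qoi("affine"), seed=0)
        hess = np.zeros((tess.n_vertices, 2, 2))
        assert error_on_metric(tess, space, 100, hessians=hess) == 0.0

    def test_quadratic_matches_numeric_quadrature(self, space):
        """E for Q = l1^2 + l2^2 vs independent evaluation of the integral."""
        q = analytic_qoi("quadratic")
        tess = initial_tessellation(space, 400, q, seed=9)
        got = error_on_metric(tess, space, 100)
        # pi = 1, |H| = 2I, det = 4 -> integrand 4^(1/4) = sqrt(2) everywhere
        integral = np.sqrt(2.0)
        expected = 2 * (1 / 100.0) * integral**2
        assert got == pytest.approx(expected, rel=0.05)


class TestRefine:
    def test_isotropic_metric_splits_longest_edges(self, space):
        verts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.55]], float)
        tess = SimplexTessellation(verts, np.zeros(5))
        metric = MetricField(np.broadcast_to(np.eye(2), (5, 2, 2)).copy())
        out = refine(tess, metric, 1, lambda l: 0.0, seed=0)
        new = out.vertices[-1]
        edges = tess.edges()
        lengths = np.linalg.norm(verts[edges[:, 1]] - verts[edges[:, 0]], axis=1)
        best = edges[np.lexsort((edges[:, 1], edges[:, 0], -lengths))[0]]
        np.testing.assert_allclose(new, verts[best].mean(axis=0), atol=1e-12)

    def test_anisotropic_metric_prefers_one_axis(self, space, rng):
        """diag(100, 1) metric: splits are predominantly along axis-1-long edges."""
        g = np.stack(np.meshgrid(np.linspace(0, 1, 5), np.linspace(0, 1, 5)), -1).reshape(-1, 2)
        tess = SimplexTessellation(g, np.zeros(len(g)))
        metric = MetricField(np.broadcast_to(np.diag([100.0, 1.0]), (len(g), 2, 2)).copy())
        out = refine(tess, metric, 8, lambda l: 0.0, seed=0)
        new = out.vertices[len(g):]
        # metric length of axis-0 edges is 10x that of axis-1 edges: all splits
        # should bisect edges with a dominant axis-0 component
        parents = []
        for p in new:
            # recover the split axis from the midpoint coordinates (grid step 0.25)
            on_half_x = np.isclose((p[0] * 8) % 2, 1)
            parents.append(on_half_x)
        assert np.mean(parents) >= 0.75

    def test_vertex_count_and_hull_preserved(self, space):
        q = analytic_qoi("quadratic")
        tess = initial_tessellation(space, 8, q, seed=1)
        metric = optimal_metric(tess, space, 50)
        out = refine(tess, metric, 5, q, seed=2)
        assert out.n_vertices == tess.n_vertices + 5
        assert out.triangle_areas().sum() == pytest.approx(1.0, abs=1e-9)


class TestAdapt:
    def test_affine_exact_for_any_budget(self, space):
        q = analytic_qoi("affine")
        tess, stats = adapt(space, q, AdaptConfig(budget=40, n_adap=3, rng_seed=0))
        assert interpolation_error_l1(tess, q, space) < 1e-10
        assert stats["n_evaluations"] <= 40

    def test_budget_respected_and_coverage_kept(self, space):
        q = analytic_qoi("gaussian_bump")
        tess, stats = adapt(space, q, AdaptConfig(budget=60, n_adap=4, rng_seed=1))
        assert tess.n_vertices <= 60
        assert tess.triangle_areas().sum() == pytest.approx(1.0, abs=1e-9)

    def test_statistics_match_direct_mc_on_metamodel(self, space):
        q = analytic_qoi("quadratic")
        tess, stats = adapt(space, q, AdaptConfig(budget=50, n_adap=3, rng_seed=2))
        # E[l1^2 + l2^2] = 2/3 under the uniform density
        assert stats["mean"] == pytest.approx(2 / 3, abs=0.02)

    def test_deterministic_given_seed(self, space):
        q = analytic_qoi("gaussian_bump")
        cfg = AdaptConfig(budget=45, n_adap=3, rng_seed=8)
        t1, _ = adapt(space, q, cfg)
        t2, _ = adapt(space, q, cfg)
        np.testing.assert_array_equal(t1.vertices, t2.vertices)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_budget_below_initial_raises(self, space):
        with pytest.raises(ValueError):
            adapt(space, analytic_qoi("affine"), AdaptConfig(budget=5, n_adap=2, n_initial=10))

    def test_extras_records_kept_for_selection(self, space):
        """Dict-valued QoIs carry accuracy/j10 records for best-prediction choice."""
        from craniomorph.meshtools import select_best

        def qoi(lam):
            acc = 1.0 + abs(lam[0] - 0.5)
            j = 1.0 - 0.5 * abs(lam[1] - 0.5)
            return {"value": acc, "accuracy": acc, "j10": j,
                    "lambda1": lam[0], "lambda2": lam[1]}

        tess, _ = adapt(space, qoi, AdaptConfig(budget=30, n_adap=2, rng_seed=3))
        assert tess.extras is not None and len(tess.extras) == tess.n_vertices
        best = select_best(tess.extras)
        expected = min(
            tess.extras, key=lambda r: (r["accuracy"] * (r["j10"] - 1) ** 2, -r["j10"], r["lambda1"])
        )
        assert best is expected
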