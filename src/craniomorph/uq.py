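"""Adaptive simplex stochastic collocation over a 2-D parameter space.

The registration's two most sensitive parameters — the finest control-grid
spacing lambda1 (mm) and the bending-penalty weight lambda2 — are treated as
random inputs with a prescribed joint density pi. A piecewise-linear
metamodel of a scalar quantity of interest Q(lambda) is built on a Delaunay
tessellation of samples, and refined adaptively: the local Hessian of Q
defines a Riemannian metric whose optimal form (for a fixed sample budget
C) minimizes the pi-weighted L1 interpolation error; edges that are long in
the metric are bisected, concentrating samples where the response is curved
or the density is high. For n = 2 the optimal error estimate decays like
C^(-1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

__all__ = [
    "PdfSpec",
    "ParameterSpace",
    "SimplexTessellation",
    "MetricField",
    "AdaptConfig",
    "pdf_eval",
    "initial_tessellation",
    "metamodel_eval",
    "interpolation_error_l1",
    "estimate_qoi_hessian",
    "optimal_metric",
    "error_on_metric",
    "refine",
    "adapt",
    "default_registration_space",
]


# ---------------------------------------------------------------------------
# Probability densities
# ---------------------------------------------------------------------------


@dataclass
class PdfSpec:
    """1-D marginal density: truncated Gaussian or uniform on [lo, hi]."""

    kind: str  # "truncated_gaussian" | "uniform"
    lo: float
    hi: float
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("truncated_gaussian", "uniform"):
            raise ValueError(f"unknown pdf kind {self.kind!r}")
        if not self.hi > self.lo:
            raise ValueError("pdf bounds must satisfy hi > lo")
        if self.kind == "truncated_gaussian" and self.sd <= 0:
            raise ValueError("sd must be > 0")

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm(a, b, loc=self.mean, scale=self.sd)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lo) & (x <= self.hi)
        if self.kind == "uniform":
            out = np.full(x.shape, 1.0 / (self.hi - self.lo))
        else:
            out = self._dist().pdf(x)
        return np.where(inside, out, 0.0)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        u = rng.uniform(0.0, 1.0, size=n)
        return self._dist().ppf(u)


def pdf_eval(spec: PdfSpec, x: np.ndarray) -> np.ndarray:
    """Density of a marginal at points; renormalized over its bounds, 0 outside."""
    return spec.pdf(x)


@dataclass
class ParameterSpace:
    """2-D uncertain-parameter domain with independent marginals."""

    pdfs: tuple[PdfSpec, PdfSpec]

    @property
    def n(self) -> int:
        return 2

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[p.lo, p.hi] for p in self.pdfs])

    @property
    def corners(self) -> np.ndarray:
        (l0, h0), (l1, h1) = self.bounds
        return np.array([[l0, l1], [l0, h1], [h0, l1], [h0, h1]])

    @property
    def area(self) -> float:
        b = self.bounds
        return float(np.prod(b[:, 1] - b[:, 0]))

    def pdf(self, lam: np.ndarray) -> np.ndarray:
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        return self.pdfs[0].pdf(lam[:, 0]) * self.pdfs[1].pdf(lam[:, 1])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.stack([p.sample(rng, n) for p in self.pdfs], axis=1)


def default_registration_space() -> ParameterSpace:
    """The registration study's parameter setup.

    lambda1 (finest grid spacing, mm): truncated Gaussian N(20, 4) on [8, 32]
    — a prior centered on a plausible spacing. lambda2 (penalty weight):
    uniform on [0, 1000] — no a-priori information on its effect.
    """
    return ParameterSpace(
        pdfs=(
            PdfSpec("truncated_gaussian", 8.0, 32.0, mean=20.0, sd=4.0),
            PdfSpec("uniform", 0.0, 1000.0),
        )
    )


def unit_square_space() -> ParameterSpace:
    """Uniform density on [0, 1]^2 (analytic test surfaces)."""
    return ParameterSpace(pdfs=(PdfSpec("uniform", 0.0, 1.0), PdfSpec("uniform", 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Tessellation / metamodel
# ---------------------------------------------------------------------------


@dataclass
class SimplexTessellation:
    """Delaunay tessellation of parameter samples carrying QoI values.

    ``extras`` optionally stores one record (dict) per vertex, e.g. the
    accuracy and J10% behind a mesh-distance QoI.
    """

    vertices: np.ndarray
    values: np.ndarray
    extras: Optional[list] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.vertices) != len(self.values):
            raise ValueError("one QoI value per vertex required")
        if len(self.vertices) < 3:
            raise ValueError("need at least 3 vertices")
        try:
            self._delaunay = Delaunay(self.vertices)
        except QhullError as exc:
            raise ValueError(f"degenerate sample set (collinear?): {exc}") from exc

    @property
    def triangles(self) -> np.ndarray:
        return self._delaunay.simplices

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        t = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (t[:, 1, 0] - t[:, 0, 0]) * (t[:, 2, 1] - t[:, 0, 1])
            - (t[:, 2, 0] - t[:, 0, 0]) * (t[:, 1, 1] - t[:, 0, 1])
        )

    def edges(self) -> np.ndarray:
        """Unique undirected edges (k, 2), sorted lexicographically."""
        tri = self.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def barycentric(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing triangle index and barycentric coordinates for points."""
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        simplex = self._delaunay.find_simplex(lam, tol=1e-10)
        if np.any(simplex < 0):
            bad = lam[simplex < 0][0]
            raise ValueError(f"point {bad} lies outside the tessellation hull")
        Tm = self._delaunay.transform[simplex]
        b = np.einsum("nij,nj->ni", Tm[:, :2, :], lam - Tm[:, 2, :])
        bary = np.concatenate([b, 1.0 - b.sum(axis=1, keepdims=True)], axis=1)
        return simplex, bary

    def eval(self, lam: np.ndarray) -> np.ndarray:
        """Piecewise-linear metamodel value(s) at parameter points."""
        simplex, bary = self.barycentric(lam)
        return np.einsum("ni,ni->n", bary, self.values[self.triangles[simplex]])


def metamodel_eval(tess: SimplexTessellation, lam: np.ndarray) -> np.ndarray:
    """Barycentric linear interpolation of vertex QoI values (errors outside hull)."""
    return tess.eval(lam)


@dataclass
class MetricField:
    """Per-vertex 2x2 symmetric positive-definite metric matrices."""

    matrices: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float).reshape(-1, 2, 2)
        sym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if sym > 1e-8 * max(1.0, np.abs(self.matrices).max()):
            raise ValueError("metric matrices must be symmetric")
        if np.any(np.linalg.eigvalsh(self.matrices) <= 0):
            raise ValueError("metric matrices must be positive definite")


@dataclass
class AdaptConfig:
    """Budget and rounds for the adaptive loop."""

    budget: int
    n_adap: int = 4
    n_initial: int = 10
    rng_seed: int = 0
    hessian_neighbors: int = 6


# ---------------------------------------------------------------------------
# Construction and error estimation
# ---------------------------------------------------------------------------


def _evaluate(qoi: Callable, lam: np.ndarray) -> tuple[float, Optional[dict]]:
    out = qoi(lam)
    if isinstance(out, dict):
        return float(out["value"]), out
    return float(out), None


def initial_tessellation(
    space: ParameterSpace,
    n0: int,
    qoi: Callable,
    seed: int = 0,
    include_corners: bool = True,
) -> SimplexTessellation:
    """Random initial samples from pi plus the 4 domain corners, triangulated.

    The corners guarantee that the convex hull equals the full domain, which
    the linear metamodel needs for coverage. Degenerate (collinear) draws are
    redrawn.
    """
    if n0 < 3 and not include_corners:
        raise ValueError("need at least 3 initial samples")
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        pts = space.sample(rng, n0)
        if include_corners:
            pts = np.vstack([space.corners, pts])
        pts = np.unique(pts, axis=0)
        try:
            Delaunay(pts)
        except QhullError:
            logger.warning("degenerate initial draw (attempt %d); redrawing", attempt + 1)
            continue
        values, extras = [], []
        for p in pts:
            v, e = _evaluate(qoi, p)
            values.append(v)
            extras.append(e)
        return SimplexTessellation(
            vertices=pts,
            values=np.array(values),
            extras=extras if any(e is not None for e in extras) else None,
        )
    raise RuntimeError("could not draw a non-degenerate initial sample set")


def interpolation_error_l1(
    tess: SimplexTessellation,
    qoi_true: Callable,
    space: ParameterSpace,
    n_points: int = 10000,
    seed: int = 0,
) -> float:
    """pi-weighted L1 metamodel error, eta = E_pi |Q - Theta_h Q|.

    Estimated by fixed-seed Monte-Carlo quadrature with samples drawn from pi
    (so the estimator is the plain mean of absolute differences).
    """
    rng = np.random.default_rng(seed)
    pts = space.sample(rng, n_points)
    b = space.bounds
    pts = np.clip(pts, b[:, 0], b[:, 1])
    truth = np.asarray([_evaluate(qoi_true, p)[0] for p in pts]) if not _vectorizable(
        qoi_true
    ) else np.asarray(qoi_true(pts), dtype=float)
    approx = tess.eval(pts)
    return float(np.mean(np.abs(truth - approx)))


def _vectorizable(qoi: Callable) -> bool:
    try:
        out = qoi(np.zeros((2, 2)))
    except Exception:
        return False
    return isinstance(out, np.ndarray) and out.shape == (2,)


def _adjacency(tess: SimplexTessellation) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for i, j in tess.edges():
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    return adj


def _patch_hessian(
    tess: SimplexTessellation, vertex: int, adj: dict[int, set[int]], min_neighbors: int
) -> np.ndarray:
    """Weighted least-squares quadratic fit over the vertex's triangulation patch.

    The patch starts at the 1-ring and expands ring by ring until it holds at
    least ``min_neighbors`` neighbours (6 are needed for a 2-D quadratic).
    Patch-local fitting keeps the estimate from smearing curvature across a
    strongly graded tessellation, which a plain k-nearest-neighbour stencil
    does. Gaussian distance weights, bandwidth = median patch distance;
    rank-deficient patches are ridge-regularized.
    """
    patch = {vertex}
    frontier = {vertex}
    while len(patch) < min_neighbors + 1 and frontier:
        frontier = set().union(*(adj.get(v, set()) for v in frontier)) - patch
        patch |= frontier
    idx = np.array(sorted(patch))
    d = tess.vertices[idx] - tess.vertices[vertex]
    dist = np.linalg.norm(d, axis=1)
    pos = dist[dist > 0]
    bw = float(np.median(pos)) if len(pos) else 1.0
    w = np.exp(-0.5 * (dist / max(bw, 1e-12)) ** 2)
    X = np.column_stack(
        [np.ones(len(idx)), d[:, 0], d[:, 1], d[:, 0] ** 2, d[:, 0] * d[:, 1], d[:, 1] ** 2]
    )
    A = X * w[:, None]
    y = tess.values[idx] * w
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 6:
        logger.warning("rank-deficient Hessian patch at vertex %d; regularizing", vertex)
        sol = np.linalg.solve(A.T @ A + 1e-10 * np.eye(6), A.T @ y)
    return np.array([[2 * sol[3], sol[4]], [sol[4], 2 * sol[5]]])


def estimate_qoi_hessian(
    tess: SimplexTessellation,
    vertex: int,
    k: int = 6,
    weighted: bool = False,
    space: Optional[ParameterSpace] = None,
) -> np.ndarray:
    """Hessian of Q at a vertex recovered from surrounding samples.

    Needs at least 6 samples in the neighbourhood; ``k`` is the minimum
    neighbour count of the fitting patch. With ``weighted=True`` the result
    is multiplied by pi(lambda) (requires ``space``).
    """
    if tess.n_vertices < 6:
        raise ValueError("need at least 6 samples to estimate a 2-D Hessian")
    H = _patch_hessian(tess, vertex, _adjacency(tess), max(k, 6))
    if weighted:
        if space is None:
            raise ValueError("space required for the pdf-weighted Hessian")
        H = H * float(space.pdf(tess.vertices[vertex])[0])
    return H


def _abs_spd(H: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """|H| via eigen-decomposition with absolute eigenvalues floored for SPD-ness."""
    vals, vecs = np.linalg.eigh(H)
    vals = np.maximum(np.abs(vals), floor)
    return (vecs * vals) @ vecs.T


def _vertex_hessians(tess: SimplexTessellation, k: int = 6) -> np.ndarray:
    adj = _adjacency(tess)
    return np.stack(
        [_patch_hessian(tess, v, adj, max(k, 6)) for v in range(tess.n_vertices)]
    )


def _density_integral(
    tess: SimplexTessellation, space: ParameterSpace, hessians: np.ndarray
) -> tuple[float, np.ndarray]:
    """Integral over the domain of det(pi |H|)^(1/(2+n)) and the per-vertex
    integrand values (vertex-mean quadrature per triangle)."""
    n = space.n
    pi_v = space.pdf(tess.vertices)
    # |det(pi H)| without the SPD floor: a truly flat response contributes 0
    g = np.abs(np.linalg.det(hessians * pi_v[:, None, None])) ** (1.0 / (2.0 + n))
    areas = tess.triangle_areas()
    integral = float(np.sum(areas * g[tess.triangles].mean(axis=1)))
    return integral, g


def optimal_metric(
    tess: SimplexTessellation,
    space: ParameterSpace,
    budget: int,
    hessians: Optional[np.ndarray] = None,
    k: int = 10,
) -> MetricField:
    """The continuous-framework optimal metric for a complexity budget C.

    M_opt(lam) = C^(2/n) (Int det(pi|H|)^(1/(2+n)) dlam)^(-2/n)
                 det(pi|H|)^(-1/(2+n)) pi|H|.

    Doubling C scales the metric by 2^(2/n). With vanishing Hessians the
    metric degenerates; an isotropic fallback (uniform refinement) is
    returned with a warning.
    """
    n = space.n
    if hessians is None:
        hessians = _vertex_hessians(tess, k=k)
    integral, g = _density_integral(tess, space, hessians)
    if integral <= 1e-300:
        warnings.warn(
            "all Hessians vanish; falling back to an isotropic metric (uniform refinement)",
            stacklevel=2,
        )
        iso = budget ** (2.0 / n) / space.area * np.eye(2)
        return MetricField(np.broadcast_to(iso, (tess.n_vertices, 2, 2)).copy())
    pi_v = space.pdf(tess.vertices)
    mats = np.empty((tess.n_vertices, 2, 2))
    scale = budget ** (2.0 / n) * integral ** (-2.0 / n)
    for v in range(tess.n_vertices):
        absH = _abs_spd(hessians[v] * pi_v[v])
        mats[v] = scale * np.linalg.det(absH) ** (-1.0 / (2.0 + n)) * absH
    return MetricField(mats)


def error_on_metric(
    tess: SimplexTessellation,
    space: ParameterSpace,
    budget: int,
    hessians: Optional[np.ndarray] = None,
    k: int = 10,
) -> float:
    """Closed-form optimal error estimate:

    E = n C^(-2/n) (Int det(pi|H|)^(1/(2+n)) dlam)^((2+n)/n).

    For n = 2 this decays like C^(-1); zero Hessians give 0.
    """
    n = space.n
    if hessians is None:
        hessians = _vertex_hessians(tess, k=k)
    integral, _ = _density_integral(tess, space, hessians)
    return float(n * budget ** (-2.0 / n) * integral ** ((2.0 + n) / n))


# ---------------------------------------------------------------------------
# Refinement and the adaptive loop
# ---------------------------------------------------------------------------


def refine(
    tess: SimplexTessellation,
    metric: MetricField,
    n_new: int,
    qoi: Callable,
    seed: int = 0,
) -> SimplexTessellation:
    """Insert ``n_new`` vertices at midpoints of the metric-longest edges.

    Edge length is measured as sqrt(e^T M_bar e) with M_bar the average of the
    endpoint metrics; ties break on the lowest vertex-index pair. The point
    set is re-triangulated by Delaunay; existing vertices and values are
    retained and the QoI is evaluated at the new vertices only.
    """
    if n_new < 1:
        raise ValueError("n_new must be >= 1")
    rng = np.random.default_rng(seed)
    verts = tess.vertices.copy()
    values = list(tess.values)
    extras = list(tess.extras) if tess.extras is not None else None
    mats = list(metric.matrices)
    if len(mats) != len(verts):
        raise ValueError("metric field size does not match vertex count")
    added = 0
    current = tess
    while added < n_new:
        edges = current.edges()
        e_vec = verts[edges[:, 1]] - verts[edges[:, 0]]
        M_arr = np.asarray(mats)
        M_bar = 0.5 * (M_arr[edges[:, 0]] + M_arr[edges[:, 1]])
        lengths = np.sqrt(np.einsum("ki,kij,kj->k", e_vec, M_bar, e_vec))
        order = np.lexsort((edges[:, 1], edges[:, 0], -lengths))
        batch = min(n_new - added, len(order))
        for ei in order[:batch]:
            mid = 0.5 * (verts[edges[ei, 0]] + verts[edges[ei, 1]])
            if _is_duplicate(mid, verts):
                mid = mid + 1e-9 * e_vec[ei] * rng.uniform(0.5, 1.0)
                logger.info("perturbed duplicate insertion point")
            v, e = _evaluate(qoi, mid)
            verts = np.vstack([verts, mid])
            values.append(v)
            mats.append(M_bar[ei])  # new vertex inherits the edge-average metric
            if extras is not None:
                extras.append(e)
        added += batch
        current = SimplexTessellation(vertices=verts, values=np.array(values), extras=extras)
    return current


def _is_duplicate(p: np.ndarray, pts: np.ndarray, tol: float = 1e-12) -> bool:
    if len(pts) == 0:
        return False
    return bool(np.min(np.linalg.norm(pts - p, axis=1)) < tol)


def adapt(
    space: ParameterSpace,
    qoi: Callable,
    cfg: AdaptConfig,
) -> tuple[SimplexTessellation, dict]:
    """Adaptive metamodel construction with a fixed evaluation budget.

    Runs the initial tessellation, then ``n_adap`` rounds of Hessian
    estimation -> optimal metric -> metric-driven edge refinement,
    distributing the remaining budget evenly across rounds (remainder to the
    last). Returns the final tessellation and statistics: pi-weighted mean
    and variance of the metamodel, the optimal-metric error estimate, and the
    evaluation count.
    """
    tess = initial_tessellation(space, cfg.n_initial, qoi, seed=cfg.rng_seed)
    n0 = tess.n_vertices
    if cfg.budget < n0:
        raise ValueError(f"budget {cfg.budget} below initial sample count {n0}")
    remaining = cfg.budget - n0
    per_round = remaining // cfg.n_adap if cfg.n_adap > 0 else 0
    error_estimate = None
    for round_idx in range(cfg.n_adap):
        n_new = per_round if round_idx < cfg.n_adap - 1 else remaining - per_round * (
            cfg.n_adap - 1
        )
        if n_new <= 0:
            continue
        hess = _vertex_hessians(tess, k=cfg.hessian_neighbors)
        metric = optimal_metric(tess, space, cfg.budget, hessians=hess)
        error_estimate = error_on_metric(tess, space, cfg.budget, hessians=hess)
        tess = refine(tess, metric, n_new, qoi, seed=cfg.rng_seed + 1 + round_idx)
    rng = np.random.default_rng(cfg.rng_seed + 10_000)
    pts = space.sample(rng, 10000)
    b = space.bounds
    vals = tess.eval(np.clip(pts, b[:, 0], b[:, 1]))
    stats = {
        "mean": float(vals.mean()),
        "variance": float(vals.var()),
        "error_estimate": error_estimate,
        "n_evaluations": tess.n_vertices,
    }
    return tess, stats
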