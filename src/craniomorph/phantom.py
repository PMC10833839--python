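"""Deterministic synthetic head/neck phantom with known ground truth.

Real head/neck CT exams suitable for this pipeline are large and rarely
shareable, so the phantom emulates their essential structure: a bright bone
shell (ellipsoid, ~+700 HU) enclosing a mid-intensity soft-tissue body
(~+40 HU) that contains an air cavity (mouth analogue, -1000 HU) bounded
below by a tongue-like organ. The pair of volumes is related by a known
smooth, diffeomorphic, mirror-symmetric FFD; paired landmarks sit on the
bone shell, a tetrahedral mesh and a mask cover the organ, and evaluation
points sample the organ-air interface in the moving frame.

Everything is a deterministic function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import Delaunay

from .ffd import AffineTransform, FFDTransform, build_symmetric_grid
from .meshtools import SurfacePointSet, TetMesh
from .volumes import LandmarkSet, MaskVolume, SideLabelImage, VolumeImage

__all__ = ["PhantomSpec", "PhantomPair", "generate_pair", "analytic_qoi", "AnalyticQoI"]

_AIR = -1000.0


@dataclass
class PhantomSpec:
    """Geometry, intensities and ground-truth deformation of the phantom.

    Lengths in mm, intensities in HU. The volume is centered on the world
    origin with the mid-sagittal plane along axis 0; geometry radii default to
    head-like proportions for the default 64^3 grid at 2.5 mm spacing
    (160 mm field of view).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.5
    bone_outer_radii: tuple[float, float, float] = (58.0, 66.0, 62.0)
    shell_thickness: float = 7.0
    bone_hu: float = 700.0
    soft_hu: float = 40.0
    cavity_center: tuple[float, float, float] = (0.0, 28.0, -16.0)
    cavity_radii: tuple[float, float, float] = (18.0, 22.0, 17.0)
    organ_center: tuple[float, float, float] = (0.0, 28.0, -30.0)
    organ_radii: tuple[float, float, float] = (15.0, 19.0, 13.0)
    edge_width: float = 1.5
    n_landmarks: int = 21
    deformation: str = "random"  # random | zero | translation
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation_spacing: float = 24.0
    max_displacement: float = 8.0
    min_jacobian: float = 0.2
    noise_sd: float = 10.0
    n_surface_points: int = 608
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation not in ("random", "zero", "translation"):
            raise ValueError(f"unknown deformation kind {self.deformation!r}")
        if self.deformation_spacing < 20.0:
            raise ValueError("ground-truth lattice spacing must be >= 20 mm")


@dataclass
class PhantomPair:
    """All artefacts of one generated phantom pair."""

    fixed: VolumeImage
    moving: VolumeImage
    fixed_side: SideLabelImage
    moving_side: SideLabelImage
    fixed_landmarks: LandmarkSet
    moving_landmarks: LandmarkSet
    ground_truth: FFDTransform
    organ_mesh: TetMesh  # fixed frame
    surface_points: SurfacePointSet  # moving frame
    organ_mask: MaskVolume  # fixed frame
    evaluation_points: np.ndarray  # fixed-frame points withheld from the cost


# ---------------------------------------------------------------------------
# Analytic phantom intensity field
# ---------------------------------------------------------------------------


def _smooth_inside(points: np.ndarray, center, radii, width: float) -> np.ndarray:
    """Smoothed indicator of an ellipsoid: 1 inside, 0 outside, ~width mm edge."""
    q = (points - np.asarray(center)) / np.asarray(radii)
    rho = np.linalg.norm(q, axis=-1)
    # approximate signed distance to the ellipsoid surface
    d = (rho - 1.0) * float(np.min(radii))
    return 0.5 * (1.0 - np.tanh(d / max(width, 1e-6)))


def _intensity(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """HU intensity of the undeformed phantom at world points."""
    outer = _smooth_inside(points, (0, 0, 0), spec.bone_outer_radii, spec.edge_width)
    inner_radii = tuple(r - spec.shell_thickness for r in spec.bone_outer_radii)
    inner = _smooth_inside(points, (0, 0, 0), inner_radii, spec.edge_width)
    cavity = _smooth_inside(points, spec.cavity_center, spec.cavity_radii, spec.edge_width)
    organ = _smooth_inside(points, spec.organ_center, spec.organ_radii, spec.edge_width)
    air_in_cavity = cavity * (1.0 - organ)
    hu = _AIR * (1.0 - outer)  # outside the head: air
    hu += spec.bone_hu * (outer - inner * outer)  # shell
    soft = inner * outer
    hu += soft * ((1.0 - air_in_cavity) * spec.soft_hu + air_in_cavity * _AIR)
    return hu


# ---------------------------------------------------------------------------
# Ground-truth deformation
# ---------------------------------------------------------------------------


def _symmetrize_coefficients(coef: np.ndarray) -> np.ndarray:
    """Make the displacement field commute with the mid-sagittal mirror.

    For a lattice whose control coordinates are mirror-symmetric about the
    plane (axis 0), this averages each coefficient with its mirrored partner
    (axis-0 component negated).
    """
    mirrored = np.flip(coef, axis=0).copy()
    mirrored[..., 0] *= -1.0
    return 0.5 * (coef + mirrored)


def _ground_truth_transform(
    spec: PhantomSpec, domain: VolumeImage, rng: np.random.Generator
) -> FFDTransform:
    T = build_symmetric_grid(domain, spec.deformation_spacing, plane_axis=0, plane_coord=0.0)
    if spec.deformation == "zero":
        return T
    if spec.deformation == "translation":
        coef = np.tile(np.asarray(spec.translation, dtype=float), T.control_shape + (1,))
        return FFDTransform(T.control_origin, T.control_spacing, coef)
    coef = rng.normal(size=T.control_shape + (3,))
    coef = _symmetrize_coefficients(coef)
    T = FFDTransform(T.control_origin, T.control_spacing, coef)
    # scale so the max displacement magnitude over the volume is as requested
    probe = domain.voxel_centers()[::2, ::2, ::2].reshape(-1, 3)
    mag = np.linalg.norm(T.displacement(probe), axis=1).max()
    coef *= spec.max_displacement / max(mag, 1e-12)
    return FFDTransform(T.control_origin, T.control_spacing, coef)


def _invert_displacement(
    T: FFDTransform, targets: np.ndarray, iterations: int = 40
) -> np.ndarray:
    """Solve T(x) = y for x by fixed-point iteration x <- y - D(x).

    Valid for the phantom's smooth, contractive displacement fields (identity
    pre-affine). Iterates are clipped into the lattice support box.
    """
    lo = T.control_origin + T.control_spacing
    hi = T.control_origin + (np.array(T.control_shape) - 2) * T.control_spacing
    x = np.clip(targets, lo, hi)
    for _ in range(iterations):
        x = np.clip(targets - T.displacement(x), lo, hi)
    return x


# ---------------------------------------------------------------------------
# Landmarks, organ mesh, surface points
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic well-spread unit directions (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _landmarks(spec: PhantomSpec) -> LandmarkSet:
    """21 landmarks on the bone shell: 19 mid-sagittal, ids 20/21 off-midline.

    Mirrors the conventional anatomical layout (most landmarks on the
    mid-sagittal plane, two lateral orbital points) so the standard affine
    subset {2, 4, 7, 20, 21} is well-conditioned (non-coplanar).
    """
    n = spec.n_landmarks
    mid_radii = np.array(spec.bone_outer_radii) - spec.shell_thickness / 2.0
    n_mid = max(n - 2, 3)
    ang = np.linspace(0.0, 2.0 * np.pi, n_mid, endpoint=False)
    pts = np.zeros((n, 3))
    pts[:n_mid, 1] = mid_radii[1] * np.cos(ang)
    pts[:n_mid, 2] = mid_radii[2] * np.sin(ang)
    for k in range(n - n_mid):  # off-midline pair (the "orbitale" analogues)
        side = 1.0 if k % 2 == 0 else -1.0
        d = np.array([side * 0.55, 0.55, 0.35])
        d /= np.linalg.norm(d / mid_radii)  # scale to the shell mid-surface
        pts[n_mid + k] = d
    ids = np.arange(1, n + 1)
    names = [f"midline_{i}" for i in range(1, n_mid + 1)] + [
        f"lateral_{'right' if k % 2 == 0 else 'left'}" for k in range(n - n_mid)
    ]
    return LandmarkSet(ids=ids, names=names, points=pts)


def _organ_mesh(spec: PhantomSpec, n_surface: int = 180, grid_step: float = 5.0) -> TetMesh:
    """Tetrahedral mesh of the organ ellipsoid (Delaunay of interior + surface points)."""
    c = np.asarray(spec.organ_center)
    r = np.asarray(spec.organ_radii)
    axes = [np.arange(-rr, rr + 1e-9, grid_step) for rr in r]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    interior = g[np.linalg.norm(g / r, axis=1) <= 0.88]
    # deterministic jitter puts the lattice points in general position so the
    # Delaunay tetrahedralization has no degenerate simplices and its boundary
    # is exactly the (watertight) convex hull
    interior = interior + np.random.default_rng(12345).uniform(
        -1e-3, 1e-3, interior.shape
    ) * grid_step
    surface = _fibonacci_directions(n_surface) * r
    pts = np.vstack([interior, surface]) + c
    tess = Delaunay(pts - c)
    return TetMesh(nodes=pts, tets=tess.simplices).oriented()


# ---------------------------------------------------------------------------
# Pair generation
# ---------------------------------------------------------------------------


def generate_pair(spec: PhantomSpec | None = None) -> PhantomPair:
    """Generate a deterministic phantom pair with known ground truth.

    The moving volume is the analytic phantom observed through the inverse of
    the ground-truth map (so that fixed(x) ~ moving(T_gt(x))) plus Gaussian
    noise; moving landmarks are the exact images of the fixed landmarks.
    Raises if the requested deformation folds (min Jacobian <= threshold).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=int)
    origin = -(shape - 1) / 2.0 * spec.spacing
    grid = VolumeImage(np.zeros(tuple(shape)), spacing=[spec.spacing] * 3, origin=origin)
    centers = grid.voxel_centers().reshape(-1, 3)

    fixed_data = _intensity(centers, spec).reshape(tuple(shape))
    fixed = VolumeImage(fixed_data, grid.spacing.copy(), grid.origin.copy())

    T_gt = _ground_truth_transform(spec, grid, rng)

    head = _smooth_inside(centers, (0, 0, 0), spec.bone_outer_radii, spec.edge_width) > 0.5
    if spec.deformation == "random":
        J = T_gt.jacobian_det(centers[head])
        if J.min() <= spec.min_jacobian:
            raise ValueError(
                f"ground-truth deformation folds: min Jacobian {J.min():.3f} <= "
                f"{spec.min_jacobian}; reduce max_displacement or coarsen the lattice"
            )

    # moving volume: evaluate the analytic phantom at T_gt^{-1}(voxel center)
    if spec.deformation == "zero":
        moving_data = fixed_data.copy()
    else:
        pre = _invert_displacement(T_gt, centers)
        moving_data = _intensity(pre, spec).reshape(tuple(shape))
    if spec.noise_sd > 0:
        moving_data = moving_data + rng.normal(0.0, spec.noise_sd, size=moving_data.shape)
    moving = VolumeImage(moving_data, grid.spacing.copy(), grid.origin.copy())

    side = (centers[:, 0] >= 0.0).astype(float).reshape(tuple(shape))
    fixed_side = SideLabelImage(side.copy(), grid.spacing.copy(), grid.origin.copy())
    moving_side = SideLabelImage(side.copy(), grid.spacing.copy(), grid.origin.copy())

    L_h = _landmarks(spec)
    L_b = L_h.transformed(T_gt.apply)

    organ_mesh = _organ_mesh(spec)
    organ = _smooth_inside(centers, spec.organ_center, spec.organ_radii, spec.edge_width)
    organ_mask = MaskVolume((organ > 0.5).reshape(tuple(shape)), grid.spacing.copy(), grid.origin.copy())

    # evaluation points withheld from the cost: spread through the soft tissue
    inner_radii = tuple(r - spec.shell_thickness for r in spec.bone_outer_radii)
    soft_idx = np.flatnonzero(
        _smooth_inside(centers, (0, 0, 0), inner_radii, spec.edge_width).ravel() > 0.5
    )
    eval_points = centers[rng.choice(soft_idx, size=min(500, len(soft_idx)), replace=False)]

    # organ-air interface points in the moving frame (upper organ surface)
    dirs = _fibonacci_directions(2 * spec.n_surface_points)
    upper = dirs[dirs[:, 2] > 0.0][: spec.n_surface_points]
    surf_fixed = upper * np.asarray(spec.organ_radii) + np.asarray(spec.organ_center)
    surface_points = SurfacePointSet(T_gt.apply(surf_fixed))

    return PhantomPair(
        fixed=fixed,
        moving=moving,
        fixed_side=fixed_side,
        moving_side=moving_side,
        fixed_landmarks=L_h,
        moving_landmarks=L_b,
        ground_truth=T_gt,
        organ_mesh=organ_mesh,
        surface_points=surface_points,
        organ_mask=organ_mask,
        evaluation_points=eval_points,
    )


# ---------------------------------------------------------------------------
# Analytic QoI surfaces for the UQ module
# ---------------------------------------------------------------------------


@dataclass
class AnalyticQoI:
    """Closed-form scalar field on [0, 1]^2 with a documented Hessian."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    hessian_fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        return self.fn(np.asarray(lam, dtype=float))

    def hessian(self, lam: np.ndarray) -> np.ndarray:
        return self.hessian_fn(np.asarray(lam, dtype=float))


def analytic_qoi(name: str) -> AnalyticQoI:
    """Test response surfaces: affine, quadratic, gaussian_bump, step.

    The step surface exercises the collocation method's ability to capture
    near-discontinuous responses; its Hessian is zero on both sides of the
    jump.
    """
    if name == "affine":
        return AnalyticQoI(
            name,
            lambda l: 2.0 * l[..., 0] + 3.0 * l[..., 1] + 1.0,
            lambda l: np.zeros(l.shape[:-1] + (2, 2)),
        )
    if name == "quadratic":
        return AnalyticQoI(
            name,
            lambda l: l[..., 0] ** 2 + l[..., 1] ** 2,
            lambda l: np.broadcast_to(2.0 * np.eye(2), l.shape[:-1] + (2, 2)).copy(),
        )
    if name == "gaussian_bump":
        c = np.array([0.75, 0.75])
        a = 10.0

        def fn(l: np.ndarray) -> np.ndarray:
            return np.exp(-a * np.sum((l - c) ** 2, axis=-1))

        def hess(l: np.ndarray) -> np.ndarray:
            d = l - c
            f = fn(l)[..., None, None]
            outer = d[..., :, None] * d[..., None, :]
            return f * (4.0 * a * a * outer - 2.0 * a * np.eye(2))

        return AnalyticQoI(name, fn, hess)
    if name == "step":
        return AnalyticQoI(
            name,
            lambda l: (l[..., 0] + l[..., 1] > 1.0).astype(float),
            lambda l: np.zeros(l.shape[:-1] + (2, 2)),
        )
    raise ValueError(f"unknown analytic QoI {name!r}")
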