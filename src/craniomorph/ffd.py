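"""Transformation models: affine and cubic-B-spline free-form deformation.

The free-form deformation (FFD) maps a point x of the fixed domain to

    T(x) = A x + t + sum_k B3((x - c_k) / h) mu_k,

where A, t form an affine pre-transform, c_k are control points on a regular
axis-aligned lattice with spacing h, B3 is the tensor-product cubic B-spline,
and mu_k are per-control-point displacement vectors (mm). Spatial first and
second derivatives are analytic (B-spline derivative weights); finite
differences are used only as test oracles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .volumes import LandmarkSet, MaskVolume, VolumeImage, central_plane_coord

__all__ = [
    "AffineTransform",
    "FFDTransform",
    "GridSchedule",
    "build_symmetric_grid",
    "fit_affine_landmarks",
    "bending_energy",
]

_OFFSETS = np.array(list(product(range(4), repeat=3)), dtype=int)  # (64, 3)


# ---------------------------------------------------------------------------
# Cubic B-spline basis
# ---------------------------------------------------------------------------


def cubic_bspline_weights(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline weights over the 4 supporting control points.

    ``u`` in [0, 1) is the fractional lattice coordinate; returns (n, 4).
    The weights sum to one (partition of unity).
    """
    u = np.asarray(u, dtype=float)
    u2, u3 = u * u, u * u * u
    w = np.empty(u.shape + (4,))
    w[..., 0] = (1 - u) ** 3 / 6.0
    w[..., 1] = (3 * u3 - 6 * u2 + 4) / 6.0
    w[..., 2] = (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0
    w[..., 3] = u3 / 6.0
    return w


def cubic_bspline_weights_d1(u: np.ndarray) -> np.ndarray:
    """First derivative (w.r.t. u) of the cubic B-spline weights."""
    u = np.asarray(u, dtype=float)
    u2 = u * u
    w = np.empty(u.shape + (4,))
    w[..., 0] = -((1 - u) ** 2) / 2.0
    w[..., 1] = (3 * u2 - 4 * u) / 2.0
    w[..., 2] = (-3 * u2 + 2 * u + 1) / 2.0
    w[..., 3] = u2 / 2.0
    return w


def cubic_bspline_weights_d2(u: np.ndarray) -> np.ndarray:
    """Second derivative (w.r.t. u) of the cubic B-spline weights."""
    u = np.asarray(u, dtype=float)
    w = np.empty(u.shape + (4,))
    w[..., 0] = 1 - u
    w[..., 1] = 3 * u - 2
    w[..., 2] = -3 * u + 1
    w[..., 3] = u
    return w


# ---------------------------------------------------------------------------
# Affine transform
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """Affine map x -> matrix @ x + translation (mm)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_rotation_scale(
        cls,
        rotvec: Sequence[float] = (0, 0, 0),
        scale: Sequence[float] = (1, 1, 1),
        translation: Sequence[float] = (0, 0, 0),
    ) -> "AffineTransform":
        """Rotation (rotation-vector, radians) composed with anisotropic scaling."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls(matrix=R @ np.diag(np.asarray(scale, dtype=float)), translation=translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    __call__ = apply

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, translation=-inv @ self.translation)

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(
            np.all(np.abs(self.matrix - np.eye(3)) <= tol)
            and np.all(np.abs(self.translation) <= tol)
        )

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(matrix=np.array(d["matrix"]), translation=np.array(d["translation"]))


# ---------------------------------------------------------------------------
# FFD transform
# ---------------------------------------------------------------------------


@dataclass
class FFDTransform:
    """Cubic B-spline free-form deformation with an affine pre-transform.

    ``coefficients`` has shape (Nx, Ny, Nz, 3): the displacement (mm) attached
    to each control point. Control point (i, j, k) sits at world coordinate
    ``control_origin + (i, j, k) * control_spacing``.
    """

    control_origin: np.ndarray
    control_spacing: np.ndarray
    coefficients: np.ndarray
    pre_affine: AffineTransform = field(default_factory=AffineTransform.identity)

    def __post_init__(self) -> None:
        self.control_origin = np.asarray(self.control_origin, dtype=float).reshape(3)
        self.control_spacing = np.asarray(self.control_spacing, dtype=float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (Nx, Ny, Nz, 3)")
        if np.any(self.control_spacing <= 0):
            raise ValueError("control spacing must be > 0")
        if np.any(np.array(self.control_shape) < 4):
            raise ValueError("lattice needs at least 4 control points per axis")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def control_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    @property
    def n_parameters(self) -> int:
        return self.coefficients.size

    def control_coords(self, axis: int) -> np.ndarray:
        n = self.control_shape[axis]
        return self.control_origin[axis] + np.arange(n) * self.control_spacing[axis]

    # -- support ----------------------------------------------------------

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (base, u): base lattice index of the 4^3 support and the
        fractional coordinate in [0, 1). Raises for points outside support."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = (pts - self.control_origin) / self.control_spacing
        shape = np.array(self.control_shape)
        # valid iff 1 <= t <= N-2 (support needs indices floor(t)-1 .. floor(t)+2)
        eps = 1e-9
        bad = np.any((t < 1.0 - eps) | (t > shape - 2 + eps), axis=1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point {pts[i]} outside the FFD lattice support "
                f"(lattice origin {self.control_origin}, shape {tuple(shape)})"
            )
        t = np.clip(t, 1.0, shape - 2 - 1e-12)
        base = np.floor(t).astype(int) - 1
        u = t - (base + 1)
        return base, u

    # -- evaluation -------------------------------------------------------

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """B-spline displacement field (mm) at world points, shape (n, 3)."""
        base, u = self.locate(points)
        wx = cubic_bspline_weights(u[:, 0])
        wy = cubic_bspline_weights(u[:, 1])
        wz = cubic_bspline_weights(u[:, 2])
        disp = np.zeros((len(base), 3))
        c = self.coefficients
        for a, b, d in _OFFSETS:
            w = wx[:, a] * wy[:, b] * wz[:, d]
            disp += w[:, None] * c[base[:, 0] + a, base[:, 1] + b, base[:, 2] + d]
        return disp

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.pre_affine.apply(pts) + self.displacement(pts)

    __call__ = apply

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Spatial gradient dT/dx, shape (n, 3, 3): G[p, c, a] = dT_c/dx_a."""
        base, u = self.locate(points)
        w = [cubic_bspline_weights(u[:, ax]) for ax in range(3)]
        dw = [
            cubic_bspline_weights_d1(u[:, ax]) / self.control_spacing[ax] for ax in range(3)
        ]
        n = len(base)
        grad = np.zeros((n, 3, 3))
        c = self.coefficients
        for a, b, d in _OFFSETS:
            coef = c[base[:, 0] + a, base[:, 1] + b, base[:, 2] + d]  # (n, 3)
            grad[:, :, 0] += (dw[0][:, a] * w[1][:, b] * w[2][:, d])[:, None] * coef
            grad[:, :, 1] += (w[0][:, a] * dw[1][:, b] * w[2][:, d])[:, None] * coef
            grad[:, :, 2] += (w[0][:, a] * w[1][:, b] * dw[2][:, d])[:, None] * coef
        grad += self.pre_affine.matrix[None, :, :]
        return grad

    def jacobian_det(self, points: np.ndarray) -> np.ndarray:
        """det(grad T) at each point: the local volume-change factor."""
        return np.linalg.det(self.gradient(points))

    def hessian(self, points: np.ndarray) -> np.ndarray:
        """Second derivatives, shape (n, 3, 3, 3): H[p, c, a, b] = d2T_c/dx_a dx_b.

        The affine part contributes nothing; H is linear in the coefficients.
        """
        base, u = self.locate(points)
        h = self.control_spacing
        w0 = [cubic_bspline_weights(u[:, ax]) for ax in range(3)]
        w1 = [cubic_bspline_weights_d1(u[:, ax]) / h[ax] for ax in range(3)]
        w2 = [cubic_bspline_weights_d2(u[:, ax]) / h[ax] ** 2 for ax in range(3)]
        n = len(base)
        H = np.zeros((n, 3, 3, 3))
        c = self.coefficients
        for a, b, d in _OFFSETS:
            coef = c[base[:, 0] + a, base[:, 1] + b, base[:, 2] + d]
            fac = {
                (0, 0): w2[0][:, a] * w0[1][:, b] * w0[2][:, d],
                (1, 1): w0[0][:, a] * w2[1][:, b] * w0[2][:, d],
                (2, 2): w0[0][:, a] * w0[1][:, b] * w2[2][:, d],
                (0, 1): w1[0][:, a] * w1[1][:, b] * w0[2][:, d],
                (0, 2): w1[0][:, a] * w0[1][:, b] * w1[2][:, d],
                (1, 2): w0[0][:, a] * w1[1][:, b] * w1[2][:, d],
            }
            for (p, q), f in fac.items():
                H[:, :, p, q] += f[:, None] * coef
                if p != q:
                    H[:, :, q, p] += f[:, None] * coef
        return H

    # -- multi-resolution -------------------------------------------------

    def subdivide(self) -> "FFDTransform":
        """Halve the lattice spacing via cubic B-spline two-scale subdivision.

        The refined transform reproduces the displacement field exactly over
        the entire valid support region of the coarse lattice.
        """
        c = self.coefficients
        for axis in range(3):
            c = _subdivide_axis(c, axis)
        return FFDTransform(
            control_origin=self.control_origin + self.control_spacing / 2.0,
            control_spacing=self.control_spacing / 2.0,
            coefficients=c,
            pre_affine=AffineTransform(
                matrix=self.pre_affine.matrix.copy(),
                translation=self.pre_affine.translation.copy(),
            ),
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "ffd_cubic_bspline",
            "control_origin": self.control_origin.tolist(),
            "control_spacing": self.control_spacing.tolist(),
            "control_shape": list(self.control_shape),
            "coefficients": self.coefficients.ravel().tolist(),
            "pre_affine": self.pre_affine.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FFDTransform":
        shape = tuple(d["control_shape"]) + (3,)
        return cls(
            control_origin=np.array(d["control_origin"]),
            control_spacing=np.array(d["control_spacing"]),
            coefficients=np.array(d["coefficients"]).reshape(shape),
            pre_affine=AffineTransform.from_dict(d["pre_affine"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "FFDTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _subdivide_axis(c: np.ndarray, axis: int) -> np.ndarray:
    """Two-scale refinement of B-spline coefficients along one axis (N -> 2N-3)."""
    c = np.moveaxis(c, axis, 0)
    n = c.shape[0]
    out = np.empty((2 * n - 3,) + c.shape[1:])
    # fine index m corresponds to knot o + h/2 + m*h/2, i.e. coarse index j=m+1
    # odd j = 2i+1 -> (c_i + c_{i+1}) / 2 ; even j = 2i -> (c_{i-1} + 6 c_i + c_{i+1}) / 8
    out[0::2] = (c[:-1] + c[1:]) / 2.0  # m even -> j odd, i = m/2
    out[1::2] = (c[:-2] + 6.0 * c[1:-1] + c[2:]) / 8.0  # m odd -> j even, i = (m+1)/2
    return np.moveaxis(out, 0, axis)


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------


@dataclass
class GridSchedule:
    """Three-level multi-resolution schedule: images and lattice refine by 2.

    ``finest_spacing`` is the finest control-grid spacing (mm); the coarser
    levels use 2x and 4x that spacing, and the images are downsampled by the
    matching factors.
    """

    finest_spacing: float
    levels: int = 3

    def spacing_at(self, level: int) -> float:
        """Control-grid spacing at ``level`` (0 = coarsest)."""
        return self.finest_spacing * 2 ** (self.levels - 1 - level)

    def image_factor_at(self, level: int) -> int:
        return 2 ** (self.levels - 1 - level)


def build_symmetric_grid(
    domain: VolumeImage,
    spacing: float | Sequence[float],
    plane_axis: int = 0,
    plane_coord: float | None = None,
    pre_affine: AffineTransform | None = None,
) -> FFDTransform:
    """Build a zero-coefficient FFD lattice covering ``domain``.

    Along ``plane_axis`` the control-point world coordinates are exactly
    mirror-symmetric about the mid-sagittal plane (a control point lies on the
    plane). The lattice includes the cubic-B-spline support margin (one extra
    control span beyond the domain on each side).
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).astype(float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be > 0")
    if plane_coord is None:
        plane_coord = central_plane_coord(domain, plane_axis)
    lo, hi = domain.world_bounds()
    origin = np.zeros(3)
    shape = np.zeros(3, dtype=int)
    for ax in range(3):
        h = spacing[ax]
        center = plane_coord if ax == plane_axis else 0.5 * (lo[ax] + hi[ax])
        # valid support is [origin + h, origin + (N-2) h]; symmetric about center
        half = max(center - lo[ax], hi[ax] - center)
        k = int(np.ceil(half / h + 1.0 + 1e-9))
        origin[ax] = center - k * h
        shape[ax] = 2 * k + 1
    coef = np.zeros(tuple(shape) + (3,))
    return FFDTransform(
        control_origin=origin,
        control_spacing=spacing,
        coefficients=coef,
        pre_affine=pre_affine if pre_affine is not None else AffineTransform.identity(),
    )


# ---------------------------------------------------------------------------
# Bending energy
# ---------------------------------------------------------------------------


def bending_energy(
    transform: FFDTransform, domain: MaskVolume, chunk: int = 50000
) -> float:
    """Mean squared Frobenius norm of the second-derivative tensor over a mask.

    Exactly zero for any affine transform (constant or zero coefficients).
    """
    if domain.count == 0:
        raise ValueError("bending energy over an empty domain is undefined")
    pts = domain.world_points()
    total = 0.0
    for start in range(0, len(pts), chunk):
        H = transform.hessian(pts[start : start + chunk])
        total += float(np.sum(H * H))
    return total / len(pts)


# ---------------------------------------------------------------------------
# Landmark-based affine initialization
# ---------------------------------------------------------------------------


def _params_to_affine(params: np.ndarray) -> AffineTransform:
    t, rotvec, logs = params[0:3], params[3:6], params[6:9]
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return AffineTransform(matrix=R @ np.diag(np.exp(logs)), translation=t)


def fit_affine_landmarks(
    fixed: LandmarkSet,
    moving: LandmarkSet,
    subset: Sequence[int] | None = None,
) -> tuple[AffineTransform, float]:
    """Fit translation + rotation + anisotropic scaling between paired landmarks.

    Minimizes the mean Euclidean distance from mapped fixed-subset points to the
    moving-subset points. Returns (transform, residual in mm). With fewer than
    3 points the problem is underdetermined and an error is raised; coplanar
    points trigger a warning and the out-of-plane scale is fixed to 1.
    """
    if subset is not None:
        fixed = fixed.subset(subset)
        moving = moving.subset(subset)
    fixed.paired_with(moving)
    P, Q = fixed.points, moving.points
    if len(P) < 3:
        raise ValueError("affine initialization needs at least 3 landmark pairs")

    centered = P - P.mean(axis=0)
    coplanar = np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9 * max(
        1.0, np.abs(centered).max()
    )
    if coplanar:
        warnings.warn(
            "landmark subset is coplanar; out-of-plane scaling is not recoverable "
            "and is fixed to the in-plane average",
            stacklevel=2,
        )

    # warm start: full-affine least squares, then polar factorization R * P
    # with the symmetric factor's diagonal as the anisotropic scale estimate
    X = np.hstack([P, np.ones((len(P), 1))])
    sol, *_ = np.linalg.lstsq(X, Q, rcond=None)
    A0, t0 = sol[:3].T, sol[3]
    U, s, Vt = np.linalg.svd(A0)
    R0 = U @ Vt
    if np.linalg.det(R0) < 0:
        U[:, -1] *= -1
        s = s.copy()
        R0 = U @ Vt
    S0 = Vt.T @ np.diag(s) @ Vt  # symmetric factor of the polar decomposition
    scale0 = np.clip(np.diag(S0), 1e-3, None)
    x0 = np.concatenate([t0, Rotation.from_matrix(R0).as_rotvec(), np.log(scale0)])

    def mean_dist(params: np.ndarray) -> float:
        T = _params_to_affine(params)
        return float(np.mean(np.linalg.norm(T.apply(P) - Q, axis=1)))

    res = minimize(mean_dist, x0, method="Powell", options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
    best = res.x if res.fun <= mean_dist(x0) else x0
    transform = _params_to_affine(best)
    return transform, float(mean_dist(best))
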