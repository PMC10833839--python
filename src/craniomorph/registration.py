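"""Four-term cost function and multi-resolution stochastic optimizer.

The registration minimizes

    F(mu) = NC + alpha * SD + beta * D + gamma * P

over the FFD coefficients mu, where NC is the negative normalized
cross-correlation between fixed and warped-moving intensities, SD the
sum-of-squared-differences between the side-label images (enforcing
mid-sagittal symmetry), D the mean Euclidean distance between warped fixed
landmarks and their moving pairs (mm), and P the bending energy of the
transformation. Three resolution levels are used, coarse to fine by a factor
of two for both the images and the control grid; each level runs a decaying-
step stochastic gradient descent on a fresh random subset of the head/neck
mask per iteration. All gradients are analytic (chain rule through the
B-spline weights); the run is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import preprocess
from .ffd import (
    AffineTransform,
    FFDTransform,
    GridSchedule,
    bending_energy,
    build_symmetric_grid,
    cubic_bspline_weights,
    cubic_bspline_weights_d1,
    cubic_bspline_weights_d2,
)
from .volumes import (
    LandmarkSet,
    MaskVolume,
    SideLabelImage,
    VolumeImage,
    mirror,
    resample,
    trilinear_sample,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CostWeights",
    "RegistrationConfig",
    "RegistrationResult",
    "nc_term",
    "sd_term",
    "landmark_term",
    "total_cost",
    "register",
    "asymmetry_score",
]

_AIR = -1000.0
_OFFSETS = np.array(list(product(range(4), repeat=3)), dtype=int)


@dataclass
class CostWeights:
    """Per-level weights of the four cost terms.

    alpha weights the symmetry (SD) term and defaults to 1: mid-sagittal
    alignment is treated as important as intensity alignment. beta weights the
    landmark distance term per level, (0, 0.05, 0.1) coarse to fine. gamma
    weights the bending-energy penalty per level and is derived from the
    finest-level weight lambda2 as (0, lambda2/2, lambda2). Weights are not
    normalized across terms.
    """

    alpha: float = 1.0
    beta: tuple[float, ...] = (0.0, 0.05, 0.1)
    gamma: tuple[float, ...] = (0.0, 0.0, 0.0)

    @classmethod
    def from_lambda2(
        cls,
        lambda2: float,
        alpha: float = 1.0,
        beta: tuple[float, ...] = (0.0, 0.05, 0.1),
    ) -> "CostWeights":
        return cls(alpha=alpha, beta=beta, gamma=(0.0, lambda2 / 2.0, lambda2))


@dataclass
class RegistrationConfig:
    """Everything that parameterizes one registration run.

    ``grid_spacing`` is the finest FFD control spacing lambda1 (mm);
    ``weights.gamma`` carries the penalty schedule derived from lambda2.
    ``samples_per_iter`` points are drawn from the head/neck mask at every
    iteration; if the mask is smaller, sampling falls back to replacement
    with a warning. Fixing ``rng_seed`` makes the run bit-reproducible.
    """

    grid_spacing: float = 20.0
    weights: CostWeights = field(default_factory=CostWeights)
    samples_per_iter: int = 20000
    bending_samples: int = 1000
    iterations: tuple[int, ...] = (2000, 2000, 2000)
    rng_seed: int = 0
    initial_step_mm: float = 1.0
    asgd_A: float = 20.0
    asgd_alpha: float = 0.602
    levels: int = 3

    @property
    def schedule(self) -> GridSchedule:
        return GridSchedule(finest_spacing=self.grid_spacing, levels=self.levels)


@dataclass
class RegistrationResult:
    """Final transform plus per-level cost traces and final term values."""

    transform: FFDTransform
    cost_traces: list[np.ndarray]
    final_terms: dict[str, float]
    config: RegistrationConfig


class RegistrationDivergence(RuntimeError):
    """Raised when the cost becomes non-finite; carries the traces so far."""

    def __init__(self, message: str, traces: list[np.ndarray]):
        super().__init__(message)
        self.traces = traces


# ---------------------------------------------------------------------------
# Cost terms (reference implementations on explicit sample points)
# ---------------------------------------------------------------------------


def nc_term(
    transform,
    fixed: VolumeImage,
    moving: VolumeImage,
    sample_points: np.ndarray,
) -> float:
    """Negative Pearson correlation between fixed and warped-moving intensities.

    Lower is better: minimizing this maximizes the normalized
    cross-correlation. Affine intensity changes of either image leave the
    value unchanged. Zero variance in either sample vector is uninformative
    and maps to 0.
    """
    pts = np.atleast_2d(sample_points)
    f = trilinear_sample(fixed, pts, fill=_AIR)
    m = trilinear_sample(moving, _apply(transform, pts), fill=_AIR)
    if _zero_variance(f) or _zero_variance(m):
        logger.warning("NC term: zero intensity variance in a sample vector; returning 0")
        return 0.0
    fc, mc = f - f.mean(), m - m.mean()
    return float(-(fc @ mc) / np.sqrt(float(fc @ fc) * float(mc @ mc)))


def _zero_variance(v: np.ndarray) -> bool:
    """Constant up to interpolation round-off: an uninformative sample vector."""
    return bool(np.ptp(v) <= 1e-9 * (1.0 + abs(float(np.mean(v)))))


def sd_term(
    transform,
    fixed_side: SideLabelImage,
    moving_side: SideLabelImage,
    sample_points: np.ndarray,
) -> float:
    """Mean squared side-label difference: penalizes crossing the mid-sagittal plane."""
    pts = np.atleast_2d(sample_points)
    s_h = trilinear_sample(fixed_side, pts, fill=0.0)
    s_b = trilinear_sample(moving_side, _apply(transform, pts), fill=0.0)
    return float(np.mean((s_h - s_b) ** 2))


def landmark_term(transform, fixed_lm: LandmarkSet, moving_lm: LandmarkSet) -> float:
    """Mean Euclidean distance (mm) between warped fixed landmarks and moving pairs."""
    fixed_lm.paired_with(moving_lm)
    mapped = _apply(transform, fixed_lm.points)
    return float(np.mean(np.linalg.norm(mapped - moving_lm.points, axis=1)))


def total_cost(
    transform: FFDTransform,
    fixed: VolumeImage,
    moving: VolumeImage,
    fixed_side: SideLabelImage,
    moving_side: SideLabelImage,
    fixed_lm: LandmarkSet,
    moving_lm: LandmarkSet,
    alpha: float,
    beta: float,
    gamma: float,
    sample_points: np.ndarray,
    domain: MaskVolume,
) -> float:
    """F = NC + alpha SD + beta D + gamma P with P the exact mask-mean bending energy."""
    return (
        nc_term(transform, fixed, moving, sample_points)
        + alpha * sd_term(transform, fixed_side, moving_side, sample_points)
        + beta * landmark_term(transform, fixed_lm, moving_lm)
        + gamma * bending_energy(transform, domain)
    )


def _apply(transform, points: np.ndarray) -> np.ndarray:
    if callable(getattr(transform, "apply", None)):
        return transform.apply(points)
    return transform(points)


def asymmetry_score(volume: VolumeImage, plane_axis: int = 0) -> float:
    """Mean absolute difference between a volume and its mirror image."""
    return float(np.mean(np.abs(volume.data - mirror(volume, plane_axis).data)))


# ---------------------------------------------------------------------------
# Image pyramid
# ---------------------------------------------------------------------------


def _downsample(volume: VolumeImage, factor: int, smooth: bool = True) -> VolumeImage:
    """Gaussian-smooth (sigma = factor/2 voxels) and subsample by ``factor``."""
    if factor == 1:
        return volume
    data = volume.data.astype(float)
    if smooth:
        data = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    return VolumeImage(data=data, spacing=volume.spacing * factor, origin=volume.origin.copy())


def _downsample_mask(mask: MaskVolume, factor: int) -> MaskVolume:
    if factor == 1:
        return mask
    data = mask.data[::factor, ::factor, ::factor]
    return MaskVolume(data=data, spacing=mask.spacing * factor, origin=mask.origin.copy())


def _downsample_side(side: SideLabelImage, factor: int) -> VolumeImage:
    """Side labels go through the same smoothing pyramid as the intensities.

    The smoothed labels take values in [0, 1] near the plane, which widens the
    capture range of the symmetry term at coarse levels.
    """
    if factor == 1:
        return side
    data = ndimage.gaussian_filter(side.data.astype(float), sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    return VolumeImage(data=data, spacing=side.spacing * factor, origin=side.origin.copy())


# ---------------------------------------------------------------------------
# Fused evaluation of cost and analytic coefficient gradient
# ---------------------------------------------------------------------------


class _LevelData:
    """Precomputed per-level arrays: sample pool and moving-image channels."""

    def __init__(
        self,
        fixed: VolumeImage,
        moving: VolumeImage,
        fixed_side: SideLabelImage,
        moving_side: SideLabelImage,
        mask: MaskVolume,
    ):
        idx = np.argwhere(mask.data)
        self.pool = mask.origin + idx * mask.spacing
        self.fixed_vals = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        self.fixed_side_vals = fixed_side.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        gm = np.gradient(moving.data.astype(float), *moving.spacing)
        gs = np.gradient(moving_side.data.astype(float), *moving_side.spacing)
        self.channels = np.stack(
            [moving.data.astype(float), *gm, moving_side.data.astype(float), *gs]
        )
        self.fill = np.array([_AIR, 0, 0, 0, 0.0, 0, 0, 0])
        self.moving_origin = moving.origin
        self.moving_spacing = moving.spacing
        self.moving_shape = np.array(moving.shape)

    def sample_moving(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear sample of all channels at world points; (n, 8)."""
        idx = (pts - self.moving_origin) / self.moving_spacing
        inside = np.all((idx >= 0) & (idx <= self.moving_shape - 1), axis=1)
        base = np.clip(np.floor(idx).astype(int), 0, self.moving_shape - 2)
        frac = idx - base
        out = np.empty((len(pts), self.channels.shape[0]))
        acc = np.zeros((len(pts), self.channels.shape[0]))
        for dx in (0, 1):
            wx = frac[:, 0] if dx else 1 - frac[:, 0]
            for dy in (0, 1):
                wy = frac[:, 1] if dy else 1 - frac[:, 1]
                for dz in (0, 1):
                    wz = frac[:, 2] if dz else 1 - frac[:, 2]
                    vals = self.channels[:, base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
                    acc += (wx * wy * wz)[:, None] * vals.T
        out[:] = self.fill
        out[inside] = acc[inside]
        return out


def _scatter_gradient(
    transform: FFDTransform,
    base: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray, np.ndarray],
    point_grads: np.ndarray,
) -> np.ndarray:
    """Accumulate d(loss)/d(coefficients) from per-point gradients d(loss)/dT(x)."""
    nx, ny, nz = transform.control_shape
    wx, wy, wz = weights
    base_flat = (base[:, 0] * ny + base[:, 1]) * nz + base[:, 2]
    n = len(base_flat)
    idx_all = np.empty(64 * n, dtype=np.int64)
    val_all = np.empty((64 * n, 3))
    for k, (a, b, d) in enumerate(_OFFSETS):
        delta = (a * ny + b) * nz + d
        w = wx[:, a] * wy[:, b] * wz[:, d]
        idx_all[k * n : (k + 1) * n] = base_flat + delta
        val_all[k * n : (k + 1) * n] = w[:, None] * point_grads
    size = nx * ny * nz
    g = np.stack(
        [np.bincount(idx_all, weights=val_all[:, c], minlength=size) for c in range(3)],
        axis=1,
    )
    return g.reshape(nx, ny, nz, 3)


def _bending_value_and_gradient(
    transform: FFDTransform, pts: np.ndarray
) -> tuple[float, np.ndarray]:
    """Sampled bending energy and its analytic coefficient gradient."""
    base, u = transform.locate(pts)
    h = transform.control_spacing
    w0 = [cubic_bspline_weights(u[:, ax]) for ax in range(3)]
    w1 = [cubic_bspline_weights_d1(u[:, ax]) / h[ax] for ax in range(3)]
    w2 = [cubic_bspline_weights_d2(u[:, ax]) / h[ax] ** 2 for ax in range(3)]
    n = len(base)
    combos = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    mult = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])  # off-diagonals appear twice in ||.||_F^2

    def fac(a: int, b: int, d: int, combo: tuple[int, int]) -> np.ndarray:
        sel = [w0[0][:, a], w0[1][:, b], w0[2][:, d]]
        p, q = combo
        if p == q:
            sel[p] = [w2[0][:, a], w2[1][:, b], w2[2][:, d]][p]
        else:
            sel[p] = [w1[0][:, a], w1[1][:, b], w1[2][:, d]][p]
            sel[q] = [w1[0][:, a], w1[1][:, b], w1[2][:, d]][q]
        return sel[0] * sel[1] * sel[2]

    c = transform.coefficients
    H = np.zeros((n, 3, 6))  # H[:, comp, combo]
    facs = np.empty((64, 6, n))
    for k, (a, b, d) in enumerate(_OFFSETS):
        coef = c[base[:, 0] + a, base[:, 1] + b, base[:, 2] + d]  # (n, 3)
        for ci, combo in enumerate(combos):
            f = fac(a, b, d, combo)
            facs[k, ci] = f
            H[:, :, ci] += f[:, None] * coef
    value = float(np.sum((H * H) * mult[None, None, :]) / n)

    nx, ny, nz = transform.control_shape
    base_flat = (base[:, 0] * ny + base[:, 1]) * nz + base[:, 2]
    idx_all = np.empty(64 * n, dtype=np.int64)
    val_all = np.empty((64 * n, 3))
    Hw = H * (2.0 * mult / n)[None, None, :]  # d||H||^2 contributions
    for k, (a, b, d) in enumerate(_OFFSETS):
        delta = (a * ny + b) * nz + d
        v = np.einsum("ncj,jn->nc", Hw, facs[k])
        idx_all[k * n : (k + 1) * n] = base_flat + delta
        val_all[k * n : (k + 1) * n] = v
    size = nx * ny * nz
    g = np.stack(
        [np.bincount(idx_all, weights=val_all[:, comp], minlength=size) for comp in range(3)],
        axis=1,
    ).reshape(nx, ny, nz, 3)
    return value, g


def _iteration(
    transform: FFDTransform,
    data: _LevelData,
    fixed_lm: LandmarkSet,
    moving_lm: LandmarkSet,
    alpha: float,
    beta: float,
    gamma: float,
    sample_idx: np.ndarray,
    n_bend: int,
) -> tuple[float, np.ndarray, dict[str, float]]:
    """One stochastic evaluation of F and its analytic coefficient gradient."""
    x = data.pool[sample_idx]
    f = data.fixed_vals[sample_idx]
    s_h = data.fixed_side_vals[sample_idx]
    n = len(x)

    base, u = transform.locate(x)
    wx = cubic_bspline_weights(u[:, 0])
    wy = cubic_bspline_weights(u[:, 1])
    wz = cubic_bspline_weights(u[:, 2])
    disp = np.zeros((n, 3))
    c = transform.coefficients
    for a, b, d in _OFFSETS:
        w = wx[:, a] * wy[:, b] * wz[:, d]
        disp += w[:, None] * c[base[:, 0] + a, base[:, 1] + b, base[:, 2] + d]
    mapped = transform.pre_affine.apply(x) + disp

    ch = data.sample_moving(mapped)
    m, m_grad = ch[:, 0], ch[:, 1:4]
    s_b, s_grad = ch[:, 4], ch[:, 5:8]

    # NC: negative Pearson correlation
    fc = f - f.mean()
    mc = m - m.mean()
    sff, smm, sfm = float(fc @ fc), float(mc @ mc), float(fc @ mc)
    if _zero_variance(f) or _zero_variance(m):
        nc = 0.0
        d_nc_dm = np.zeros(n)
    else:
        denom = np.sqrt(sff * smm)
        r = sfm / denom
        nc = -r
        d_nc_dm = -(fc - (sfm / smm) * mc) / denom

    # SD: mean squared label difference
    sd_val = float(np.mean((s_h - s_b) ** 2))
    d_sd_ds = 2.0 * (s_b - s_h) / n

    point_grads = d_nc_dm[:, None] * m_grad + alpha * d_sd_ds[:, None] * s_grad
    grad = _scatter_gradient(transform, base, (wx, wy, wz), point_grads)

    # D: landmarks (cheap; every iteration)
    d_val = 0.0
    if beta != 0.0:
        lm_base, lm_u = transform.locate(fixed_lm.points)
        lwx = cubic_bspline_weights(lm_u[:, 0])
        lwy = cubic_bspline_weights(lm_u[:, 1])
        lwz = cubic_bspline_weights(lm_u[:, 2])
        lm_disp = np.zeros((len(fixed_lm), 3))
        for a, b, d in _OFFSETS:
            w = lwx[:, a] * lwy[:, b] * lwz[:, d]
            lm_disp += w[:, None] * c[lm_base[:, 0] + a, lm_base[:, 1] + b, lm_base[:, 2] + d]
        lm_mapped = transform.pre_affine.apply(fixed_lm.points) + lm_disp
        diff = lm_mapped - moving_lm.points
        dist = np.linalg.norm(diff, axis=1)
        d_val = float(dist.mean())
        lm_grads = diff / (np.maximum(dist, 1e-12)[:, None] * len(fixed_lm))
        grad += beta * _scatter_gradient(transform, lm_base, (lwx, lwy, lwz), lm_grads)
    else:
        d_val = landmark_term(transform, fixed_lm, moving_lm)

    # P: sampled bending energy
    p_val = 0.0
    if gamma != 0.0:
        bend_pts = x[: min(n_bend, n)]
        p_val, p_grad = _bending_value_and_gradient(transform, bend_pts)
        grad += gamma * p_grad

    cost = nc + alpha * sd_val + beta * d_val + gamma * p_val
    terms = {"NC": nc, "SD": sd_val, "D": d_val, "P": p_val}
    return cost, grad, terms


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def register(
    fixed: VolumeImage,
    moving: VolumeImage,
    fixed_side: SideLabelImage,
    moving_side: SideLabelImage,
    fixed_lm: LandmarkSet,
    moving_lm: LandmarkSet,
    config: RegistrationConfig | None = None,
    mask: MaskVolume | None = None,
    pre_affine: AffineTransform | None = None,
) -> RegistrationResult:
    """Multi-resolution symmetric FFD registration of a preprocessed pair.

    Inputs are assumed plane-aligned, symmetrized and affine-initialized (or
    ``pre_affine`` carries the landmark-fitted affine map). ``mask`` is the
    head/neck sampling region of the fixed image; it is segmented with the
    default preprocessing configuration if not supplied.
    """
    config = config or RegistrationConfig()
    fixed_lm.paired_with(moving_lm)
    if mask is None:
        mask = preprocess.segment_head_neck(fixed)
    rng = np.random.default_rng(config.rng_seed)
    schedule = config.schedule

    transform: Optional[FFDTransform] = None
    traces: list[np.ndarray] = []
    warned_replacement = False

    for level in range(config.levels):
        factor = schedule.image_factor_at(level)
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)
        sh_l = _downsample_side(fixed_side, factor)
        sb_l = _downsample_side(moving_side, factor)
        mask_l = _downsample_mask(mask, factor)
        data = _LevelData(f_l, m_l, sh_l, sb_l, mask_l)

        if transform is None:
            transform = build_symmetric_grid(
                fixed,
                schedule.spacing_at(0),
                plane_axis=0,
                pre_affine=pre_affine,
            )
        else:
            transform = transform.subdivide()

        alpha = config.weights.alpha
        beta = config.weights.beta[min(level, len(config.weights.beta) - 1)]
        gamma = config.weights.gamma[min(level, len(config.weights.gamma) - 1)]

        n_pool = len(data.pool)
        n_samp = config.samples_per_iter
        replace = n_samp > n_pool
        if replace and not warned_replacement:
            logger.warning(
                "head/neck mask (%d voxels) smaller than samples_per_iter (%d); "
                "sampling with replacement",
                n_pool,
                n_samp,
            )
            warned_replacement = True

        n_iter = config.iterations[min(level, len(config.iterations) - 1)]
        trace = np.empty(n_iter)
        step_a = None
        for t in range(n_iter):
            idx = rng.choice(n_pool, size=min(n_samp, n_pool) if not replace else n_samp, replace=replace)
            cost, grad, _ = _iteration(
                transform, data, fixed_lm, moving_lm, alpha, beta, gamma, idx,
                config.bending_samples,
            )
            if not np.isfinite(cost):
                traces.append(trace[:t])
                raise RegistrationDivergence(
                    f"cost became non-finite at level {level}, iteration {t}", traces
                )
            trace[t] = cost
            if step_a is None:
                gmax = float(np.abs(grad).max())
                step_a = config.initial_step_mm * (config.asgd_A + 1.0) ** config.asgd_alpha / max(
                    gmax, 1e-12
                )
            gamma_t = step_a / (config.asgd_A + t) ** config.asgd_alpha
            transform.coefficients -= gamma_t * grad
        traces.append(trace)

    # final term values on a deterministic sample of the full-resolution mask
    data = _LevelData(fixed, moving, fixed_side, moving_side, mask)
    n_eval = min(config.samples_per_iter, len(data.pool))
    eval_idx = np.random.default_rng(config.rng_seed + 1).choice(
        len(data.pool), size=n_eval, replace=False
    )
    _, _, terms = _iteration(
        transform, data, fixed_lm, moving_lm, config.weights.alpha,
        config.weights.beta[-1], config.weights.gamma[-1], eval_idx,
        config.bending_samples,
    )
    terms["P"] = bending_energy(transform, mask)
    return RegistrationResult(
        transform=transform, cost_traces=traces, final_terms=terms, config=config
    )
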