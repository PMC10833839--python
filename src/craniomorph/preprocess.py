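"""Registration input construction.

Builds the four inputs the registration consumes from a raw CT-like volume:
a plane-aligned, mirror-symmetrized intensity volume; a side-label image
(which side of the mid-sagittal plane each voxel lies on); a head/neck region
mask restricting cost-function sampling; and a bone-only volume in which all
soft tissue is replaced by air, emulating fossil data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .ffd import AffineTransform
from .volumes import (
    MaskVolume,
    SideLabelImage,
    VolumeImage,
    central_plane_coord,
    mirror,
    resample,
)

__all__ = [
    "PlaneSpec",
    "PreprocessConfig",
    "align_to_plane",
    "symmetrize",
    "segment_head_neck",
    "bone_only",
]

_AIR_HU = -1000.0


@dataclass
class PlaneSpec:
    """A plane defined by three non-collinear points (mm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(3, 3)
        n = np.cross(self.points[1] - self.points[0], self.points[2] - self.points[0])
        norm = np.linalg.norm(n)
        if norm < 1e-9:
            raise ValueError("plane points are collinear (degenerate plane)")
        self._normal = n / norm

    @property
    def normal(self) -> np.ndarray:
        """Unit normal vector of the plane."""
        return self._normal

    @property
    def point(self) -> np.ndarray:
        return self.points[0]


@dataclass
class PreprocessConfig:
    """Thresholds and morphology radii for segmentation and bone extraction.

    air_threshold (HU) sits slightly above air (-1000); bone_threshold (HU)
    separates soft tissue (< ~100 HU) from cancellous/cortical bone. Radii are
    in voxels (Euclidean-ball structuring elements).
    """

    air_threshold: float = -900.0
    bone_threshold: float = 200.0
    closing_radius: int = 3
    dilation_radius: int = 1
    hyoid_mask: Optional[MaskVolume] = None

    def __post_init__(self) -> None:
        if self.air_threshold <= _AIR_HU:
            raise ValueError("air_threshold must be above -1000 HU")
        if self.bone_threshold <= self.air_threshold:
            raise ValueError("bone_threshold must exceed air_threshold")
        if self.closing_radius < 0 or self.dilation_radius < 0:
            raise ValueError("morphology radii must be >= 0")


# ---------------------------------------------------------------------------
# Plane alignment
# ---------------------------------------------------------------------------


def _rotation_to_axis(normal: np.ndarray, axis: int) -> np.ndarray:
    """Minimal rotation matrix R with R @ normal = e_axis."""
    e = np.zeros(3)
    e[axis] = 1.0
    n = normal / np.linalg.norm(normal)
    if np.dot(n, e) < 0:  # choose the normal orientation closest to +e
        n = -n
    v = np.cross(n, e)
    s = np.linalg.norm(v)
    c = float(np.dot(n, e))
    if s < 1e-15:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_to_plane(
    volume: VolumeImage,
    plane: PlaneSpec,
    plane_axis: int = 0,
    fill: float = _AIR_HU,
) -> tuple[VolumeImage, AffineTransform]:
    """Rigidly resample a volume so the given plane becomes the central voxel
    plane along ``plane_axis`` and the volume center sits at the world origin.

    Returns the aligned volume together with the rigid map (old world -> new
    world) so landmarks can be carried through the same transform. The output
    grid keeps the input shape and spacing, with its origin centered on the
    world origin; the plane's offset along its own normal translates the
    output accordingly.
    """
    if abs(np.dot(plane.normal, plane.normal)) < 1e-12:
        raise ValueError("degenerate plane")
    R = _rotation_to_axis(plane.normal, plane_axis)
    lo, hi = volume.world_bounds()
    center = 0.5 * (lo + hi)
    # project the volume center onto the plane: rigid pivot point
    n = plane.normal
    pivot = center - n * float(np.dot(center - plane.point, n))
    rigid = AffineTransform(matrix=R, translation=-R @ pivot)

    shape = np.array(volume.shape)
    new_origin = -(shape - 1) / 2.0 * volume.spacing
    reference = VolumeImage(
        data=np.zeros(volume.shape), spacing=volume.spacing.copy(), origin=new_origin
    )
    inv = rigid.inverse()
    aligned = resample(volume, inv.apply, reference, fill=fill)
    return aligned, rigid


# ---------------------------------------------------------------------------
# Symmetrization
# ---------------------------------------------------------------------------


def symmetrize(
    volume: VolumeImage, plane_axis: int = 0, keep: str = "upper"
) -> tuple[VolumeImage, SideLabelImage]:
    """Mirror one half of a plane-aligned volume onto the other.

    ``keep`` names the half that is copied: "upper" (larger world coordinate
    along ``plane_axis``; conventionally called "right") or "lower". For an
    even-length axis the reflection plane lies between the two central layers;
    for an odd length the central voxel layer lies on the plane and is shared.

    Returns the exactly mirror-symmetric volume and the side-label image
    (1 on the kept side, 0 on the mirrored side; plane voxels labelled 1).
    """
    if keep not in ("upper", "lower"):
        raise ValueError("keep must be 'upper' or 'lower'")
    n = volume.shape[plane_axis]
    data = volume.data.copy()
    flipped = np.flip(volume.data, axis=plane_axis)
    idx = np.arange(n)
    # voxel layers strictly on the replaced side
    if keep == "upper":
        replace = idx < (n - 1) / 2.0
    else:
        replace = idx > (n - 1) / 2.0
    sel = [slice(None)] * 3
    sel[plane_axis] = replace
    data[tuple(sel)] = flipped[tuple(sel)]
    sym = volume.copy_with(data)

    if keep == "upper":
        side = (idx >= (n - 1) / 2.0).astype(float)
    else:
        side = (idx <= (n - 1) / 2.0).astype(float)
    shape = [1, 1, 1]
    shape[plane_axis] = n
    labels = np.broadcast_to(side.reshape(shape), volume.shape).copy()
    side_img = SideLabelImage(
        data=labels, spacing=volume.spacing.copy(), origin=volume.origin.copy()
    )
    return sym, side_img


# ---------------------------------------------------------------------------
# Head/neck segmentation
# ---------------------------------------------------------------------------


def ball_footprint(radius: int) -> np.ndarray:
    """Euclidean-ball structuring element of the given voxel radius."""
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


def _closing_padded(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary closing with padding so the image border does not clip dilation."""
    r = footprint.shape[0] // 2
    if r == 0:
        return mask
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=footprint), structure=footprint
    )
    return closed[r:-r, r:-r, r:-r]


def segment_head_neck(volume: VolumeImage, cfg: PreprocessConfig | None = None) -> MaskVolume:
    """Segment the head/neck region: threshold above air, close, dilate.

    Internal air cavities (oral/nasal) smaller than the closing scale are
    filled so that sampling covers air-tissue interfaces inside the head; the
    mask only gates cost-function sampling, the intensity volume is untouched.
    Raises if the mask comes out empty (nothing to register).
    """
    cfg = cfg or PreprocessConfig()
    mask = volume.data > cfg.air_threshold
    if not mask.any():
        raise ValueError("head/neck segmentation is empty (volume is all air)")
    if cfg.closing_radius > 0:
        mask = _closing_padded(mask, ball_footprint(cfg.closing_radius))
    if cfg.dilation_radius > 0:
        mask = ndimage.binary_dilation(mask, structure=ball_footprint(cfg.dilation_radius))
    return MaskVolume(data=mask, spacing=volume.spacing.copy(), origin=volume.origin.copy())


# ---------------------------------------------------------------------------
# Bone-only images
# ---------------------------------------------------------------------------


def bone_only(volume: VolumeImage, cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Replace soft tissue (and optionally the hyoid bone) with air.

    Voxels below ``bone_threshold`` are set to -1000 HU; voxels inside the
    optional hyoid mask are removed as well (the hyoid does not fossilize).
    Idempotent.
    """
    cfg = cfg or PreprocessConfig()
    data = volume.data.astype(float).copy()
    data[data < cfg.bone_threshold] = _AIR_HU
    if cfg.hyoid_mask is not None:
        if cfg.hyoid_mask.shape != volume.shape:
            raise ValueError("hyoid mask grid does not match the volume")
        data[cfg.hyoid_mask.data] = _AIR_HU
    return volume.copy_with(data)
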