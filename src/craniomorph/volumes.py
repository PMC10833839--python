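"""Volumetric data model, I/O and resampling primitives.

All images are axis-aligned scalar grids with Hounsfield-unit semantics.
The world coordinate of voxel index ``i`` (0-based) is ``origin + i * spacing``
in millimetres; no orientation matrix is carried because the pipeline operates
on plane-aligned, symmetrized volumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "MaskVolume",
    "SideLabelImage",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "resample",
    "mirror",
    "trilinear_sample",
]

_AIR_HU = -1000.0


@dataclass
class VolumeImage:
    """3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities (HU). Index order is (x, y, z).
    spacing : array-like of 3 floats
        Voxel size in mm along each axis; strictly positive.
    origin : array-like of 3 floats
        World coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        grids = np.meshgrid(
            *[self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)],
            indexing="ij",
        )
        return np.stack(grids, axis=-1)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return lo, hi

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return type(self)(data=data, spacing=self.spacing.copy(), origin=self.origin.copy())


class MaskVolume(VolumeImage):
    """Boolean region-of-interest volume on the same grid as its parent image."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        super().__post_init__()

    @property
    def count(self) -> int:
        """Number of voxels in the region (|Omega|)."""
        return int(self.data.sum())

    def world_points(self) -> np.ndarray:
        """World coordinates of all true voxels, shape (count, 3)."""
        idx = np.argwhere(self.data)
        return self.origin + idx * self.spacing


class SideLabelImage(VolumeImage):
    """Binary image labelling each voxel by its side of the mid-sagittal plane.

    Exactly two label values (0 and 1); the label boundary is the mid-sagittal
    voxel plane.
    """

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("side labels must be encoded 0/1")


@dataclass
class LandmarkSet:
    """Ordered, identified anatomical landmarks (id, name, point in mm)."""

    ids: np.ndarray
    names: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int).reshape(-1)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("landmark ids must be unique")
        if len(self.names) != len(self.ids) or len(self.points) != len(self.ids):
            raise ValueError("ids, names and points must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[int]) -> "LandmarkSet":
        order = {int(i): k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if int(i) not in order]
        if missing:
            raise KeyError(f"landmark ids not present: {missing}")
        sel = [order[int(i)] for i in ids]
        return LandmarkSet(
            ids=self.ids[sel], names=[self.names[k] for k in sel], points=self.points[sel]
        )

    def paired_with(self, other: "LandmarkSet") -> None:
        """Raise if the two sets are not identically ordered pairings."""
        if len(self) != len(other) or not np.array_equal(self.ids, other.ids):
            raise ValueError("landmark sets are not paired (id order differs)")

    def transformed(self, point_map: Callable[[np.ndarray], np.ndarray]) -> "LandmarkSet":
        return LandmarkSet(ids=self.ids.copy(), names=list(self.names), points=point_map(self.points))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {
    ".nii": "nifti",
    ".gz": "nifti",  # .nii.gz
    ".mha": "metaimage",
    ".mhd": "metaimage",
}


def _check_path_format(path: str | Path) -> None:
    suffixes = Path(path).suffixes
    if not suffixes or suffixes[-1].lower() not in _FORMATS:
        raise ValueError(
            f"unsupported volume format for {path!s}; use .nii, .nii.gz, .mha or .mhd"
        )


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Grid metadata (spacing, origin) is preserved exactly and intensities are
    returned unchanged. Raises on unreadable files and non-3D payloads.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_path_format(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - sitk error text varies
        raise ValueError(f"could not parse {path} as a volume: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D volume, got {img.GetDimension()}D payload")
    # sitk arrays are indexed (z, y, x); transpose to our (x, y, z) convention.
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeImage(data=data, spacing=np.array(img.GetSpacing()), origin=np.array(img.GetOrigin()))


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume in NIfTI or MetaImage format (chosen by extension)."""
    _check_path_format(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from CSV with header ``id,name,x,y,z`` (mm units)."""
    ids, names, pts = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "name", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"landmark CSV must have header id,name,x,y,z, got {reader.fieldnames}")
        for row in reader:
            ids.append(int(row["id"]))
            names.append(row["name"])
            pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
    return LandmarkSet(ids=np.array(ids), names=names, points=np.array(pts))


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "x", "y", "z"])
        for i, name, p in zip(landmarks.ids, landmarks.names, landmarks.points):
            writer.writerow([int(i), name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])


# ---------------------------------------------------------------------------
# Sampling / resampling / mirroring
# ---------------------------------------------------------------------------


def trilinear_sample(
    volume: VolumeImage, points: np.ndarray, fill: float = _AIR_HU
) -> np.ndarray:
    """Trilinear interpolation of ``volume`` at world-mm ``points`` (n, 3).

    Points outside the volume's world bounds get ``fill``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = volume.world_to_index(pts)
    shape = np.array(volume.shape)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1), axis=1)
    out = np.full(len(pts), float(fill))
    if np.any(inside):
        out[inside] = _trilinear_at_indices(volume.data, idx[inside])
    return out


def _trilinear_at_indices(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional voxel indices known to be in-bounds."""
    shape = np.array(data.shape)
    base = np.floor(idx).astype(int)
    base = np.minimum(base, shape - 2)  # allow exact upper boundary
    base = np.maximum(base, 0)
    frac = idx - base
    out = np.zeros(len(idx), dtype=float)
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                vals = data[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
                out += wx * wy * wz * vals
    return out


def nearest_sample(volume: VolumeImage, points: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Nearest-neighbour interpolation (used for masks/labels)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = volume.world_to_index(pts)
    shape = np.array(volume.shape)
    inside = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1)
    out = np.full(len(pts), float(fill))
    nearest = np.clip(np.rint(idx).astype(int), 0, shape - 1)
    vals = volume.data[nearest[:, 0], nearest[:, 1], nearest[:, 2]].astype(float)
    out[inside] = vals[inside]
    return out


def resample(
    moving: VolumeImage,
    transform: Callable[[np.ndarray], np.ndarray],
    reference_grid: VolumeImage,
    fill: float = _AIR_HU,
    order: str = "linear",
) -> VolumeImage:
    """Resample ``moving`` onto ``reference_grid`` through a point map x -> T(x).

    The output value at reference voxel center x is the interpolated value of
    ``moving`` at T(x); points mapping outside the moving bounds get ``fill``.
    ``order`` is "linear" (intensities) or "nearest" (masks/labels).
    """
    centers = reference_grid.voxel_centers().reshape(-1, 3)
    mapped = transform(centers)
    if order == "nearest":
        vals = nearest_sample(moving, mapped, fill=fill)
    elif order == "linear":
        vals = trilinear_sample(moving, mapped, fill=fill)
    else:
        raise ValueError(f"unknown interpolation order {order!r}")
    data = vals.reshape(reference_grid.shape)
    out = VolumeImage(data=data, spacing=reference_grid.spacing.copy(), origin=reference_grid.origin.copy())
    if isinstance(moving, MaskVolume):
        return MaskVolume(data=data > 0.5, spacing=out.spacing, origin=out.origin)
    return out


def mirror(volume: VolumeImage, plane_axis: int = 0) -> VolumeImage:
    """Reflect a volume about its central voxel plane along ``plane_axis``.

    For an odd-length axis the central voxel layer is fixed; for an even-length
    axis the reflection plane lies between the two central layers (no voxel
    lies on the plane). ``mirror(mirror(v)) == v`` in both cases.
    """
    if plane_axis not in (0, 1, 2):
        raise ValueError("plane_axis must be 0, 1 or 2")
    data = np.flip(volume.data, axis=plane_axis).copy()
    return volume.copy_with(data)


def mirror_point(points: np.ndarray, plane_coord: float, plane_axis: int = 0) -> np.ndarray:
    """Reflect world points about the plane {x_axis = plane_coord}."""
    pts = np.array(points, dtype=float, copy=True)
    pts[..., plane_axis] = 2.0 * plane_coord - pts[..., plane_axis]
    return pts


def central_plane_coord(volume: VolumeImage, plane_axis: int = 0) -> float:
    """World coordinate of the central voxel plane along ``plane_axis``."""
    n = volume.shape[plane_axis]
    return float(volume.origin[plane_axis] + (n - 1) / 2.0 * volume.spacing[plane_axis])
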