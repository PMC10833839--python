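"""Tetrahedral mesh model, morphing through the FFD, and assessment metrics.

The predicted organ mesh is obtained by pushing every node of the reference
finite-element mesh through the recovered transformation; connectivity is
never altered, preserving the carefully designed internal structure of the
reference mesh. Prediction quality is summarized by an accuracy (mm), a
worst-case Jacobian statistic J10% and the combined selection score
``accuracy * (J10% - 1)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ffd import FFDTransform
from .volumes import MaskVolume

__all__ = [
    "TetMesh",
    "SurfacePointSet",
    "AssessmentReport",
    "warp_mesh",
    "point_to_surface_accuracy",
    "node_to_node_accuracy",
    "j10",
    "score",
    "select_best",
    "read_mesh",
    "write_mesh",
]


@dataclass
class TetMesh:
    """Linear tetrahedral mesh: nodes (N, 3) in mm, tets (M, 4) node indices.

    Optional ``surface`` holds triangles (K, 3); if absent, the boundary faces
    (faces belonging to exactly one tetrahedron) stand in for the surface.
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= len(self.nodes):
            raise ValueError("tetrahedron indices out of range")
        if self.surface is not None:
            self.surface = np.asarray(self.surface, dtype=int).reshape(-1, 3)
            if self.surface.max(initial=-1) >= len(self.nodes):
                raise ValueError("surface triangle indices out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (positive for positive orientation)."""
        a, b, c, d = (self.nodes[self.tets[:, k]] for k in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def oriented(self) -> "TetMesh":
        """Return a copy with all tetrahedra positively oriented."""
        tets = self.tets.copy()
        neg = self.tet_volumes() < 0
        tets[neg] = tets[neg][:, [0, 1, 3, 2]]
        return TetMesh(nodes=self.nodes.copy(), tets=tets, surface=None if self.surface is None else self.surface.copy())

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tetrahedron, shape (K, 3)."""
        faces = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def surface_triangles(self) -> np.ndarray:
        return self.surface if self.surface is not None else self.boundary_faces()

    def surface_node_indices(self) -> np.ndarray:
        """Indices of nodes referenced by the surface triangles, sorted."""
        return np.unique(self.surface_triangles())


@dataclass
class SurfacePointSet:
    """Evaluation points (K, 3) in mm on an organ surface."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface points must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AssessmentReport:
    """Accuracy (mm), Jacobian statistic J10%, selection score and distance stats."""

    accuracy: float
    j10: float
    score: float
    mean_distance: float
    sd_distance: float
    max_distance: float


# ---------------------------------------------------------------------------
# Morphing
# ---------------------------------------------------------------------------


def warp_mesh(mesh: TetMesh, transform: FFDTransform) -> TetMesh:
    """Push every node through the transformation; connectivity is unchanged."""
    try:
        new_nodes = transform.apply(mesh.nodes)
    except ValueError:
        for i, node in enumerate(mesh.nodes):
            try:
                transform.apply(node)
            except ValueError as exc:
                raise ValueError(
                    f"mesh node {i} at {node} lies outside the transform support"
                ) from exc
        raise
    return TetMesh(
        nodes=new_nodes,
        tets=mesh.tets.copy(),
        surface=None if mesh.surface is None else mesh.surface.copy(),
    )


# ---------------------------------------------------------------------------
# Accuracy measures
# ---------------------------------------------------------------------------


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact min distance from each point to each triangle.

    ``points`` (n, 3); ``tri`` (m, 3, 3). Returns (n, m). The closest point is
    either the orthogonal projection (if its barycentric coordinates are
    non-negative) or lies on one of the three edges.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    def seg_dist2(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        d = p1 - p0  # (m, 3)
        pq = points[:, None, :] - p0[None, :, :]  # (n, m, 3)
        t = np.einsum("nmk,mk->nm", pq, d) / np.maximum(
            np.einsum("mk,mk->m", d, d)[None, :], 1e-300
        )
        t = np.clip(t, 0.0, 1.0)
        diff = pq - t[..., None] * d[None, :, :]
        return np.einsum("nmk,nmk->nm", diff, diff)

    d2 = np.minimum(seg_dist2(a, b), np.minimum(seg_dist2(b, c), seg_dist2(c, a)))

    # interior projection where barycentric coordinates are all non-negative
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)  # (m, 3)
    nn = np.einsum("mk,mk->m", n, n)
    ok = nn > 1e-300  # skip degenerate triangles (edge distance already covers)
    ap = points[:, None, :] - a[None, :, :]
    dot = np.einsum("nmk,mk->nm", ap, n)
    proj = ap - (dot / np.maximum(nn, 1e-300))[..., None] * n[None, :, :]
    d00 = np.einsum("mk,mk->m", ab, ab)
    d01 = np.einsum("mk,mk->m", ab, ac)
    d11 = np.einsum("mk,mk->m", ac, ac)
    pd0 = np.einsum("nmk,mk->nm", proj, ab)
    pd1 = np.einsum("nmk,mk->nm", proj, ac)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * pd0 - d01 * pd1) / denom
    w = (d00 * pd1 - d01 * pd0) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & ok[None, :]
    plane_d2 = dot * dot / np.maximum(nn, 1e-300)[None, :]
    d2 = np.where(inside, np.minimum(d2, plane_d2), d2)
    return np.sqrt(np.maximum(d2, 0.0))


def point_to_surface_accuracy(
    points: SurfacePointSet | np.ndarray,
    mesh: TetMesh,
    chunk: int = 256,
    return_distances: bool = False,
):
    """Mean exact point-to-triangle distance from points to the mesh surface.

    This is the soft-tissue accuracy: the average distance between delineated
    organ-surface points and the surface of the predicted FE mesh.
    """
    pts = points.points if isinstance(points, SurfacePointSet) else np.asarray(points, dtype=float)
    tris = mesh.surface_triangles()
    if len(tris) == 0:
        raise ValueError("mesh has no surface triangles")
    tri = mesh.nodes[tris]
    dists = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        dists[start : start + chunk] = _point_triangle_distances(block, tri).min(axis=1)
    if return_distances:
        return float(dists.mean()), dists
    return float(dists.mean())


def node_to_node_accuracy(a: TetMesh, b: TetMesh) -> tuple[float, np.ndarray]:
    """Mean node-to-node distance over surface nodes of two same-topology meshes.

    This is the bone-based accuracy: both meshes derive from the same
    reference mesh, so nodes correspond one-to-one. Returns the mean together
    with the per-surface-node distance field (for color-coded visualization).
    """
    if a.n_nodes != b.n_nodes or a.n_tets != b.n_tets or not np.array_equal(a.tets, b.tets):
        raise ValueError("meshes do not share topology (node/element mismatch)")
    idx = a.surface_node_indices()
    per_node = np.linalg.norm(a.nodes[idx] - b.nodes[idx], axis=1)
    return float(per_node.mean()), per_node


# ---------------------------------------------------------------------------
# Jacobian quality and selection score
# ---------------------------------------------------------------------------


def j10(transform: FFDTransform, organ_mask: MaskVolume, fraction: float = 0.10) -> float:
    """Average of the lowest 10% Jacobian determinants inside the organ.

    Evaluated at the organ's voxel centers in the reference frame; the count
    of retained values is ``ceil(fraction * n)``.
    """
    if organ_mask.count == 0:
        raise ValueError("organ mask is empty")
    pts = organ_mask.world_points()
    J = transform.jacobian_det(pts)
    k = int(np.ceil(fraction * len(J)))
    return float(np.sort(J)[:k].mean())


def score(accuracy: float, j10_value: float) -> float:
    """Selection score: accuracy * (J10% - 1)^2; lower is better.

    J10% = 1 corresponds to isochoric (volume-preserving) deformation, the
    mesh-quality ideal, so the quality factor vanishes there.
    """
    if accuracy < 0:
        raise ValueError("accuracy must be >= 0")
    return float(accuracy) * (float(j10_value) - 1.0) ** 2


def select_best(candidates: Sequence[dict]) -> dict:
    """Pick the best prediction from candidate records.

    Each record needs keys ``accuracy`` and ``j10`` (and typically ``lambda1``,
    ``lambda2``). Lowest score wins; ties broken by larger j10, then smaller
    lambda1 (prefer smoother, better-conditioned meshes).
    """
    if not candidates:
        raise ValueError("no candidates to select from")

    def keyfun(rec: dict):
        return (
            score(rec["accuracy"], rec["j10"]),
            -rec["j10"],
            rec.get("lambda1", 0.0),
        )

    return min(candidates, key=keyfun)


# ---------------------------------------------------------------------------
# Mesh I/O: Gmsh MSH 2.2 ASCII and legacy VTK ASCII
# ---------------------------------------------------------------------------


def write_mesh(
    mesh: TetMesh, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> None:
    """Write a tet mesh as Gmsh MSH 2.2 (.msh) or legacy VTK (.vtk) ASCII.

    ``point_data`` (name -> per-node scalars) is supported for VTK output,
    e.g. the per-node distance field of :func:`node_to_node_accuracy`.
    """
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtk":
        _write_vtk(mesh, path, point_data or {})
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}; use .msh or .vtk")


def read_mesh(path: str | Path) -> TetMesh:
    path = Path(path)
    if path.suffix == ".msh":
        return _read_msh(path)
    if path.suffix == ".vtk":
        return _read_vtk(path)
    raise ValueError(f"unsupported mesh format {path.suffix!r}; use .msh or .vtk")


def _write_msh(mesh: TetMesh, path: Path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for i, t in enumerate(mesh.tets, start=1):
        lines.append(f"{i} 4 2 0 1 {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> TetMesh:
    tokens = path.read_text().split("\n")
    nodes, tets = [], []
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line == "$Nodes":
            n = int(tokens[i + 1])
            for j in range(n):
                parts = tokens[i + 2 + j].split()
                nodes.append([float(x) for x in parts[1:4]])
            i += 2 + n
        elif line == "$Elements":
            n = int(tokens[i + 1])
            for j in range(n):
                parts = tokens[i + 2 + j].split()
                if int(parts[1]) == 4:  # 4-node tetrahedron
                    ntags = int(parts[2])
                    conn = [int(x) - 1 for x in parts[3 + ntags : 7 + ntags]]
                    tets.append(conn)
            i += 2 + n
        else:
            i += 1
    return TetMesh(nodes=np.array(nodes), tets=np.array(tets, dtype=int))


def _write_vtk(mesh: TetMesh, path: Path, point_data: dict[str, np.ndarray]) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "craniomorph tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    for t in mesh.tets:
        lines.append(f"4 {t[0]} {t[1]} {t[2]} {t[3]}")
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines.extend(["10"] * mesh.n_tets)  # VTK_TETRA
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float).reshape(-1)
            if len(values) != mesh.n_nodes:
                raise ValueError(f"point data {name!r} length != node count")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(v)) for v in values)
    path.write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path) -> TetMesh:
    lines = path.read_text().split("\n")
    nodes, tets = [], []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals: list[float] = []
            while len(vals) < 3 * n:
                i += 1
                vals.extend(float(x) for x in lines[i].split())
            nodes = np.array(vals).reshape(n, 3)
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            for j in range(m):
                parts = lines[i + 1 + j].split()
                if int(parts[0]) == 4:
                    tets.append([int(x) for x in parts[1:5]])
            i += m
        i += 1
    return TetMesh(nodes=np.array(nodes), tets=np.array(tets, dtype=int))


def write_surface_ply(nodes: np.ndarray, triangles: np.ndarray, path: str | Path) -> None:
    """Write a triangulated surface as ASCII PLY."""
    nodes = np.asarray(nodes, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=int).reshape(-1, 3)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(nodes)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(triangles)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines.extend(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}" for p in nodes)
    lines.extend(f"3 {t[0]} {t[1]} {t[2]}" for t in triangles)
    Path(path).write_text("\n".join(lines) + "\n")
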