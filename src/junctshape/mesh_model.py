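"""Contour stacks and triangulated membrane surfaces.

Segmentations of membranes arrive as planar contours traced on tomographic
slices (the bilayer midline, one polyline per slice).  This module defines the
exchange containers for those contours and for the triangulated surfaces built
from them, plus the stitching step that turns a stack of consecutive contours
into a surface mesh whose total triangle area is (greedily) minimal.

All coordinates are nanometres in a right-handed frame with z along the
tomographic axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "Contour",
    "ContourStack",
    "SurfaceMesh",
    "read_contours",
    "write_contours",
    "contours_to_mesh",
    "surface_area",
    "read_mesh",
    "write_mesh",
]

_CSV_COLUMNS = ["object_id", "contour_id", "z_index", "x_nm", "y_nm"]


@dataclass
class Contour:
    """One planar polyline at a fixed z slice.

    ``closed`` contours describe the outline of a closed object (>=3 points);
    open contours are membrane traces such as the nuclear envelope seen edge-on
    (>=2 points).
    """

    object_id: int
    contour_id: int
    z_index: int
    points: np.ndarray  # (n, 2) x/y in nm
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        min_pts = 3 if self.closed else 2
        if len(self.points) < min_pts:
            raise ValueError(
                f"contour {self.contour_id}: needs >= {min_pts} points "
                f"({'closed' if self.closed else 'open'}), got {len(self.points)}"
            )
        if not np.isfinite(self.points).all():
            raise ValueError(f"contour {self.contour_id}: non-finite coordinates")

    def xyz(self, z_spacing: float) -> np.ndarray:
        """Contour points lifted to 3D at ``z = z_index * z_spacing`` (nm)."""
        z = np.full(len(self.points), self.z_index * z_spacing)
        return np.column_stack([self.points, z])


@dataclass
class ContourStack:
    """A z-indexed set of planar contours with its slice spacing.

    ``z_spacing`` is the distance in nm between consecutive z indices
    (the tracing interval, e.g. every 2.25-4.51 nm of slices for fine
    membrane work, 9.02 nm for coarser surveys); ``pixel_size`` records the
    in-plane sampling for provenance and is not used in geometry (points are
    already in nm).
    """

    contours: list[Contour]
    z_spacing: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def by_object(self) -> dict[int, list[Contour]]:
        out: dict[int, list[Contour]] = {}
        for c in self.contours:
            out.setdefault(c.object_id, []).append(c)
        for cs in out.values():
            cs.sort(key=lambda c: c.z_index)
        return out


@dataclass
class SurfaceMesh:
    """Triangulated membrane surface in nm coordinates."""

    vertices: np.ndarray  # (n, 3) nm
    faces: np.ndarray  # (m, 3) int
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise ValueError("negative face index")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(
            vertices=np.asarray(tm.vertices, dtype=float),
            faces=np.asarray(tm.faces, dtype=np.int64),
            closed=bool(tm.is_watertight),
        )


# ---------------------------------------------------------------------------
# contour I/O
# ---------------------------------------------------------------------------

def write_contours(stack: ContourStack, path: str | Path, format: str | None = None) -> None:
    """Write a contour stack as CSV or JSON.

    CSV columns: object_id, contour_id, z_index, x_nm, y_nm; a leading
    ``# units: nm`` comment line records the unit convention.  JSON carries the
    same fields plus per-contour ``closed`` flags and the stack metadata.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        rows = []
        for c in stack.contours:
            for x, y in c.points:
                rows.append((c.object_id, c.contour_id, c.z_index, x, y))
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        with open(path, "w") as fh:
            fh.write(f"# units: nm; z_spacing_nm={stack.z_spacing}; pixel_size_nm={stack.pixel_size}\n")
            df.to_csv(fh, index=False)
    elif fmt == "json":
        doc = {
            "units": "nm",
            "z_spacing_nm": stack.z_spacing,
            "pixel_size_nm": stack.pixel_size,
            "contours": [
                {
                    "object_id": c.object_id,
                    "contour_id": c.contour_id,
                    "z_index": c.z_index,
                    "closed": c.closed,
                    "points_nm": c.points.tolist(),
                }
                for c in stack.contours
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown contour format: {fmt!r}")


def read_contours(path: str | Path, format: str | None = None) -> ContourStack:
    """Read a contour stack written by :func:`write_contours`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing units header line")
            meta = dict(
                kv.strip().split("=")
                for kv in header.lstrip("#").split(";")
                if "=" in kv
            )
            if "units: nm" not in header:
                raise ValueError(f"{path}: units are not nm")
            df = pd.read_csv(fh)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        bad = df[~np.isfinite(df[["x_nm", "y_nm"]]).all(axis=1)]
        if len(bad):
            # +3: 1-based lines, units header, column header
            raise ValueError(f"{path}: malformed row at line {bad.index[0] + 3}")
        contours = []
        for (obj, cid, z), grp in df.groupby(
            ["object_id", "contour_id", "z_index"], sort=True
        ):
            contours.append(
                Contour(int(obj), int(cid), int(z), grp[["x_nm", "y_nm"]].to_numpy())
            )
        return ContourStack(
            contours,
            z_spacing=float(meta.get("z_spacing_nm", 1.0)),
            pixel_size=float(meta.get("pixel_size_nm", 1.0)),
        )
    if fmt == "json":
        doc = json.loads(Path(path).read_text())
        if doc.get("units") != "nm":
            raise ValueError(f"{path}: units are not nm")
        contours = [
            Contour(
                int(c["object_id"]),
                int(c["contour_id"]),
                int(c["z_index"]),
                np.asarray(c["points_nm"], dtype=float),
                closed=bool(c.get("closed", True)),
            )
            for c in doc["contours"]
        ]
        return ContourStack(
            contours,
            z_spacing=float(doc["z_spacing_nm"]),
            pixel_size=float(doc.get("pixel_size_nm", 1.0)),
        )
    raise ValueError(f"unknown contour format: {fmt!r}")


# ---------------------------------------------------------------------------
# contour stitching
# ---------------------------------------------------------------------------

def _triangle_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def _resample_polyline(points: np.ndarray, n: int, closed: bool) -> np.ndarray:
    """Resample a polyline to n points by arc length."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if closed:
        targets = np.linspace(0.0, total, n, endpoint=False)
    else:
        targets = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(targets, t, pts[:, d])
    return out


def _align_start(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Cyclically rotate a closed ring so its start is nearest ref's start."""
    i = int(np.argmin(np.linalg.norm(other - ref[0], axis=1)))
    return np.roll(other, -i, axis=0)


def _zip_band(a: np.ndarray, b: np.ndarray, closed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Greedy triangulated band between two 3D polylines.

    At each step the frontier edge (a_i, b_j) is closed with whichever of the
    two candidate diagonals (a_{i+1}-b_j or a_i-b_{j+1}) is shorter — the
    classic zipper rule, which keeps the two fronts in lockstep and yields a
    band of near-minimal total area for overlapping consecutive contours.
    """
    na, nb = len(a), len(b)
    verts = np.vstack([a, b])
    faces = []
    i = j = 0
    # closed rings wrap around; open traces stop at the last vertex
    max_i, max_j = (na, nb) if closed else (na - 1, nb - 1)
    while i < max_i or j < max_j:
        can_a = i < max_i
        can_b = j < max_j
        diag_a = (
            float(np.linalg.norm(a[(i + 1) % na] - b[j % nb])) if can_a else np.inf
        )
        diag_b = (
            float(np.linalg.norm(b[(j + 1) % nb] - a[i % na])) if can_b else np.inf
        )
        if diag_a <= diag_b:
            faces.append([i % na, na + j % nb, (i + 1) % na])
            i += 1
        else:
            faces.append([i % na, na + j % nb, na + (j + 1) % nb])
            j += 1
    return verts, np.asarray(faces, dtype=np.int64)


def contours_to_mesh(
    stack: ContourStack,
    interpolate_every: float | None = None,
    samples_per_contour: int = 96,
) -> SurfaceMesh:
    """Stitch consecutive contours of each object into a triangulated surface.

    Consecutive contours are resampled to a common point count, aligned
    (closed rings rotated so starts match), and zipped with a greedy
    minimal-added-area rule.  ``interpolate_every`` optionally inserts linear
    intermediate contours at roughly that z pitch (nm) before stitching, as
    when traces drawn on sparse planes are interpolated along the tomographic
    axis.
    """
    objects = stack.by_object()
    if not objects:
        raise ValueError("empty contour stack")
    all_verts: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    offset = 0
    for obj_id, contours in objects.items():
        if len(contours) < 2:
            raise ValueError(f"object {obj_id}: needs >= 2 contours to stitch")
        closed = contours[0].closed
        rings = [_resample_polyline(c.xyz(stack.z_spacing), samples_per_contour, c.closed)
                 for c in contours]
        for k in range(1, len(rings)):
            if closed:
                rings[k] = _align_start(rings[k - 1], rings[k])
            # overlap check in xy projection: bounding boxes must intersect
            lo1, hi1 = rings[k - 1][:, :2].min(0), rings[k - 1][:, :2].max(0)
            lo2, hi2 = rings[k][:, :2].min(0), rings[k][:, :2].max(0)
            if (hi1 < lo2).any() or (hi2 < lo1).any():
                raise ValueError(
                    f"object {obj_id}: consecutive contours do not overlap in "
                    "projection; correspondence is ambiguous"
                )
        if interpolate_every is not None:
            if interpolate_every <= 0:
                raise ValueError("interpolate_every must be > 0")
            dense: list[np.ndarray] = []
            for k in range(len(rings) - 1):
                dz = abs(rings[k + 1][0, 2] - rings[k][0, 2])
                n_mid = max(0, int(np.ceil(dz / interpolate_every)) - 1)
                dense.append(rings[k])
                for m in range(1, n_mid + 1):
                    t = m / (n_mid + 1)
                    dense.append((1 - t) * rings[k] + t * rings[k + 1])
            dense.append(rings[-1])
            rings = dense
        for k in range(len(rings) - 1):
            v, f = _zip_band(rings[k], rings[k + 1], closed)
            all_verts.append(v)
            all_faces.append(f + offset)
            offset += len(v)
    return SurfaceMesh(np.vstack(all_verts), np.vstack(all_faces), closed=False)


def surface_area(mesh: SurfaceMesh | trimesh.Trimesh) -> float:
    """Total triangle area in nm^2 (sum over faces; additive over submeshes)."""
    if isinstance(mesh, SurfaceMesh):
        if len(mesh.faces) == 0:
            return 0.0
        mesh = mesh.to_trimesh()
    return float(mesh.area)


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

_MESH_FORMATS = {"obj", "ply", "stl"}


def write_mesh(mesh: SurfaceMesh, path: str | Path, format: str | None = None) -> None:
    """Write a surface as OBJ, PLY or STL (coordinates in nm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unknown mesh format: {fmt!r}")
    tm = mesh.to_trimesh()
    tm.export(path, file_type=fmt)
    if fmt == "obj":  # OBJ admits comments; record the unit convention
        text = path.read_text()
        path.write_text("# units: nm\n" + text)


def read_mesh(path: str | Path, format: str | None = None) -> SurfaceMesh:
    """Read an OBJ/PLY/STL surface; quads are triangulated, other polygons fail."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unknown mesh format: {fmt!r}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse errors uniformly
        raise ValueError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"{path}: no triangulated surface found")
    return SurfaceMesh.from_trimesh(tm)
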