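"""Stereological sampling of inspection regions on a segmented nuclear surface.

Whole-cell FIB-SEM volumes are too large to screen exhaustively, so junction
abundance is assessed in spherical regions of interest (radius 800-1000 nm)
centred on points spread uniformly over the nuclear surface: the first point
is picked at random, the rest by farthest-point sampling, which spreads them
evenly outward from the first — a reproducible form of "uniform radial"
placement.  All distances are in nm, so anisotropic voxels (e.g. FIB-SEM at
4.0 x 4.0 x 3.4 nm) are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VoxelMask",
    "ROISphere",
    "extract_surface",
    "sample_surface_points",
    "roi_sphere",
    "screen_report",
]


@dataclass
class VoxelMask:
    """Binary 3D mask with per-axis voxel size in nm (axis order z, y, x)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D array")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (nm)")
        self.voxel_size = vs
        if not self.data.any():
            raise ValueError("mask has no foreground")


@dataclass
class ROISphere:
    """A spherical inspection region centred on the nuclear surface."""

    id: int
    center: np.ndarray  # (3,) nm, (z, y, x)
    radius: float  # nm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


def extract_surface(mask: VoxelMask) -> np.ndarray:
    """Surface voxel centres of a binary mask, in nm.

    A surface voxel is a foreground voxel with at least one six-connected
    background neighbour; voxels touching the array border do not count as
    surface on that side (outside the array is not background).  Returns an
    (n, 3) array of voxel-centre coordinates (z, y, x) in nm.
    """
    data = mask.data
    if data.all():
        raise ValueError("mask is all foreground: no surface")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(data, structure=structure, border_value=1)
    surface = data & ~interior
    idx = np.argwhere(surface)
    if len(idx) == 0:
        raise ValueError("mask has no surface voxels")
    return (idx + 0.5) * np.asarray(mask.voxel_size)


def sample_surface_points(
    surface: np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """n points spread uniformly over a surface point set.

    The first point is uniform-random under the seed; each subsequent point
    is the surface point farthest (in nm) from the already chosen set
    (farthest-point sampling).  Deterministic given the seed; the points are
    distinct members of the input set.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != 2 or surface.shape[1] != 3:
        raise ValueError("surface must be an (n, 3) point array")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(surface):
        raise ValueError(f"requested {n} points from a surface of {len(surface)}")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(0, len(surface)))]
    min_dist = np.linalg.norm(surface - surface[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        d = np.linalg.norm(surface - surface[nxt], axis=1)
        np.minimum(min_dist, d, out=min_dist)
    return surface[chosen]


def roi_sphere(
    mask: VoxelMask, center: np.ndarray, radius: float, roi_id: int = 0
) -> tuple[np.ndarray, tuple[slice, slice, slice], dict]:
    """Crop a spherical ROI from a mask.

    Returns the cropped subvolume with the spherical membership mask applied
    (voxels whose centre lies within ``radius`` nm of ``center``), the
    bounding-box slices into the parent array, and metadata with the world
    coordinates and a ``clipped`` flag when the sphere exceeds the array.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    vs = np.asarray(mask.voxel_size)
    lo_f = np.floor((center - radius) / vs).astype(int)
    hi_f = np.ceil((center + radius) / vs).astype(int) + 1
    shape = np.array(mask.data.shape)
    lo = np.clip(lo_f, 0, shape)
    hi = np.clip(hi_f, 0, shape)
    clipped = bool((lo_f < 0).any() or (hi_f > shape).any())
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = mask.data[box]
    zi, yi, xi = np.ogrid[box[0], box[1], box[2]]
    dz = (zi + 0.5) * vs[0] - center[0]
    dy = (yi + 0.5) * vs[1] - center[1]
    dx = (xi + 0.5) * vs[2] - center[2]
    inside = dz**2 + dy**2 + dx**2 <= radius**2
    meta = {
        "roi_id": roi_id,
        "center_nm": center.tolist(),
        "radius_nm": float(radius),
        "origin_nm": (lo * vs).tolist(),
        "clipped": clipped,
    }
    return sub & inside, box, meta


def screen_report(
    rois: list[ROISphere],
    findings: list[tuple[int, str, float]],
) -> pd.DataFrame:
    """Tidy per-ROI screening table.

    ``findings`` holds (roi_id, junction_kind, width_nm) records from manual
    or automated inspection of each ROI.  The report lists every ROI (zero
    counts included) with per-kind junction counts and width summaries;
    duplicate identical findings are kept but flagged.
    """
    roi_ids = [r.id for r in rois]
    df = pd.DataFrame(findings, columns=["roi_id", "junction_kind", "width_nm"])
    unknown = set(df["roi_id"]) - set(roi_ids)
    if unknown:
        raise ValueError(f"findings reference unknown ROI ids: {sorted(unknown)}")
    df["duplicate"] = df.duplicated(keep=False)
    rows = []
    kinds = sorted(df["junction_kind"].unique()) if len(df) else []
    for rid in roi_ids:
        sub = df[df["roi_id"] == rid]
        row: dict = {"roi_id": rid, "n_total": len(sub),
                     "n_duplicate": int(sub["duplicate"].sum())}
        for kind in kinds:
            ks = sub[sub["junction_kind"] == kind]
            row[f"n_{kind}"] = len(ks)
            row[f"width_mean_{kind}"] = ks["width_nm"].mean() if len(ks) else np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["width_totals"] = {
        kind: df.loc[df["junction_kind"] == kind, "width_nm"].tolist()
        for kind in kinds
    }
    return report
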