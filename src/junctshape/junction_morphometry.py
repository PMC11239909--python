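"""Junction neck metrics: width, aspect ratio, length, and auxiliaries.

A membrane junction is measured on a series of planar cross-sections taken
from its base (where it meets the outer nuclear membrane) along a centreline:
the *neck* is the minimum-area section within a window of the base (default
25 nm); the *width* is the mean of the two sides of the neck's minimum-area
rotated bounding rectangle; the *aspect ratio* their quotient; and the
*length* L = L1 + L2 where each L_i is the distance from the neck to the
nearest sampled section with a 1.2-fold larger area, toward the nuclear
envelope and toward the ER respectively.  Linear dimensions measured on
plastic-embedded specimens are corrected for preparation shrinkage by
dividing by (1 - shrinkage fraction), default 17%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import trimesh

from .cross_section import (
    CrossSection,
    SectionPlane,
    section_series,
    slice_plane,
)
from .mesh_model import SurfaceMesh

__all__ = [
    "LumenClass",
    "CellStage",
    "JunctionAnnotation",
    "MorphometryResult",
    "find_neck",
    "junction_width",
    "junction_aspect_ratio",
    "junction_length",
    "correct_shrinkage",
    "side_profile",
    "two_point_width",
    "ne_width_below_junction",
    "distance_to_surface",
    "measure_junction",
]


class LumenClass(str, Enum):
    WITH_LUMEN = "with_lumen"
    NO_LUMEN = "no_lumen"
    AMBIGUOUS = "ambiguous"
    CONTACT_SITE = "contact_site"


class CellStage(str, Enum):
    ANAPHASE = "anaphase"
    TELOPHASE = "telophase"
    INTERPHASE = "interphase"


@dataclass
class JunctionAnnotation:
    """Operator annotation of one junction: where it meets the NE and what
    kind it is.

    ``base_point`` sits on the mean ONM plane at the junction mouth;
    ``axis_hint`` points from the NE into the ER.  ``contact_site`` records
    apposed-but-not-fused membranes and is excluded from neck morphometry
    (counted separately in abundance tallies).
    """

    junction_id: str
    base_point: np.ndarray
    axis_hint: np.ndarray
    lumen_class: LumenClass = LumenClass.WITH_LUMEN
    truncated: bool = False
    cell_stage: CellStage = CellStage.INTERPHASE

    def __post_init__(self) -> None:
        self.base_point = np.asarray(self.base_point, dtype=float).reshape(3)
        a = np.asarray(self.axis_hint, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis_hint must be a non-zero vector")
        self.axis_hint = a / n
        self.lumen_class = LumenClass(self.lumen_class)
        self.cell_stage = CellStage(self.cell_stage)


@dataclass
class MorphometryResult:
    """One junction's measurements (all linear dimensions nm)."""

    junction_id: str
    width_W: float
    aspect_ratio_AR: float
    length_L: float | None
    L1: float | None
    L2: float | None
    neck_station: float
    neck_area_Amin: float
    top_profile: np.ndarray | None = None
    side_profile: tuple[np.ndarray, np.ndarray] | None = None
    flags: set[str] = field(default_factory=set)

    def as_record(self) -> dict:
        return {
            "junction_id": self.junction_id,
            "width_nm": self.width_W,
            "ar": self.aspect_ratio_AR,
            "L_nm": self.length_L,
            "L1_nm": self.L1,
            "L2_nm": self.L2,
            "neck_station_nm": self.neck_station,
            "Amin_nm2": self.neck_area_Amin,
            "flags": ";".join(sorted(self.flags)),
        }


def find_neck(
    sections: list[CrossSection],
    window: float = 25.0,
    smooth_nm: float = 3.0,
) -> CrossSection:
    """Minimum-area cross-section within ``window`` nm of the junction base.

    When sections are sampled much more finely than the tracing noise is
    correlated, taking a raw argmin over many sections selects downward noise
    excursions and underestimates the neck; the area profile is therefore
    smoothed with a moving average of half-width ``smooth_nm`` (default 3 nm,
    the scale over which tracing error decorrelates) before locating the
    minimum (``smooth_nm=0`` disables this).  The returned object is an
    actual sampled section with its raw area.  Ties go to the smaller station
    (closest to the base).  If the minimum sits at the first station and the
    in-window areas increase monotonically, the junction has no interior
    constriction; callers detect this via :func:`is_constricted` or the
    ``non_constricted`` flag set by :func:`measure_junction`.
    """
    in_window = [c for c in sections if 0.0 <= c.station_s <= window]
    if len(in_window) < 2:
        raise ValueError(f"need >= 2 sections with station in [0, {window}] nm")
    in_window.sort(key=lambda c: c.station_s)
    stations = np.array([c.station_s for c in in_window])
    areas = np.array([c.area for c in in_window])
    if smooth_nm > 0:
        smoothed = np.array(
            [areas[np.abs(stations - s) <= smooth_nm].mean() for s in stations]
        )
    else:
        smoothed = areas
    k = int(np.argmin(np.where(smoothed == smoothed.min(), stations, np.inf)))
    if smooth_nm > 0 and 0 < k < len(stations) - 1:
        # refine with a local parabola on the raw areas: near its waist a
        # smooth neck has a quadratic area profile, and a least-squares vertex
        # does not correlate with any single section's noise the way a raw
        # argmin does
        local = np.abs(stations - stations[k]) <= max(5.0, 2 * smooth_nm)
        if local.sum() >= 4:
            coef = np.polyfit(stations[local], areas[local], 2)
            if coef[0] > 0:
                vertex = -coef[1] / (2 * coef[0])
                if stations[local].min() <= vertex <= stations[local].max():
                    k = int(np.argmin(np.abs(stations - vertex)))
    return in_window[k]


def is_constricted(sections: list[CrossSection], window: float = 25.0) -> bool:
    """False when the in-window area profile is monotone increasing from the
    base (wide-cone geometry: no interior minimum)."""
    in_window = sorted(
        (c for c in sections if 0.0 <= c.station_s <= window),
        key=lambda c: c.station_s,
    )
    areas = np.array([c.area for c in in_window])
    at_first = np.argmin(areas) == 0
    monotone = bool(np.all(np.diff(areas) >= -1e-9 * areas[:-1]))
    return not (at_first and monotone)


def junction_width(neck: CrossSection) -> float:
    """Width = mean of the long and short sides of the neck's minimum-area
    rotated bounding rectangle, nm."""
    return 0.5 * (neck.rect_major + neck.rect_minor)


def junction_aspect_ratio(neck: CrossSection) -> float:
    """Aspect ratio = major/minor side of the neck bounding rectangle (>= 1)."""
    return neck.rect_major / neck.rect_minor


def junction_length(
    sections: list[CrossSection],
    neck: CrossSection,
    factor: float = 1.2,
) -> tuple[float | None, float | None, float | None, set[str]]:
    """Neck length from the area profile.

    On each side of the neck, take the nearest *sampled* station whose area is
    at least ``factor`` times the neck area (no interpolation); L1 toward the
    NE (stations below the neck), L2 toward the ER (stations above).  If a
    side's series ends before the threshold is reached the junction is
    truncated on that side: the corresponding flag is set, that L_i is None,
    and L is undefined.

    Returns ``(L, L1, L2, flags)``.
    """
    if factor <= 1.0:
        raise ValueError("factor must be > 1")
    threshold = factor * neck.area
    s0 = neck.station_s
    below = sorted(
        (c for c in sections if c.station_s < s0), key=lambda c: -c.station_s
    )
    above = sorted(
        (c for c in sections if c.station_s > s0), key=lambda c: c.station_s
    )
    flags: set[str] = set()

    def first_crossing(side: list[CrossSection]) -> float | None:
        for c in side:
            if c.area >= threshold:
                return abs(c.station_s - s0)
        return None

    L1 = first_crossing(below)
    L2 = first_crossing(above)
    if L1 is None:
        flags.add("truncated_L1")
    if L2 is None:
        flags.add("truncated_L2")
    L = L1 + L2 if (L1 is not None and L2 is not None) else None
    return L, L1, L2, flags


def correct_shrinkage(measured: float, shrinkage_fraction: float = 0.17) -> float:
    """Estimate the native dimension from a measured one.

    Plastic embedding and beam exposure shrink the specimen isotropically by
    ``shrinkage_fraction`` (default 0.17), so the native length is
    ``measured / (1 - fraction)``.  Linear, hence applicable to widths,
    lengths and their sums alike.
    """
    if not (0.0 <= shrinkage_fraction < 1.0):
        raise ValueError("shrinkage_fraction must be in [0, 1)")
    return measured / (1.0 - shrinkage_fraction)


def _closest_point_on_mesh(
    tm: trimesh.Trimesh, p: np.ndarray
) -> tuple[np.ndarray, float]:
    """Closest point on a triangulated surface (vectorized over triangles)."""
    tri = np.asarray(tm.triangles, dtype=float)
    if len(tri) == 0:
        raise ValueError("mesh has no faces")
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    eps = 1e-300
    closest = np.empty_like(a)
    # barycentric interior projection (default)
    denom = va + vb + vc
    v = vb / np.where(denom == 0, eps, denom)
    w = vc / np.where(denom == 0, eps, denom)
    closest[:] = a + v[:, None] * ab + w[:, None] * ac
    # edge BC
    t_bc = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, eps, (d4 - d3) + (d5 - d6))
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest[m] = b[m] + t_bc[m, None] * (c - b)[m]
    # edge AC
    t_ac = d2 / np.where(d2 - d6 == 0, eps, d2 - d6)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest[m] = a[m] + t_ac[m, None] * ac[m]
    # edge AB
    t_ab = d1 / np.where(d1 - d3 == 0, eps, d1 - d3)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest[m] = a[m] + t_ab[m, None] * ab[m]
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    m = (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    m = (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    dists = np.linalg.norm(closest - p, axis=1)
    k = int(np.argmin(dists))
    return closest[k], float(dists[k])


def two_point_width(p1: np.ndarray, p2: np.ndarray) -> float:
    """Euclidean length of a 2-point line across a neck or base, nm."""
    p1 = np.asarray(p1, dtype=float).reshape(3)
    p2 = np.asarray(p2, dtype=float).reshape(3)
    d = float(np.linalg.norm(p2 - p1))
    if d == 0.0:
        raise ValueError("the two points coincide")
    return d


def side_profile(
    mesh: SurfaceMesh | trimesh.Trimesh,
    neck_centroid: np.ndarray,
    axis: np.ndarray,
    view_normal: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal membrane profile through the junction axis.

    Slices the surface with a plane containing the centreline axis at the
    neck and splits the intersection into the two membrane traces left and
    right of the axis, each returned as an (n, 2) polyline in (transverse,
    axial) coordinates — the overlayable side-view profile.
    """
    centroid = np.asarray(neck_centroid, dtype=float).reshape(3)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    if view_normal is None:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(ax[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        view_normal = np.cross(ax, helper)
    vn = np.asarray(view_normal, dtype=float)
    vn = vn / np.linalg.norm(vn)
    if abs(float(vn @ ax)) > 1e-6:
        raise ValueError("view_normal must be perpendicular to the axis")
    trans = np.cross(ax, vn)  # in-plane transverse direction

    tm = mesh.to_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    loops = slice_plane(tm, SectionPlane(origin=centroid, normal=vn))
    if not loops:
        raise ValueError("sagittal plane does not intersect the surface")
    pts3 = np.vstack([lp.points3d for lp in loops])
    rel = pts3 - centroid
    t = rel @ trans
    s = rel @ ax
    left = np.column_stack([t[t < 0], s[t < 0]])
    right = np.column_stack([t[t >= 0], s[t >= 0]])
    left = left[np.argsort(left[:, 1])]
    right = right[np.argsort(right[:, 1])]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("profile does not straddle the axis")
    return left, right


def ne_width_below_junction(
    base_point: np.ndarray,
    inm_surface: SurfaceMesh | trimesh.Trimesh,
    ne_tangent: np.ndarray,
    controls_at: tuple[float, float] = (200.0, 500.0),
    onm_surface: SurfaceMesh | trimesh.Trimesh | None = None,
) -> tuple[float, list[float]]:
    """Perinuclear-space width below a junction and at flanking controls.

    ``base_point`` is where the ONM would run were the junction absent; the
    width below the junction is its distance to the nearest INM point.  Two
    controls are taken in opposite directions along the NE (``ne_tangent``),
    at a distance within ``controls_at`` nm of the base (midpoint of the range
    by default); if an ONM surface is supplied the control start points are
    first projected onto it.
    """
    if inm_surface is None:
        raise ValueError("INM surface is required")
    inm = inm_surface.to_trimesh() if isinstance(inm_surface, SurfaceMesh) else inm_surface
    base = np.asarray(base_point, dtype=float).reshape(3)
    t = np.asarray(ne_tangent, dtype=float)
    t = t / np.linalg.norm(t)
    lo, hi = controls_at
    if not (0 < lo <= hi):
        raise ValueError("controls_at must be a positive (lo, hi) range")
    d_ctrl = 0.5 * (lo + hi)

    width_below = _closest_point_on_mesh(inm, base)[1]
    controls = []
    for sign in (+1.0, -1.0):
        p = base + sign * d_ctrl * t
        if onm_surface is not None:
            onm = (
                onm_surface.to_trimesh()
                if isinstance(onm_surface, SurfaceMesh)
                else onm_surface
            )
            p = _closest_point_on_mesh(onm, p)[0]
        controls.append(_closest_point_on_mesh(inm, np.asarray(p))[1])
    return width_below, controls


def distance_to_surface(point: np.ndarray, mesh: SurfaceMesh | trimesh.Trimesh) -> float:
    """Minimum Euclidean distance from a point to a triangulated surface, nm."""
    tm = mesh.to_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    p = np.asarray(point, dtype=float).reshape(3)
    return _closest_point_on_mesh(tm, p)[1]


def measure_junction(
    mesh: SurfaceMesh | trimesh.Trimesh,
    annotation: JunctionAnnotation,
    step: float = 0.5,
    window: float = 25.0,
    factor: float = 1.2,
    range_nm: float | None = None,
    mode: str = "adaptive",
    with_profiles: bool = False,
) -> MorphometryResult:
    """Full morphometry of one junction: sections, neck, W, AR, L, profiles.

    Sections are taken from the annotated base along the centreline; the
    series is allowed to end early past the neck window (e.g. a junction
    truncated at the tomogram border), in which case the affected length is
    flagged rather than invented.  Contact-site annotations are rejected: the
    membranes are not continuous, so there is no neck to measure.
    """
    if annotation.lumen_class is LumenClass.CONTACT_SITE:
        raise ValueError(
            f"junction {annotation.junction_id}: contact sites are excluded "
            "from neck morphometry"
        )
    if range_nm is None:
        range_nm = 2.0 * window
    sections = section_series(
        mesh,
        base=annotation.base_point,
        axis=annotation.axis_hint,
        step=step,
        range_nm=range_nm,
        mode=mode,
        # a junction cut by the tomogram border legitimately ends early; the
        # truncation flags, not an error, report the missing side
        min_range=2 * step,
    )
    neck = find_neck(sections, window=window)
    flags: set[str] = set()
    if not is_constricted(sections, window=window):
        flags.add("non_constricted")
    L, L1, L2, lflags = junction_length(sections, neck, factor=factor)
    flags |= lflags
    if annotation.truncated:
        flags.add("truncated_L2")
    result = MorphometryResult(
        junction_id=annotation.junction_id,
        width_W=junction_width(neck),
        aspect_ratio_AR=junction_aspect_ratio(neck),
        length_L=L,
        L1=L1,
        L2=L2,
        neck_station=neck.station_s,
        neck_area_Amin=neck.area,
        flags=flags,
    )
    if with_profiles:
        result.top_profile = neck.loop
        result.side_profile = side_profile(
            mesh, neck.centroid, annotation.axis_hint
        )
    return result
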