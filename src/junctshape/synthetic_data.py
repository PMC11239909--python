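"""Synthetic junction geometries with known ground truth.

Electron-tomography morphometry of membrane junctions cannot be validated on
real tomograms without their manual segmentations, so this module builds the
relevant geometries analytically:

* *hourglass* junctions — the constricted ER–NE type — as a hyperboloid of
  revolution, radius profile ``r(s) = r0 * sqrt(1 + s^2/c^2)`` around the neck,
  optionally squeezed to an elliptical cross-section, merged into a flat
  nuclear-envelope annulus at the base and left open at the ER side;
* *wide-cone* junctions — the broad ER–ER type — as a monotonically widening
  funnel with no interior constriction;
* flat or cylindrically curved NE sheets as traced contour stacks, for
  surface-area estimation;
* ellipsoidal nuclear masks for stereological sampling;
* whole populations of junctions placed on an NE sheet, with annotations and
  per-junction ground truth, for end-to-end frequency and width-recovery
  tests.

The hyperboloid's cross-section area is ``A(s) = A(0) * (1 + s^2/c^2)``, so
the station where the area first exceeds 1.2-fold the neck area is
``s = c * sqrt(0.2)`` and the full neck length is ``2 c sqrt(0.2)`` — the
closed form every length measurement is checked against.

Default population parameters reproduce the reported interphase geometry:
neck widths 17.4 +/- 5.0 nm for junctions with a lumen and 6.9 +/- 1.1 nm
(bilayer-midline separation) for those without, and a default neck scale of
11.6 nm, which puts the default neck length at 2*11.6*sqrt(0.2) ~ 10.4 nm,
the reported with-lumen mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .junction_morphometry import CellStage, JunctionAnnotation, LumenClass
from .mesh_model import Contour, ContourStack, SurfaceMesh
from .stereology import VoxelMask

__all__ = [
    "ShapeClass",
    "SyntheticJunctionSpec",
    "GroundTruth",
    "PopulationSpec",
    "Scene",
    "make_hourglass",
    "make_wide_cone",
    "make_ne_sheet",
    "make_nuclear_mask",
    "sample_population",
]

AREA_FACTOR = 1.2  # neck-length threshold: area 1.2-fold above the minimum


class ShapeClass(str, Enum):
    HOURGLASS = "hourglass"
    WIDE_CONE = "wide_cone"


@dataclass
class SyntheticJunctionSpec:
    """Parameters of one synthetic junction.

    neck_diameter : nm, 2*r0, the minor opening of the neck (for no-lumen
        junctions this is near bilayer thickness, since profiles trace the
        bilayer midline).
    neck_scale : nm, the hyperboloid steepness c; the neck length is
        ``2 c sqrt(0.2)``.
    ellipticity : >= 1, ratio of the neck ellipse major/minor axes.
    flare_length : nm, extent of the surface on either side of the neck
        (base annulus to neck, and neck to the open ER stub).
    jitter_sd : nm, isotropic Gaussian vertex noise emulating tracing error.
    mesh_step : nm, tessellation pitch (axial and circumferential).
    truncate_at : nm or None; if set, the ER side ends at this station above
        the neck (emulating a junction cut by the tomogram border).
    """

    neck_diameter: float = 17.4
    neck_scale: float = 11.6
    ellipticity: float = 1.0
    flare_length: float = 15.0
    shape_class: ShapeClass = ShapeClass.HOURGLASS
    lumen_class: LumenClass = LumenClass.WITH_LUMEN
    jitter_sd: float = 0.0
    mesh_step: float = 0.5
    seed: int = 0
    truncate_at: float | None = None

    def __post_init__(self) -> None:
        self.shape_class = ShapeClass(self.shape_class)
        self.lumen_class = LumenClass(self.lumen_class)
        if self.neck_diameter <= 0:
            raise ValueError("neck_diameter must be > 0")
        if self.neck_scale <= 0:
            raise ValueError("neck_scale must be > 0")
        if self.ellipticity < 1:
            raise ValueError("ellipticity must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.mesh_step <= 0:
            raise ValueError("mesh_step must be > 0")
        if self.mesh_step >= self.neck_diameter:
            raise ValueError(
                "mesh_step must be smaller than neck_diameter "
                "(the neck is unresolvable at this tessellation pitch)"
            )


@dataclass
class GroundTruth:
    """Closed-form values the measurement pipeline should recover."""

    true_width: float
    true_aspect_ratio: float
    true_length: float
    true_neck_station: float
    spec: SyntheticJunctionSpec


@dataclass
class PopulationSpec:
    """A population of hourglass junctions on an NE sheet.

    Neck diameters are drawn from a normal truncated at 2 nm:
    ``Normal(width_mean, width_sd)`` for with-lumen junctions and
    ``Normal(no_lumen_width_mean, no_lumen_width_sd)`` for no-lumen ones.
    ``class_mix`` gives the lumen-class proportions (must sum to 1); the
    default mix follows the observed 10:9 with/without-lumen split.
    """

    n_junctions: int = 23
    width_mean: float = 17.4
    width_sd: float = 5.0
    no_lumen_width_mean: float = 6.9
    no_lumen_width_sd: float = 1.1
    class_mix: dict[LumenClass, float] = field(
        default_factory=lambda: {
            LumenClass.WITH_LUMEN: 10 / 19,
            LumenClass.NO_LUMEN: 9 / 19,
        }
    )
    scene_area_um2: float = 178.0
    jitter_sd: float = 0.0
    mesh_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_junctions < 0:
            raise ValueError("n_junctions must be >= 0")
        if self.width_sd < 0 or self.no_lumen_width_sd < 0:
            raise ValueError("width s.d. must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.scene_area_um2 <= 0:
            raise ValueError("scene_area_um2 must be > 0")


@dataclass
class Scene:
    """A generated population: meshes, annotations, truths, NE sheet."""

    meshes: list[SurfaceMesh]
    annotations: list[JunctionAnnotation]
    ground_truths: list[GroundTruth]
    ne_stack: ContourStack
    scene_area_um2: float


# ---------------------------------------------------------------------------
# surface-of-revolution builders
# ---------------------------------------------------------------------------

def _revolve(
    stations: np.ndarray,
    radii: np.ndarray,
    ellipticity: float,
    n_theta: int,
    z_of_s,
) -> tuple[np.ndarray, np.ndarray]:
    """Rings of an elliptical surface of revolution plus band faces."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = []
    for s, r in zip(stations, radii):
        ring = np.column_stack(
            [ellipticity * r * ct, r * st, np.full(n_theta, z_of_s(s))]
        )
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for k in range(len(stations) - 1):
        a = k * n_theta
        b = (k + 1) * n_theta
        for t in range(n_theta):
            tn = (t + 1) % n_theta
            faces.append([a + t, b + t, b + tn])
            faces.append([a + t, b + tn, a + tn])
    return verts, np.asarray(faces, dtype=np.int64)


def _axial_stations(lo: float, hi: float, step: float) -> np.ndarray:
    # one extra subdivision keeps ring planes off the measurement grid
    n = int(np.ceil((hi - lo) / step)) + 2
    return np.linspace(lo, hi, n)


def _tracing_jitter(
    stations: np.ndarray,
    n_theta: int,
    sd: float,
    seed: int,
    ctrl_spacing: float = 3.0,
) -> np.ndarray:
    """Smooth Gaussian displacement field emulating manual tracing error.

    Tracing noise lives at the scale of the traced slices (a few nm), not at
    the sub-nm tessellation pitch: i.i.d. Gaussian offsets (sd per component)
    are drawn on a coarse (station, angle) control grid with ~3 nm axial
    spacing and interpolated bilinearly (periodic in angle) to every tube
    vertex.  Returns an (n_s * n_theta, 3) displacement, ring-major order.
    """
    if sd <= 0:
        return np.zeros((len(stations) * n_theta, 3))
    rng = np.random.default_rng(seed)
    span = stations[-1] - stations[0]
    n_ctrl_s = max(2, int(np.ceil(span / ctrl_spacing)) + 1)
    ctrl_s = np.linspace(stations[0], stations[-1], n_ctrl_s)
    n_ctrl_t = 8
    coef = rng.normal(0.0, sd, size=(n_ctrl_s, n_ctrl_t, 3))
    # axial interpolation to each ring station
    axial = np.empty((len(stations), n_ctrl_t, 3))
    for j in range(n_ctrl_t):
        for c in range(3):
            axial[:, j, c] = np.interp(stations, ctrl_s, coef[:, j, c])
    # periodic angular interpolation to each vertex angle
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ctrl_t = np.linspace(0.0, 2 * np.pi, n_ctrl_t + 1)  # wrap last == first
    disp = np.empty((len(stations), n_theta, 3))
    for k in range(len(stations)):
        ring = np.vstack([axial[k], axial[k, :1]])  # wrap
        for c in range(3):
            disp[k, :, c] = np.interp(theta, ctrl_t, ring[:, c])
    # taper to zero at the tube ends so the open boundaries (NE mouth, ER
    # stub) stay planar and sections near them remain closed loops
    ramp = min(3.0, span / 4.0)
    w = np.minimum(stations - stations[0], stations[-1] - stations) / ramp
    w = np.clip(w, 0.0, 1.0)
    disp *= w[:, None, None]
    return disp.reshape(-1, 3)


def _with_base_annulus(
    verts: np.ndarray,
    faces: np.ndarray,
    base_ring: slice,
    outer_radius: float,
    ellipticity: float,
    n_theta: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Append a flat NE annulus in the z=0 plane around the base ring."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    outer = np.column_stack(
        [
            ellipticity * outer_radius * np.cos(theta),
            outer_radius * np.sin(theta),
            np.zeros(n_theta),
        ]
    )
    off = len(verts)
    base_idx = np.arange(base_ring.start, base_ring.stop)
    new_faces = []
    for t in range(n_theta):
        tn = (t + 1) % n_theta
        # wound to match the tube bands so the joined surface is orientable
        new_faces.append([off + t, base_idx[t], off + tn])
        new_faces.append([base_idx[t], base_idx[tn], off + tn])
    return np.vstack([verts, outer]), np.vstack([faces, np.asarray(new_faces)])


def make_hourglass(spec: SyntheticJunctionSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Hourglass (constricted) junction surface and its ground truth.

    The neck sits at height ``flare_length`` above the base plane (z = 0,
    the mean ONM plane); the surface continues another ``flare_length`` (or
    ``truncate_at``) toward the ER and ends open there.  With ``jitter_sd=0``
    and a fixed seed the output is a pure function of the spec.
    """
    if spec.shape_class is not ShapeClass.HOURGLASS:
        raise ValueError("spec.shape_class must be 'hourglass'")
    r0 = spec.neck_diameter / 2.0
    c = spec.neck_scale
    flare = spec.flare_length
    hi = spec.truncate_at if spec.truncate_at is not None else flare
    if hi <= 0:
        raise ValueError("truncate_at must be > 0 (above the neck)")
    stations = _axial_stations(-flare, hi, spec.mesh_step)
    radii = r0 * np.sqrt(1.0 + (stations / c) ** 2)
    circumference = 2 * np.pi * r0 * spec.ellipticity
    n_theta = int(np.clip(np.ceil(circumference / spec.mesh_step), 48, 256))
    verts, faces = _revolve(
        stations, radii, spec.ellipticity, n_theta, z_of_s=lambda s: s + flare
    )
    verts = verts + _tracing_jitter(stations, n_theta, spec.jitter_sd, spec.seed)
    r_base = float(radii[0])
    verts, faces = _with_base_annulus(
        verts, faces, slice(0, n_theta), outer_radius=3.0 * r_base + 20.0,
        ellipticity=spec.ellipticity, n_theta=n_theta,
    )
    truth = GroundTruth(
        true_width=spec.neck_diameter * (1.0 + spec.ellipticity) / 2.0,
        true_aspect_ratio=spec.ellipticity,
        true_length=2.0 * c * np.sqrt(AREA_FACTOR - 1.0),
        true_neck_station=flare,
        spec=spec,
    )
    return SurfaceMesh(verts, faces, closed=False), truth


def make_wide_cone(spec: SyntheticJunctionSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Wide-cone (non-constricted) junction: monotone-widening funnel.

    The opening at the base plane has diameter ``neck_diameter`` (the widest
    point is away from the base — the profile has no interior minimum), and
    the flank slope is set by ``neck_scale``: r(s) = r_base * (1 + s/c).
    """
    if spec.shape_class is not ShapeClass.WIDE_CONE:
        raise ValueError("spec.shape_class must be 'wide_cone'")
    r_base = spec.neck_diameter / 2.0
    c = spec.neck_scale
    hi = spec.truncate_at if spec.truncate_at is not None else 2.0 * spec.flare_length
    stations = _axial_stations(0.0, hi, spec.mesh_step)
    radii = r_base * (1.0 + stations / c)
    circumference = 2 * np.pi * r_base * spec.ellipticity
    n_theta = int(np.clip(np.ceil(circumference / spec.mesh_step), 48, 256))
    verts, faces = _revolve(
        stations, radii, spec.ellipticity, n_theta, z_of_s=lambda s: s
    )
    verts = verts + _tracing_jitter(stations, n_theta, spec.jitter_sd, spec.seed)
    verts, faces = _with_base_annulus(
        verts, faces, slice(0, n_theta), outer_radius=3.0 * r_base + 20.0,
        ellipticity=spec.ellipticity, n_theta=n_theta,
    )
    truth = GroundTruth(
        true_width=spec.neck_diameter * (1.0 + spec.ellipticity) / 2.0,
        true_aspect_ratio=spec.ellipticity,
        true_length=np.nan,  # no constricted neck, no defined length
        true_neck_station=0.0,
        spec=spec,
    )
    return SurfaceMesh(verts, faces, closed=False), truth


# ---------------------------------------------------------------------------
# NE sheets and nuclear masks
# ---------------------------------------------------------------------------

def make_ne_sheet(
    length_um: float,
    depth_um: float,
    curvature: float = 0.0,
    contour_spacing_nm: float = 10.0,
    points_per_contour: int = 64,
) -> ContourStack:
    """Traced NE sheet as an open-contour stack.

    Each contour is the NE trace on one tomographic plane: a polyline of arc
    length ``length_um`` (straight for ``curvature == 0``, an arc of radius
    ``1/curvature`` um otherwise), repeated every ``contour_spacing_nm`` along
    the tomographic axis through a depth of ``depth_um``.  The true area is
    ``length_um * depth_um`` (arc length times depth) in um^2.
    """
    if length_um <= 0 or depth_um <= 0:
        raise ValueError("length and depth must be > 0")
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    length_nm = length_um * 1000.0
    depth_nm = depth_um * 1000.0
    n_contours = max(2, int(np.round(depth_nm / contour_spacing_nm)) + 1)
    z_spacing = depth_nm / (n_contours - 1)
    t = np.linspace(0.0, 1.0, points_per_contour)
    if curvature == 0.0:
        xy = np.column_stack([t * length_nm, np.zeros_like(t)])
    else:
        radius_nm = 1000.0 / curvature
        phi = t * length_nm / radius_nm  # arc length parametrization
        xy = np.column_stack(
            [radius_nm * np.sin(phi), radius_nm * (1.0 - np.cos(phi))]
        )
    contours = [
        Contour(object_id=1, contour_id=k, z_index=k, points=xy.copy(), closed=False)
        for k in range(n_contours)
    ]
    return ContourStack(contours, z_spacing=z_spacing)


def make_nuclear_mask(
    semi_axes_um: tuple[float, float, float] | float,
    voxel_nm: tuple[float, float, float] | float,
    seed: int = 0,
) -> VoxelMask:
    """Solid ellipsoidal nucleus as a binary voxel mask.

    The ellipsoid centre is jittered by up to half a voxel (seeded) so the
    discretization is not grid-aligned.  Voxels may be anisotropic, as in
    FIB-SEM stacks (e.g. 4.0 x 4.0 x 3.4 nm); here the default scale is the
    coarser one used for whole-nucleus masks.
    """
    if np.isscalar(semi_axes_um):
        semi_axes_um = (semi_axes_um,) * 3
    if np.isscalar(voxel_nm):
        voxel_nm = (voxel_nm,) * 3
    semi_nm = np.asarray(semi_axes_um, dtype=float) * 1000.0
    voxel = np.asarray(voxel_nm, dtype=float)
    if (voxel <= 0).any():
        raise ValueError("voxel size must be > 0")
    if (semi_nm <= voxel).any():
        raise ValueError("semi-axes must exceed the voxel size")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.5, 0.5, size=3) * voxel
    shape = np.ceil(2 * semi_nm / voxel).astype(int) + 4
    center = shape * voxel / 2.0 + jitter
    zi, yi, xi = np.ogrid[: shape[0], : shape[1], : shape[2]]
    # voxel centres in nm; axis order (z, y, x) with voxel = (vz, vy, vx)
    z = (zi + 0.5) * voxel[0] - center[0]
    y = (yi + 0.5) * voxel[1] - center[1]
    x = (xi + 0.5) * voxel[2] - center[2]
    inside = (
        (x / semi_nm[0]) ** 2 + (y / semi_nm[1]) ** 2 + (z / semi_nm[2]) ** 2
    ) <= 1.0
    return VoxelMask(data=inside, voxel_size=(voxel[0], voxel[1], voxel[2]))


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _truncated_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator, lower: float = 2.0
) -> np.ndarray:
    if sd == 0:
        return np.full(n, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def sample_population(pop: PopulationSpec) -> Scene:
    """Generate a junction population on an NE sheet with ground truth.

    Neck diameters are drawn per lumen class from the truncated normals in
    the population spec; junctions are placed uniformly at random on a square
    sheet of the requested area with their axes normal to the sheet.  The
    scene is a pure function of the population spec (seeded).
    """
    rng = np.random.default_rng(pop.seed)
    side_nm = np.sqrt(pop.scene_area_um2) * 1000.0
    classes = list(pop.class_mix.keys())
    probs = np.array([pop.class_mix[c] for c in classes])
    meshes: list[SurfaceMesh] = []
    annotations: list[JunctionAnnotation] = []
    truths: list[GroundTruth] = []
    draw_classes = rng.choice(len(classes), size=pop.n_junctions, p=probs)
    for i in range(pop.n_junctions):
        cls = classes[draw_classes[i]]
        if cls is LumenClass.NO_LUMEN:
            d = _truncated_normal(pop.no_lumen_width_mean, pop.no_lumen_width_sd, 1, rng)[0]
        else:
            d = _truncated_normal(pop.width_mean, pop.width_sd, 1, rng)[0]
        spec = SyntheticJunctionSpec(
            neck_diameter=float(d),
            jitter_sd=pop.jitter_sd,
            mesh_step=pop.mesh_step,
            lumen_class=cls,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mesh, truth = make_hourglass(spec)
        base = np.array(
            [rng.uniform(0, side_nm), rng.uniform(0, side_nm), 0.0]
        )
        mesh = SurfaceMesh(mesh.vertices + base, mesh.faces, closed=mesh.closed)
        meshes.append(mesh)
        annotations.append(
            JunctionAnnotation(
                junction_id=f"j{i:03d}",
                base_point=base,
                axis_hint=np.array([0.0, 0.0, 1.0]),
                lumen_class=cls,
            )
        )
        truths.append(truth)
    side_um = side_nm / 1000.0
    ne_stack = make_ne_sheet(length_um=side_um, depth_um=side_um,
                             contour_spacing_nm=max(10.0, side_nm / 50.0))
    return Scene(
        meshes=meshes,
        annotations=annotations,
        ground_truths=truths,
        ne_stack=ne_stack,
        scene_area_um2=pop.scene_area_um2,
    )
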