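"""NE surface area, junction frequency, and per-nucleus extrapolation.

Junction abundance is the count of annotated junctions divided by the
screened NE surface area.  The area comes from one of two routes — a
triangulated mesh of the traced NE, or the sum of length x depth products of
near-flat NE regions — which agree to within a few percent on flat envelopes
and thereby cross-validate each other.  Multiplying a frequency by a typical
nucleus' total NE area (400 um^2 in early telophase, 800 um^2 in interphase)
extrapolates to junctions per nucleus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .junction_morphometry import JunctionAnnotation, LumenClass
from .mesh_model import ContourStack, contours_to_mesh, surface_area

__all__ = [
    "AreaMethod",
    "NEAreaEstimate",
    "FrequencyEstimate",
    "area_from_mesh",
    "area_from_length_depth",
    "compare_area_methods",
    "junction_frequency",
    "estimate_total",
    "deduplicate_junctions",
    "compare_widths",
    "round_frequency",
    "round_one_sig_fig",
    "TOTAL_NE_AREA_UM2",
]

# total NE surface of an average nucleus, um^2 (light-microscopy derived)
TOTAL_NE_AREA_UM2 = {"telophase": 400.0, "interphase": 800.0}


class AreaMethod(str, Enum):
    MESH = "mesh"
    LENGTH_X_DEPTH = "length_x_depth"


@dataclass
class NEAreaEstimate:
    """Screened NE surface area in um^2 and how it was obtained."""

    area_um2: float
    method: AreaMethod
    components: list[tuple[float, float]] | None = None  # (length_um, depth_um)

    def __post_init__(self) -> None:
        self.method = AreaMethod(self.method)
        if self.area_um2 <= 0:
            raise ValueError("area must be > 0")
        if self.method is AreaMethod.LENGTH_X_DEPTH and self.components:
            total = sum(l * d for l, d in self.components)
            if not math.isclose(total, self.area_um2, rel_tol=1e-9):
                raise ValueError("area must equal sum of length x depth components")


@dataclass
class FrequencyEstimate:
    """Junction counts over a screened area and the derived frequency.

    ``frequency_per_um2`` is the unrounded total-count frequency; rounding
    happens only at report time.  ``reported`` carries the two-decimal
    round-half-even value and ``reported_truncated`` the truncate-to-two-
    decimals variant, so either printing convention is auditable.
    """

    counts: dict[LumenClass, int]
    area_um2: float
    frequency_per_um2: float
    per_class_frequency: dict[LumenClass, float]
    reported: float
    reported_truncated: float
    total_ne_area_um2: float | None = None
    estimated_total: float | None = None

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def area_from_mesh(
    ne_contours: ContourStack, interpolate_every: float | None = None
) -> NEAreaEstimate:
    """NE area from stitching the traced NE contours into a mesh, um^2."""
    if len(ne_contours.contours) < 2:
        raise ValueError("need >= 2 NE contours to build a mesh")
    mesh = contours_to_mesh(ne_contours, interpolate_every=interpolate_every)
    area_nm2 = surface_area(mesh)
    return NEAreaEstimate(area_um2=area_nm2 / 1e6, method=AreaMethod.MESH)


def area_from_length_depth(
    components: list[tuple[float, float]]
) -> NEAreaEstimate:
    """NE area as the sum of per-region length x depth products (um^2).

    Each component is the traced NE length of a region in a 2D overview and
    the depth of that region along the tomographic axis, both in um.
    """
    if not components:
        raise ValueError("need at least one (length, depth) component")
    for l, d in components:
        if l <= 0 or d <= 0:
            raise ValueError("lengths and depths must be > 0")
    area = float(sum(l * d for l, d in components))
    return NEAreaEstimate(
        area_um2=area,
        method=AreaMethod.LENGTH_X_DEPTH,
        components=[(float(l), float(d)) for l, d in components],
    )


def compare_area_methods(a: NEAreaEstimate, b: NEAreaEstimate) -> float:
    """Relative difference |a-b| / mean(a, b) between two area estimates."""
    mean = 0.5 * (a.area_um2 + b.area_um2)
    return abs(a.area_um2 - b.area_um2) / mean


def deduplicate_junctions(
    annotations: list[JunctionAnnotation], min_separation: float = 50.0
) -> list[JunctionAnnotation]:
    """Merge junction records closer than ``min_separation`` nm.

    Overlapping tomograms can record the same junction twice; records within
    the separation threshold are treated as one (the first kept).  Idempotent.
    """
    kept: list[JunctionAnnotation] = []
    for ann in annotations:
        if all(
            np.linalg.norm(ann.base_point - k.base_point) >= min_separation
            for k in kept
        ):
            kept.append(ann)
    return kept


def round_frequency(freq: float) -> float:
    """Report a frequency to two decimals, round-half-even."""
    return float(round(freq, 2))


def truncate_frequency(freq: float) -> float:
    """Truncate a frequency to two decimals (floor toward zero)."""
    return math.trunc(freq * 100) / 100.0


def round_one_sig_fig(x: float) -> float:
    """Round to one significant figure (per-nucleus totals)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return float(round(x, -exp))


def junction_frequency(
    annotations: list[JunctionAnnotation],
    area: NEAreaEstimate,
    deduplicate: bool = True,
    min_separation: float = 50.0,
) -> FrequencyEstimate:
    """Junction frequency per um^2 of screened NE, total and per class.

    Ambiguous-class junctions count toward the all-junction total but are
    also tallied separately; contact sites are tallied but never enter
    morphometry.  Frequencies are kept unrounded; two-decimal reported values
    (round-half-even and truncated) accompany them.
    """
    if area.area_um2 <= 0:
        raise ValueError("area must be > 0")
    if deduplicate:
        annotations = deduplicate_junctions(annotations, min_separation)
    counts: dict[LumenClass, int] = {}
    for ann in annotations:
        counts[ann.lumen_class] = counts.get(ann.lumen_class, 0) + 1
    n_total = sum(counts.values())
    freq = n_total / area.area_um2
    per_class = {cls: n / area.area_um2 for cls, n in counts.items()}
    return FrequencyEstimate(
        counts=counts,
        area_um2=area.area_um2,
        frequency_per_um2=freq,
        per_class_frequency=per_class,
        reported=round_frequency(freq),
        reported_truncated=truncate_frequency(freq),
    )


def estimate_total(
    freq: FrequencyEstimate,
    total_ne_area_um2: float,
    use_reported: bool = False,
) -> tuple[float, float]:
    """Extrapolate a frequency to junctions per nucleus.

    Multiplies the frequency by the total NE area of an average nucleus.
    Returns ``(unrounded, one_sig_fig)``; an estimate from n junctions over
    area A extrapolated back to A returns n exactly before rounding.  With
    ``use_reported`` the two-decimal truncated frequency is multiplied
    instead, reproducing published-figure arithmetic that starts from the
    printed frequency.
    """
    if total_ne_area_um2 <= 0:
        raise ValueError("total NE area must be > 0")
    base = freq.reported_truncated if use_reported else freq.frequency_per_um2
    est = base * total_ne_area_um2
    freq.total_ne_area_um2 = total_ne_area_um2
    freq.estimated_total = est
    return est, round_one_sig_fig(est)


def compare_widths(
    group_a: "np.ndarray | list[float]", group_b: "np.ndarray | list[float]"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two width samples.

    Thin wrapper over the standard rank-sum routine; warns when either group
    has fewer than 3 observations (the test is then uninformative).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        warnings.warn("group with n < 3: Mann-Whitney test is uninformative",
                      stacklevel=2)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
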