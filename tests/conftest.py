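"""Shared geometry fixtures built analytically (no binary data)."""

from __future__ import annotations

import numpy as np
import pytest

from junctshape.mesh_model import SurfaceMesh


def tube_along_centreline(
    centreline: np.ndarray, radius: float, n_theta: int = 64
) -> SurfaceMesh:
    """Tube of constant circular cross-section swept along a polyline.

    Rings are placed perpendicular to the local tangent with a
    parallel-transported frame, so cross-sections normal to the centreline
    are exact circles of the given radius everywhere.
    """
    pts = np.asarray(centreline, dtype=float)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # parallel transport an initial normal frame along the polyline
    t0 = tangents[0]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t0, helper)
    u /= np.linalg.norm(u)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = []
    for k, (p, t) in enumerate(zip(pts, tangents)):
        if k > 0:
            # rotate u to stay perpendicular to the new tangent
            u = u - (u @ t) * t
            u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ring = p + radius * (
            np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
        )
        rings.append(ring)
    verts = np.vstack(rings)
    faces = []
    for k in range(len(pts) - 1):
        a, b = k * n_theta, (k + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    return SurfaceMesh(verts, np.asarray(faces))


@pytest.fixture
def elbow_tube() -> tuple[SurfaceMesh, float]:
    """90-degree elbow: straight 5 nm, then a quarter turn of radius 40 nm.

    Tube radius 10 nm; returns (mesh, tube_radius).  The centreline starts at
    the origin heading +z and ends heading +x.
    """
    radius, bend = 10.0, 40.0
    straight = np.column_stack(
        [np.zeros(6), np.zeros(6), np.linspace(0, 5, 6)]
    )
    phi = np.linspace(0, np.pi / 2, 60)[1:]
    arc = np.column_stack(
        [bend * (1 - np.cos(phi)), np.zeros(len(phi)), 5 + bend * np.sin(phi)]
    )
    centre = np.vstack([straight, arc])
    return tube_along_centreline(centre, radius), radius


@pytest.fixture
def straight_cylinder() -> tuple[SurfaceMesh, float]:
    """Open cylinder of radius 25 nm along +z, length 60 nm."""
    z = np.linspace(0, 60, 40)
    centre = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return tube_along_centreline(centre, 25.0), 25.0
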