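"""Deterministic analytic test shapes with closed-form morphometrics.

These fixtures stand in for EM-reconstructed cell morphologies: boxes,
polygonal cylinders/cones, UV spheres, varying-radius tubes emulating an
astrocytic nanoprocess, and stacked contour-ring point clouds of the
kind produced by serial-section reconstructions.

The oracles used in tests are the *polygonal* closed forms (e.g. an
n-gon prism has volume ``(n/2)·r²·sin(2π/n)·h``), which are exact for
the generated tessellation — no discretisation slack is needed in
equality assertions.  All generators are deterministic: identical
parameters give bit-identical vertices.
"""

from __future__ import annotations

import numpy as np

from .cloud import PointCloud
from .core import TriMesh, axis_index
from .errors import RemorphError


def polygon_area(n_sides: int, radius: float) -> float:
    """Area of a regular n-gon with circumradius r: (n/2)·r²·sin(2π/n)."""
    return 0.5 * n_sides * radius**2 * np.sin(2 * np.pi / n_sides)


def make_box(extents=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> TriMesh:
    """Axis-aligned box as 12 outward-wound triangles.

    Surface area ``2(ab+bc+ca)``, volume ``abc``.
    """
    e = np.asarray(extents, dtype=float)
    if np.any(e <= 0):
        raise RemorphError("box extents must be positive")
    o = np.asarray(origin, dtype=float)
    corners = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    verts = o + corners * e
    # index bits: x*4 + y*2 + z; quads wound outward, fan-split
    quads = [
        (0, 1, 3, 2),  # x = 0
        (4, 6, 7, 5),  # x = 1
        (0, 4, 5, 1),  # y = 0
        (2, 3, 7, 6),  # y = 1
        (0, 2, 6, 4),  # z = 0
        (1, 5, 7, 3),  # z = 1
    ]
    faces = []
    for a, b, c, d in quads:
        faces.append((a, b, c))
        faces.append((a, c, d))
    return TriMesh(verts, faces)


def _ring(radius: float, z: float, n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)])


def make_cylinder(
    radius: float, height: float, n_sides: int = 64, capped: bool = True
) -> TriMesh:
    """Polygonal cylinder along z, base at z=0.

    Closed forms: lateral area ``2·n·r·sin(π/n)·h``, cap area
    ``(n/2)·r²·sin(2π/n)``, volume ``cap area × h``.
    """
    if n_sides < 3:
        raise RemorphError("a cylinder needs at least 3 sides")
    if radius <= 0 or height <= 0:
        raise RemorphError("radius and height must be positive")
    n = n_sides
    verts = [_ring(radius, 0.0, n), _ring(radius, height, n)]
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        # bottom ring 0..n-1, top ring n..2n-1; outward winding
        faces.append((k, k2, n + k2))
        faces.append((k, n + k2, n + k))
    nv = 2 * n
    if capped:
        verts.append(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, height]]))
        cb, ct = nv, nv + 1
        for k in range(n):
            k2 = (k + 1) % n
            faces.append((cb, k2, k))  # bottom, outward -z
            faces.append((ct, n + k, n + k2))  # top, outward +z
    return TriMesh(np.concatenate(verts), faces)


def make_cone(base_radius: float, height: float, n_sides: int = 64) -> TriMesh:
    """Polygonal cone: base n-gon at z=0, apex at (0,0,h).

    Volume is the pyramid closed form ``(1/3)·base polygon area·h``.
    """
    if n_sides < 3:
        raise RemorphError("a cone needs at least 3 sides")
    if base_radius <= 0 or height <= 0:
        raise RemorphError("radius and height must be positive")
    n = n_sides
    verts = np.concatenate(
        [_ring(base_radius, 0.0, n), [[0.0, 0.0, 0.0], [0.0, 0.0, height]]]
    )
    cb, apex = n, n + 1
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        faces.append((k, k2, apex))  # lateral, outward
        faces.append((cb, k2, k))  # base, outward -z
    return TriMesh(verts, faces)


def make_uv_sphere(radius: float = 1.0, n_u: int = 64, n_v: int = 32) -> TriMesh:
    """Latitude/longitude sphere: n_u meridians, n_v latitude bands.

    Watertight; SA → 4πr² and V → (4/3)πr³ as the tessellation refines
    (within 1% at 64×32).
    """
    if radius <= 0:
        raise RemorphError("radius must be positive")
    if n_u < 3 or n_v < 2:
        raise RemorphError("need n_u >= 3 meridians and n_v >= 2 bands")
    verts = [np.array([[0.0, 0.0, -radius]])]
    for i in range(1, n_v):
        phi = -np.pi / 2 + np.pi * i / n_v
        verts.append(_ring(radius * np.cos(phi), radius * np.sin(phi), n_u))
    verts.append(np.array([[0.0, 0.0, radius]]))
    south, north = 0, 1 + (n_v - 1) * n_u

    def rv(i, k):  # ring vertex index (ring i = 1..n_v-1)
        return 1 + (i - 1) * n_u + (k % n_u)

    faces = []
    for k in range(n_u):
        faces.append((south, rv(1, k + 1), rv(1, k)))
    for i in range(1, n_v - 1):
        for k in range(n_u):
            a, b = rv(i, k), rv(i, k + 1)
            c, d = rv(i + 1, k + 1), rv(i + 1, k)
            faces.append((a, b, c))
            faces.append((a, c, d))
    for k in range(n_u):
        faces.append((north, rv(n_v - 1, k), rv(n_v - 1, k + 1)))
    return TriMesh(np.concatenate(verts), faces)


def make_tube(
    radius_profile,
    height: float = 10.0,
    n_sides: int = 64,
    n_stations: int = 64,
    capped: bool = True,
) -> TriMesh:
    """Varying-radius tube along z (a nanoprocess-like shape).

    ``radius_profile`` maps z ∈ [0, height] to a positive radius; it may
    also be a sequence of per-station radii (length ``n_stations``).
    Stations are evenly spaced from z=0 to z=height inclusive.
    """
    if n_sides < 3 or n_stations < 2:
        raise RemorphError("need at least 3 sides and 2 stations")
    zs = np.linspace(0.0, height, n_stations)
    if callable(radius_profile):
        radii = np.array([float(radius_profile(z)) for z in zs])
    else:
        radii = np.asarray(radius_profile, dtype=float)
        if len(radii) != n_stations:
            raise RemorphError("radius profile length must equal n_stations")
    if np.any(radii <= 0):
        raise RemorphError("tube radii must be positive")
    verts = [_ring(r, z, n_sides) for r, z in zip(radii, zs)]
    n = n_sides
    faces = []
    for i in range(n_stations - 1):
        lo, hi = i * n, (i + 1) * n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append((lo + k, lo + k2, hi + k2))
            faces.append((lo + k, hi + k2, hi + k))
    nv = n_stations * n
    if capped:
        verts.append(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, height]]))
        cb, ct = nv, nv + 1
        top = (n_stations - 1) * n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append((cb, k2, k))
            faces.append((ct, top + k, top + k2))
    return TriMesh(np.concatenate(verts), faces)


def default_nanoprocess_radius(z: float, height: float = 10.0) -> float:
    """Gaussian bulge on a thin neck, mimicking a varicose nanoprocess."""
    return 0.3 + 0.7 * np.exp(-((z - height / 2) ** 2) / (2 * (height / 8) ** 2))


def make_nanoprocess_cloud(
    n_stations: int = 20,
    points_per_loop: int = 24,
    radius_profile=None,
    axis="z",
    height: float = 10.0,
) -> PointCloud:
    """Stacked circular contour loops with radius varying along the axis.

    Emulates a serial-section surface point cloud of a nanoprocess:
    each station is one exactly coplanar ring of points.  Deterministic
    given its parameters.
    """
    if n_stations < 1 or points_per_loop < 3:
        raise RemorphError("need n_stations >= 1 and points_per_loop >= 3")
    ax = axis_index(axis)
    if radius_profile is None:
        radius_profile = lambda z: default_nanoprocess_radius(z, height)  # noqa: E731
    zs = np.linspace(0.0, height, n_stations) if n_stations > 1 else np.array([0.0])
    pts = []
    labels = []
    for i, z in enumerate(zs):
        r = float(radius_profile(z)) if callable(radius_profile) else radius_profile[i]
        ring = _ring(r, z, points_per_loop)
        if ax != 2:  # rings are built in the xy-plane; roll into place
            ring = np.roll(ring, ax + 1, axis=1)
        pts.append(ring)
        labels.extend([(ax, i)] * points_per_loop)
    return PointCloud(np.concatenate(pts), labels=np.array(labels, dtype=np.int64))


def make_two_component(separation: float = 10.0) -> TriMesh:
    """Two disjoint unit cubes ``separation`` apart along x."""
    from .core import merge

    a = make_box()
    b = make_box(origin=(separation, 0.0, 0.0))
    return merge([a, b])
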