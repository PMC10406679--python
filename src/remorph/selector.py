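"""Extracting sub-structures (nanoprocesses) from clouds and meshes.

A programmatic region (axis-aligned box or sphere) replaces interactive
viewport selection.  Point clouds are filtered point-wise; meshes use an
all-vertices-in rule — a face is selected when all three of its vertices
lie inside (or on the boundary of) the region, so selected geometry is
saved unmodified, mirroring vertex-based selection in mesh editors.

Morphometrics of a mesh selection are computed automatically.  Selected
pieces are generally open surfaces, so the enclosed volume is recovered,
when possible, by capping each boundary loop with a centroid fan —
accepted only when the loop is planar to within 1% of its diameter —
and is flagged as capped in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._section import chain_loops
from .cloud import PointCloud
from .core import (
    Morphometrics,
    TriMesh,
    _directed_edges,
    _face_components,
    enclosed_volume,
    is_watertight,
    measure,
    submesh,
)
from .errors import EmptySelectionError, EmptyMeshError, RemorphError


@dataclass
class SelectionRegion:
    """Axis-aligned box or sphere; ``grow_connectivity`` (meshes only)
    expands a selection to whole edge-connected components it touches."""

    kind: str  # "box" | "sphere"
    box_min: np.ndarray | None = None
    box_max: np.ndarray | None = None
    center: np.ndarray | None = None
    radius: float | None = None
    grow_connectivity: bool = False

    def __post_init__(self):
        if self.kind == "box":
            self.box_min = np.asarray(self.box_min, dtype=float).reshape(3)
            self.box_max = np.asarray(self.box_max, dtype=float).reshape(3)
            if np.any(self.box_min > self.box_max):
                raise RemorphError("box min must not exceed max")
        elif self.kind == "sphere":
            self.center = np.asarray(self.center, dtype=float).reshape(3)
            self.radius = float(self.radius)
            if self.radius <= 0:
                raise RemorphError("sphere radius must be positive")
        else:
            raise RemorphError(f"unknown region kind {self.kind!r}")

    @classmethod
    def box(cls, box_min, box_max, grow_connectivity: bool = False):
        return cls("box", box_min=box_min, box_max=box_max,
                   grow_connectivity=grow_connectivity)

    @classmethod
    def sphere(cls, center, radius, grow_connectivity: bool = False):
        return cls("sphere", center=center, radius=radius,
                   grow_connectivity=grow_connectivity)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: inside or on the region boundary."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.kind == "box":
            return np.all(
                (points >= self.box_min) & (points <= self.box_max), axis=1
            )
        d2 = np.einsum("ij,ij->i", points - self.center, points - self.center)
        return d2 <= self.radius**2


def select_points(
    cloud: PointCloud, region: SelectionRegion
) -> tuple[PointCloud, PointCloud]:
    """Split a cloud into (selected, remainder); order and labels kept."""
    if cloud.is_empty:
        raise EmptyMeshError("cannot select from an empty point cloud")
    mask = region.contains(cloud.points)
    if not mask.any():
        raise EmptySelectionError(
            "selection region contains no points; enlarge or move the region"
        )
    return cloud.subset(mask), cloud.subset(~mask)


def _boundary_loops(mesh: TriMesh) -> list[list[int]]:
    """Vertex loops of edges used by exactly one face."""
    de = _directed_edges(mesh.faces)
    und = np.sort(de, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    loops, _chains = chain_loops([(int(a), int(b)) for a, b in boundary])
    return [lp for lp in loops if len(lp) >= 3]


def _cap_boundary_loops(mesh: TriMesh, planarity_rel: float = 0.01) -> TriMesh | None:
    """Cap planar boundary loops with centroid fans; None if not cappable.

    A loop qualifies when its best-fit plane fits within
    ``planarity_rel`` of the loop's diameter.  Fan orientation is taken
    from the loop's traversal so the directed-edge manifold condition
    holds against the open shell.
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return None
    # directed boundary edges as used by the shell, for orientation
    de = set(map(tuple, _directed_edges(mesh.faces).tolist()))
    verts = mesh.vertices
    new_verts = [verts]
    new_faces = [mesh.faces]
    nv = mesh.n_vertices
    for lp in loops:
        pts = verts[np.array(lp)]
        centroid = pts.mean(axis=0)
        q = pts - centroid
        # planarity via smallest singular value of the centred loop
        _u, s, vt = np.linalg.svd(q, full_matrices=False)
        diam = float(np.ptp(pts, axis=0).max())
        if diam <= 0 or s[-1] > planarity_rel * diam:
            return None
        # orient the fan so its directed edges oppose the shell's
        a, b = lp[0], lp[1]
        seq = lp if (a, b) in de else lp[::-1]
        ci = nv
        nv += 1
        new_verts.append(centroid.reshape(1, 3))
        fan = []
        for k in range(len(seq)):
            p, q2 = seq[k], seq[(k + 1) % len(seq)]
            fan.append((ci, q2, p))
        new_faces.append(np.array(fan, dtype=np.int64))
    return TriMesh(np.concatenate(new_verts), np.concatenate(new_faces))


def select_submesh(
    mesh: TriMesh, region: SelectionRegion
) -> tuple[TriMesh, TriMesh, Morphometrics]:
    """Extract the faces whose vertices all lie in the region.

    Returns (selected, remainder, morphometrics-of-selected).  With
    ``region.grow_connectivity`` the selection is expanded to every
    edge-connected component that the region touches.  The face
    partition is exact: selected + remainder = input, disjoint.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot select from an empty mesh")
    vin = region.contains(mesh.vertices)
    fmask = np.all(vin[mesh.faces], axis=1)
    if region.grow_connectivity and fmask.any():
        grown = fmask.copy()
        for comp in _face_components(mesh.faces):
            if fmask[comp].any():
                grown[comp] = True
        fmask = grown
    if not fmask.any():
        raise EmptySelectionError(
            "selection region contains no whole face; enlarge or move the region"
        )
    sel = submesh(mesh, np.flatnonzero(fmask))
    rem = (
        submesh(mesh, np.flatnonzero(~fmask))
        if (~fmask).any()
        else TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
    )
    morph = measure(sel)
    if morph.volume is None:
        capped = _cap_boundary_loops(sel)
        if capped is not None and is_watertight(capped):
            morph.volume = enclosed_volume(capped)
            morph.capped = True
    return sel, rem, morph
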