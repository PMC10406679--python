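"""Plane–mesh intersection machinery.

Shared kernel for the slicer (splitting with optional cap triangulation,
cumulative area/volume below a plane) and the transformer (cross-section
circumvent extraction).  All cuts are axis-aligned planes.

Crossing triangles are clipped with Sutherland–Hodgman against the
half-space; intersection points are cached per undirected mesh edge so
the two sides share vertices exactly and area is conserved bitwise.
Vertices within a small tolerance of the plane are snapped onto it and
belong to both pieces' boundary.
"""

from __future__ import annotations

import numpy as np

from ._earclip import triangulate_loops
from .core import TriMesh, axis_index, signed_volume
from .errors import SliceError

# snap tolerance relative to the axis extent
_SNAP_REL = 1e-9


def _plane_frame(ax: int) -> tuple[int, int]:
    """In-plane 2D axes (u, v) such that u × v points along +axis."""
    return (ax + 1) % 3, (ax + 2) % 3


def _signs(vals: np.ndarray, eps: float) -> np.ndarray:
    s = np.zeros(len(vals), dtype=np.int8)
    s[vals > eps] = 1
    s[vals < -eps] = -1
    return s


class _Clipper:
    """Clips crossing faces against the plane ``coord[axis] == c``.

    Maintains a registry of intersection vertices keyed by undirected
    mesh edge, appended after the original vertices, so both half-meshes
    and the cap share vertex indices.
    """

    def __init__(self, mesh: TriMesh, ax: int, c: float, eps: float):
        self.mesh = mesh
        self.ax = ax
        self.c = c
        self.eps = eps
        self.new_vertices: list[np.ndarray] = []
        self._edge_cache: dict[tuple[int, int], int] = {}
        self._n0 = mesh.n_vertices
        d = mesh.vertices[:, ax] - c
        self.d = d
        self.sign = _signs(d, eps)

    def _cut_edge(self, i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = self._edge_cache.get(key)
        if idx is None:
            vi, vj = self.mesh.vertices[i], self.mesh.vertices[j]
            t = self.d[i] / (self.d[i] - self.d[j])
            p = vi + t * (vj - vi)
            p[self.ax] = self.c  # exact
            idx = self._n0 + len(self.new_vertices)
            self.new_vertices.append(p)
            self._edge_cache[key] = idx
        return idx

    def clip_face(self, face) -> tuple[list[int], list[int], list[tuple[int, int]]]:
        """Clip one crossing triangle.

        Returns (lower polygon, upper polygon, cut segments) as vertex
        index lists; each polygon preserves the face's winding.  The cut
        segment is directed as traversed by the *lower* polygon.
        """
        idxs = list(face)
        sg = [int(self.sign[i]) for i in idxs]
        lower: list[int] = []
        upper: list[int] = []
        for k in range(3):
            i, j = idxs[k], idxs[(k + 1) % 3]
            si, sj = sg[k], sg[(k + 1) % 3]
            if si <= 0:
                lower.append(i)
            if si >= 0:
                upper.append(i)
            if si * sj == -1:
                x = self._cut_edge(i, j)
                lower.append(x)
                upper.append(x)
        # on-plane vertices of the lower polygon, in traversal order
        cut = [v for v in lower if self._on_plane(v)]
        segs = []
        if len(cut) == 2:
            segs.append((cut[0], cut[1]))
        return lower, upper, segs

    def _on_plane(self, v: int) -> bool:
        if v >= self._n0:
            return True
        return self.sign[v] == 0

    def all_vertices(self) -> np.ndarray:
        if not self.new_vertices:
            return self.mesh.vertices
        return np.concatenate([self.mesh.vertices, np.array(self.new_vertices)])


def _fan(poly: list[int]) -> list[tuple[int, int, int]]:
    return [(poly[0], poly[k], poly[k + 1]) for k in range(1, len(poly) - 1)]


def _poly_area(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    v0 = pts[0]
    cr = np.cross(pts[1:-1] - v0, pts[2:] - v0)
    return 0.5 * float(np.linalg.norm(cr.sum(axis=0)))


def chain_loops(segments) -> tuple[list[list], list[list]]:
    """Chain undirected segments into closed loops and open chains.

    ``segments``: iterable of (key_a, key_b).  Returns (loops, chains)
    as lists of key sequences; loops omit the repeated first key.
    Deterministic: traversal starts from the smallest key.
    """
    adj: dict = {}
    seen = set()
    for a, b in segments:
        k = (a, b) if a <= b else (b, a)
        if a == b or k in seen:
            continue
        seen.add(k)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for nbrs in adj.values():
        nbrs.sort()
    visited_edges = set()
    loops, chains = [], []

    def walk(start, first):
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        while True:
            cur, prev = path[-1], path[-2]
            nxt = None
            for cand in adj[cur]:
                if cand != prev or adj[cur].count(prev) > 1:
                    e = frozenset((cur, cand))
                    if e not in visited_edges:
                        nxt = cand
                        break
            if nxt is None:
                return path, False
            visited_edges.add(frozenset((cur, nxt)))
            if nxt == start:
                return path, True
            path.append(nxt)

    # open chains first (endpoints of odd degree), then cycles
    for start in sorted(adj, key=repr):
        if len(adj[start]) == 1:
            for first in adj[start]:
                if frozenset((start, first)) not in visited_edges:
                    path, closed = walk(start, first)
                    chains.append(path)
    for start in sorted(adj, key=repr):
        for first in adj[start]:
            if frozenset((start, first)) not in visited_edges:
                path, closed = walk(start, first)
                (loops if closed else chains).append(path)
    return loops, chains


def _in_plane_edge_segments(faces: np.ndarray, sign: np.ndarray):
    """Cut segments from face edges lying exactly in the plane.

    A plane passing through a vertex ring produces no crossing faces;
    the cross-section boundary is then made of whole mesh edges whose
    two endpoints are on the plane while the face's third vertex is not.
    """
    fsign = sign[faces]
    two_zero = (np.sum(fsign == 0, axis=1) == 2) & np.any(fsign != 0, axis=1)
    segs = []
    for f, s in zip(faces[np.flatnonzero(two_zero)], fsign[two_zero]):
        zs = [int(v) for v, sv in zip(f, s) if sv == 0]
        segs.append((zs[0], zs[1]))
    return segs


def split_with_info(
    mesh: TriMesh,
    axis,
    c: float,
    cap: bool,
    face_flags: np.ndarray | None = None,
):
    """Split a mesh by the plane ``coord[axis] == c``.

    Returns ``(lower, upper, lower_flags, upper_flags)`` where the flag
    arrays mark cap faces (inherited flags of split faces propagate; new
    cap faces are flagged True).  Zero-area fragments are dropped.
    """
    ax = axis_index(axis)
    lo = float(mesh.vertices[:, ax].min())
    hi = float(mesh.vertices[:, ax].max())
    if not (lo < c < hi):
        raise SliceError(
            f"cut coordinate {c} is not strictly inside the axis extent [{lo}, {hi}]"
        )
    eps = _SNAP_REL * max(hi - lo, 1.0)
    if face_flags is None:
        face_flags = np.zeros(mesh.n_faces, dtype=bool)

    clip = _Clipper(mesh, ax, c, eps)
    fsign = clip.sign[mesh.faces]
    all_le = np.all(fsign <= 0, axis=1)
    all_ge = np.all(fsign >= 0, axis=1)
    coplanar = np.all(fsign == 0, axis=1)
    lower_whole = np.flatnonzero(all_le)  # coplanar faces go to the lower piece
    upper_whole = np.flatnonzero(all_ge & ~coplanar & ~all_le)
    crossing = np.flatnonzero(~all_le & ~all_ge)

    lower_faces = [tuple(f) for f in mesh.faces[lower_whole]]
    lower_fl = list(face_flags[lower_whole])
    upper_faces = [tuple(f) for f in mesh.faces[upper_whole]]
    upper_fl = list(face_flags[upper_whole])
    cut_segments: list[tuple[int, int]] = []
    for fi in crossing:
        lp, up, segs = clip.clip_face(mesh.faces[fi])
        for t in _fan(lp):
            lower_faces.append(t)
            lower_fl.append(bool(face_flags[fi]))
        for t in _fan(up):
            upper_faces.append(t)
            upper_fl.append(bool(face_flags[fi]))
        cut_segments.extend(segs)
    if cap:
        cut_segments.extend(_in_plane_edge_segments(mesh.faces, clip.sign))

    verts = clip.all_vertices()
    if cap and cut_segments:
        loops, _chains = chain_loops(cut_segments)
        loops = [lp for lp in loops if len(lp) >= 3]
        if loops:
            u, v = _plane_frame(ax)
            pts2 = [verts[np.array(lp)][:, [u, v]] for lp in loops]
            tris = triangulate_loops(pts2, [list(map(int, lp)) for lp in loops])
            for t in tris:
                lower_faces.append(t)  # CCW in (u,v) -> normal +axis, outward for lower
                lower_fl.append(True)
                upper_faces.append((t[0], t[2], t[1]))
                upper_fl.append(True)

    def build(faces, flags):
        if not faces:
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int)), np.zeros(0, bool)
        faces = np.array(faces, dtype=np.int64)
        flags = np.array(flags, dtype=bool)
        m = TriMesh(verts, faces)
        # drop degenerate fragments produced by snapping
        from .core import face_areas

        area = face_areas(m)
        distinct = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        keep = distinct & (area > (eps * eps))
        faces = faces[keep]
        flags = flags[keep]
        used, inv = np.unique(faces, return_inverse=True)
        return TriMesh(verts[used], inv.reshape(-1, 3)), flags

    lower_m, lower_flags = build(lower_faces, lower_fl)
    upper_m, upper_flags = build(upper_faces, upper_fl)
    return lower_m, upper_m, lower_flags, upper_flags


def area_below(mesh: TriMesh, axis, c: float) -> float:
    """Original-surface area at axis-coordinate ≤ c (no caps)."""
    ax = axis_index(axis)
    vals = mesh.vertices[:, ax]
    lo, hi = float(vals.min()), float(vals.max())
    if c <= lo:
        return 0.0
    from .core import face_areas, surface_area

    if c >= hi:
        return surface_area(mesh)
    eps = _SNAP_REL * max(hi - lo, 1.0)
    clip = _Clipper(mesh, ax, c, eps)
    fsign = clip.sign[mesh.faces]
    all_le = np.all(fsign <= 0, axis=1)
    all_ge = np.all(fsign >= 0, axis=1) & ~np.all(fsign == 0, axis=1) & ~all_le
    crossing = np.flatnonzero(~all_le & ~all_ge)
    areas = face_areas(mesh)
    total = float(areas[all_le].sum())
    polys = [clip.clip_face(mesh.faces[fi])[0] for fi in crossing]
    verts = clip.all_vertices()
    for lp in polys:
        total += _poly_area(verts[np.array(lp)])
    return total


def volume_below(mesh: TriMesh, axis, c: float, orient_sign: float | None = None) -> float:
    """Volume of the capped region at axis-coordinate ≤ c.

    Uses the divergence theorem with the apex placed on the cutting
    plane, so the (implicit) cap contributes nothing and no cap has to
    be built.  Requires a watertight mesh; ``orient_sign`` (the sign of
    the mesh's signed volume) can be precomputed by the caller.
    """
    ax = axis_index(axis)
    vals = mesh.vertices[:, ax]
    lo, hi = float(vals.min()), float(vals.max())
    if orient_sign is None:
        orient_sign = 1.0 if signed_volume(mesh) >= 0 else -1.0
    if c <= lo:
        return 0.0
    eps = _SNAP_REL * max(hi - lo, 1.0)
    apex = np.zeros(3)
    apex[ax] = min(c, hi)
    V = mesh.vertices
    if c >= hi:
        sel = np.arange(mesh.n_faces)
        crossing = np.zeros(0, int)
    else:
        clip = _Clipper(mesh, ax, c, eps)
        fsign = clip.sign[mesh.faces]
        all_le = np.all(fsign <= 0, axis=1)
        all_ge = np.all(fsign >= 0, axis=1) & ~np.all(fsign == 0, axis=1) & ~all_le
        crossing = np.flatnonzero(~all_le & ~all_ge)
        sel = np.flatnonzero(all_le)

    f = mesh.faces[sel]
    a = V[f[:, 0]] - apex
    b = V[f[:, 1]] - apex
    cc = V[f[:, 2]] - apex
    total = float(np.einsum("ij,ij->i", a, np.cross(b, cc)).sum() / 6.0)
    if len(crossing):
        polys = [clip.clip_face(mesh.faces[fi])[0] for fi in crossing]
        verts = clip.all_vertices()
        for lp in polys:
            pts = verts[np.array(lp)] - apex
            for k in range(1, len(pts) - 1):
                total += float(np.dot(pts[0], np.cross(pts[k], pts[k + 1]))) / 6.0
    return orient_sign * total


def section_loops(mesh: TriMesh, axis, c: float) -> list[np.ndarray]:
    """Closed cross-section polylines (circumvents) at ``coord[axis] == c``.

    Each loop is a (K, 3) array of points on the plane, ordered along
    the loop with a deterministic start and counter-clockwise in the
    plane frame.  Open chains (from non-watertight meshes) are ignored.
    """
    ax = axis_index(axis)
    vals = mesh.vertices[:, ax]
    lo, hi = float(vals.min()), float(vals.max())
    if not (lo < c < hi):
        return []
    eps = _SNAP_REL * max(hi - lo, 1.0)
    clip = _Clipper(mesh, ax, c, eps)
    fsign = clip.sign[mesh.faces]
    all_le = np.all(fsign <= 0, axis=1)
    all_ge = np.all(fsign >= 0, axis=1) & ~np.all(fsign == 0, axis=1) & ~all_le
    crossing = np.flatnonzero(~all_le & ~all_ge)
    segments = []
    for fi in crossing:
        _lp, _up, segs = clip.clip_face(mesh.faces[fi])
        segments.extend(segs)
    segments.extend(_in_plane_edge_segments(mesh.faces, clip.sign))
    loops, _chains = chain_loops(segments)
    verts = clip.all_vertices()
    u, v = _plane_frame(ax)
    out = []
    for lp in loops:
        if len(lp) < 3:
            continue
        pts = verts[np.array(lp)]
        # canonical orientation: CCW in the (u, v) frame
        x, y = pts[:, u], pts[:, v]
        sa = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if sa < 0:
            pts = pts[::-1]
        # canonical start: lexicographically smallest point
        k = int(np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))[0])
        out.append(np.roll(pts, -k, axis=0))
    return out
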