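"""Planar polygon triangulation by ear clipping, with hole support.

Used to close cross-section polygons when slicing in volume mode.  Input
loops live in a 2D frame; outer boundaries must be counter-clockwise and
holes clockwise.  Holes are merged into their enclosing outer loop with
bridge edges before clipping.  Deterministic: ties are broken by vertex
order.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import SliceError

_EPS = 1e-12


def signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _point_in_tri(p, a, b, c, eps) -> bool:
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def _segments_intersect(p1, p2, q1, q2, eps) -> bool:
    """Proper intersection test; shared endpoints do not count."""
    d1 = _cross(q1, q2, p1)
    d2 = _cross(q1, q2, p2)
    d3 = _cross(p1, p2, q1)
    d4 = _cross(p1, p2, q2)
    if ((d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)) and (
        (d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)
    ):
        return True
    return False


def _is_blocked(P: np.ndarray, a, b, c, eps: float) -> bool:
    """Any point of P inside or on the triangle (a, b, c)?

    Points coincident with a triangle corner (duplicated hole-bridge
    vertices) never block; points on the boundary edges (collinear
    runs along a cut chord) do.
    """
    if len(P) == 0:
        return False
    d1 = (b[0] - a[0]) * (P[:, 1] - a[1]) - (b[1] - a[1]) * (P[:, 0] - a[0])
    d2 = (c[0] - b[0]) * (P[:, 1] - b[1]) - (c[1] - b[1]) * (P[:, 0] - b[0])
    d3 = (a[0] - c[0]) * (P[:, 1] - c[1]) - (a[1] - c[1]) * (P[:, 0] - c[0])
    inside = (d1 >= -eps) & (d2 >= -eps) & (d3 >= -eps)
    if not inside.any():
        return False
    Q = P[inside]
    for corner in (a, b, c):
        dd = Q - corner
        near = np.einsum("ij,ij->i", dd, dd) <= eps
        Q = Q[~near]
        if len(Q) == 0:
            return False
    return True


def _earclip_simple(pts: np.ndarray, ids: list[int]) -> list[tuple[int, int, int]]:
    """Clip ears off a simple CCW polygon; returns index triples.

    Every boundary vertex ends up in some emitted triangle (collinear
    runs are kept attached), which the cap's edge-pairing with the cut
    shell relies on.
    """
    n = len(ids)
    idx = list(range(n))
    scale = float(np.abs(pts).max()) or 1.0
    eps = _EPS * scale * scale
    tris: list[tuple[int, int, int]] = []

    def ear_ok(k: int, m: int):
        ia, ib, ic = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
        a, b, c = pts[ia], pts[ib], pts[ic]
        cr = _cross(a, b, c)
        if cr <= eps:
            return None  # reflex or flat
        others = [j for j in idx if j not in (ia, ib, ic)]
        if _is_blocked(pts[others], a, b, c, eps):
            return None
        return ia, ib, ic

    start = 0
    stale = 0
    while len(idx) > 3:
        m = len(idx)
        k = start % m
        ear = ear_ok(k, m)
        if ear is not None and m == 4:
            # avoid leaving a collinear (zero-area) terminal triangle
            rest = [idx[j] for j in range(4) if j != k]
            if abs(_cross(pts[rest[0]], pts[rest[1]], pts[rest[2]])) <= eps:
                alt = None
                for k2 in range(4):
                    if k2 == k:
                        continue
                    e2 = ear_ok(k2, m)
                    if e2 is not None:
                        rest2 = [idx[j] for j in range(4) if j != k2]
                        if abs(_cross(pts[rest2[0]], pts[rest2[1]], pts[rest2[2]])) > eps:
                            alt = (k2, e2)
                            break
                if alt is not None:
                    k, ear = alt
        if ear is not None:
            tris.append((ids[ear[0]], ids[ear[1]], ids[ear[2]]))
            idx.pop(k)
            start = k
            stale = 0
            continue
        start += 1
        stale += 1
        if stale > m:
            # no convex ear anywhere: acceptable only if degenerate
            if abs(signed_area(pts[idx])) <= eps * m:
                return tris
            raise SliceError(
                "cap triangulation found no ear (self-intersecting loop?)"
            )
    ia, ib, ic = idx
    if abs(_cross(pts[ia], pts[ib], pts[ic])) > eps:
        tris.append((ids[ia], ids[ib], ids[ic]))
    return tris


def _bridge_hole(outer_pts, outer_ids, hole_pts, hole_ids, all_edges):
    """Merge a hole into the outer chain via a mutually visible bridge."""
    h = int(np.argmax(hole_pts[:, 0]))
    hp = hole_pts[h]
    # candidate outer vertices ordered by distance; first with an
    # unobstructed bridge segment wins (deterministic)
    d2 = np.einsum("ij,ij->i", outer_pts - hp, outer_pts - hp)
    scale = float(np.abs(np.concatenate([outer_pts, hole_pts])).max()) or 1.0
    eps = _EPS * scale * scale
    for o in np.argsort(d2, kind="stable"):
        op = outer_pts[o]
        blocked = False
        for (p1, p2) in all_edges:
            if _segments_intersect(hp, op, p1, p2, eps):
                blocked = True
                break
        if not blocked:
            o = int(o)
            new_pts = np.concatenate(
                [
                    outer_pts[: o + 1],
                    hole_pts[h:],
                    hole_pts[: h + 1],
                    outer_pts[o:],
                ]
            )
            new_ids = (
                outer_ids[: o + 1]
                + hole_ids[h:]
                + hole_ids[: h + 1]
                + outer_ids[o:]
            )
            return new_pts, new_ids
    raise SliceError("could not bridge a hole loop into its outer boundary")


def triangulate_loops(
    loops_pts: list[np.ndarray], loops_ids: list[list[int]]
) -> list[tuple[int, int, int]]:
    """Triangulate a planar region bounded by nested loops.

    ``loops_pts``: 2D coordinates per loop; ``loops_ids``: the caller's
    vertex indices per loop.  Loop nesting is resolved by containment:
    even-depth loops bound material, odd-depth loops are holes in their
    immediate parent.  Orientation of the input loops is normalised
    internally.  Returns triangles (as id triples) wound CCW in the 2D
    frame.
    """
    n = len(loops_pts)
    polys = [Polygon(p) for p in loops_pts]
    depth = [0] * n
    parent = [-1] * n
    for i in range(n):
        best_area = np.inf
        for j in range(n):
            if i == j:
                continue
            if polys[j].contains(Point(loops_pts[i][0])):
                depth[i] += 1
                if polys[j].area < best_area:
                    best_area = polys[j].area
                    parent[i] = j

    def oriented(pts, ids, ccw: bool):
        if (signed_area(pts) > 0) != ccw:
            return pts[::-1].copy(), ids[::-1]
        return pts, list(ids)

    tris: list[tuple[int, int, int]] = []
    for i in range(n):
        if depth[i] % 2 != 0:
            continue  # holes handled with their parent
        outer_pts, outer_ids = oriented(loops_pts[i], loops_ids[i], ccw=True)
        holes = [j for j in range(n) if parent[j] == i and depth[j] % 2 == 1]
        # merge holes right-to-left so bridges cannot cross each other
        hole_data = []
        for j in holes:
            hp, hi = oriented(loops_pts[j], loops_ids[j], ccw=False)
            hole_data.append((hp, hi))
        hole_data.sort(key=lambda t: -float(t[0][:, 0].max()))
        all_edges = []
        for pts in [outer_pts] + [hd[0] for hd in hole_data]:
            for k in range(len(pts)):
                all_edges.append((pts[k], pts[(k + 1) % len(pts)]))
        for hp, hi in hole_data:
            outer_pts, outer_ids = _bridge_hole(
                outer_pts, outer_ids, hp, hi, all_edges
            )
        tris.extend(_earclip_simple(outer_pts, outer_ids))
    used = {i for t in tris for i in t}
    missing = {i for ids in loops_ids for i in ids} - used
    if missing:
        raise SliceError(
            f"cap triangulation left {len(missing)} boundary vertex(es) "
            "unused; the cross-section polygon is degenerate"
        )
    return tris
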