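"""Triangle-mesh data model and morphometrics.

The universal substrate of the toolkit is an indexed triangle surface:
an ``(N, 3)`` float array of vertex coordinates (length units of the
source morphology, e.g. µm) plus an ``(M, 3)`` integer array of vertex
indices, wound counter-clockwise when viewed from outside so that face
normals point outward.

Morphometrics follow the standard discrete formulas: surface area as the
sum of per-triangle cross-product magnitudes, enclosed volume via the
divergence theorem as the absolute sum of signed tetrahedron volumes
spanned with an arbitrary apex.  Volume is only defined for watertight
surfaces: every undirected edge shared by exactly two faces with
opposite directed orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyMeshError,
    InconsistentOrientationError,
    NotWatertightError,
    RemorphError,
)

logger = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}
AXIS_NAMES = ("x", "y", "z")


def axis_index(axis) -> int:
    """Map an axis name ('x'|'y'|'z') or index to 0|1|2."""
    try:
        return _AXES[axis]
    except KeyError:
        raise RemorphError(f"unknown axis {axis!r}; expected x, y or z") from None


@dataclass
class TriMesh:
    """Indexed triangle surface mesh.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates.
    faces : (M, 3) int array
        Vertex-index triples, counter-clockwise seen from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise RemorphError("face index out of range [0, n_vertices)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    # Convenience mirrors of the module-level operations -----------------
    @property
    def area(self) -> float:
        return surface_area(self)

    @property
    def volume(self) -> float:
        return enclosed_volume(self)

    @property
    def is_watertight(self) -> bool:
        return is_watertight(self)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, float), self.faces.copy())

    def scaled(self, s: float) -> "TriMesh":
        return TriMesh(self.vertices * float(s), self.faces.copy())


@dataclass
class Morphometrics:
    """Quantitative shape report for a mesh: the payload of run reports.

    ``volume`` is ``None`` when the surface is open and could not be
    capped; ``capped`` flags a volume obtained after closing boundary
    loops of an open selection.
    """

    surface_area: float
    volume: float | None
    n_vertices: int
    n_faces: int
    watertight: bool
    n_components: int
    capped: bool = False

    def as_dict(self) -> dict:
        d = {
            "surface_area": self.surface_area,
            "volume": self.volume if self.volume is not None else "unavailable",
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
            "watertight": self.watertight,
            "n_components": self.n_components,
        }
        if self.capped:
            d["volume_capped"] = True
        return d


@dataclass
class BoundingBox:
    """Axis-aligned bounding box with a deterministic longest axis.

    Ties on extent are broken x before y before z.
    """

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self):
        self.min = np.asarray(self.min, dtype=np.float64).reshape(3)
        self.max = np.asarray(self.max, dtype=np.float64).reshape(3)
        if np.any(self.min > self.max):
            raise RemorphError("bounding box min exceeds max")

    @property
    def extent(self) -> np.ndarray:
        return self.max - self.min

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.extent))

    @property
    def longest_axis(self) -> str:
        return AXIS_NAMES[int(np.argmax(self.extent))]  # argmax: first max wins


# ---------------------------------------------------------------------------
# Morphometric operations
# ---------------------------------------------------------------------------

def _face_cross(mesh: TriMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])


def surface_area(mesh: TriMesh) -> float:
    """Total surface area: sum of half cross-product magnitudes per face."""
    if mesh.is_empty:
        raise EmptyMeshError("surface area of an empty mesh is undefined")
    return float(0.5 * np.linalg.norm(_face_cross(mesh), axis=1).sum())


def face_areas(mesh: TriMesh) -> np.ndarray:
    if mesh.is_empty:
        return np.zeros(0)
    return 0.5 * np.linalg.norm(_face_cross(mesh), axis=1)


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def _edge_status(mesh: TriMesh) -> tuple[bool, bool]:
    """Return (closed, consistently_oriented).

    closed: every undirected edge is used by exactly two faces.
    consistently_oriented: additionally the two uses run in opposite
    directions (no directed edge repeats).
    """
    if mesh.is_empty:
        return False, False
    de = _directed_edges(mesh.faces)
    und = np.sort(de, axis=1)
    _, und_counts = np.unique(und, axis=0, return_counts=True)
    closed = bool(np.all(und_counts == 2))
    _, dir_counts = np.unique(de, axis=0, return_counts=True)
    consistent = bool(np.all(dir_counts == 1))
    return closed, closed and consistent


def is_watertight(mesh: TriMesh) -> bool:
    """True iff every undirected edge is shared by exactly two faces with
    opposite directed orientation (closed, 2-manifold, consistent winding)."""
    closed, consistent = _edge_status(mesh)
    return closed and consistent


def enclosed_volume(mesh: TriMesh) -> float:
    """Enclosed volume by the divergence theorem.

    Sums signed tetrahedron volumes (origin, v0, v1, v2) over faces and
    takes the absolute value, so a globally flipped but consistent mesh
    still yields the correct magnitude.  Translation invariant.
    """
    if mesh.is_empty:
        raise EmptyMeshError("volume of an empty mesh is undefined")
    closed, consistent = _edge_status(mesh)
    if not closed:
        raise NotWatertightError(
            "enclosed volume is undefined for an open surface "
            "(some edges are not shared by exactly two faces)"
        )
    if not consistent:
        raise InconsistentOrientationError(
            "mesh is closed but its faces have mixed winding; "
            "fix the orientation before measuring volume"
        )
    return abs(signed_volume(mesh))


def signed_volume(mesh: TriMesh, apex=None) -> float:
    """Signed volume sum; positive for outward-wound closed surfaces.

    ``apex`` (default: first vertex, for numerical robustness far from
    the origin) is arbitrary for closed surfaces.
    """
    v = mesh.vertices
    f = mesh.faces
    if apex is None:
        apex = v[0]
    a = v[f[:, 0]] - apex
    b = v[f[:, 1]] - apex
    c = v[f[:, 2]] - apex
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def bounding_box(obj) -> BoundingBox:
    """Axis-aligned bounding box of a mesh, point cloud, or point array."""
    pts = getattr(obj, "vertices", None)
    if pts is None:
        pts = getattr(obj, "points", obj)
    pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise EmptyMeshError("bounding box of empty input is undefined")
    return BoundingBox(pts.min(axis=0), pts.max(axis=0))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _face_components(faces: np.ndarray) -> list[np.ndarray]:
    """Partition face indices into maximal shared-edge-connected groups."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as _cc

    m = len(faces)
    if m == 0:
        return []
    und = np.sort(_directed_edges(faces), axis=1)
    face_of = np.tile(np.arange(m), 3)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und_s = und[order]
    face_s = face_of[order]
    same = np.all(und_s[1:] == und_s[:-1], axis=1)
    rows = face_s[:-1][same]
    cols = face_s[1:][same]
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m)
    )
    n_comp, labels = _cc(graph, directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


def submesh(mesh: TriMesh, face_idx) -> TriMesh:
    """Extract the faces ``face_idx`` with vertices re-indexed compactly."""
    face_idx = np.asarray(face_idx, dtype=np.int64)
    faces = mesh.faces[face_idx]
    used, inverse = np.unique(faces, return_inverse=True)
    return TriMesh(mesh.vertices[used], inverse.reshape(-1, 3))


def connected_components(mesh: TriMesh) -> list[TriMesh]:
    """Split into maximal edge-connected pieces, each re-indexed.

    Components are ordered by their smallest original face index, so the
    result is deterministic and the face partition covers the input.
    """
    comps = _face_components(mesh.faces)
    comps.sort(key=lambda idx: int(idx[0]))
    return [submesh(mesh, idx) for idx in comps]


def keep_largest_component(mesh: TriMesh) -> TriMesh:
    """Keep the component with the greatest surface area.

    Ranking by area rather than face count is robust to non-uniform
    tessellation; ties go to the component containing the lowest
    original face index.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot filter components of an empty mesh")
    comps = _face_components(mesh.faces)
    comps.sort(key=lambda idx: int(idx[0]))
    if len(comps) == 1:
        return submesh(mesh, comps[0])
    pieces = [submesh(mesh, idx) for idx in comps]
    areas = [surface_area(p) for p in pieces]
    best = int(np.argmax(areas))  # argmax keeps the first (lowest face idx) on ties
    n_dropped = len(comps) - 1
    logger.info("keep_largest_component: dropped %d smaller component(s)", n_dropped)
    return pieces[best]


def drop_degenerate_faces(mesh: TriMesh, area_eps: float = 0.0) -> TriMesh:
    """Remove faces that repeat a vertex or have (near-)zero area.

    The dropped count is logged; geometry is otherwise untouched.
    """
    f = mesh.faces
    if len(f) == 0:
        return mesh
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    areas = face_areas(mesh)
    keep = distinct & (areas > area_eps)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d degenerate face(s)", n_drop)
        return TriMesh(mesh.vertices, f[keep])
    return mesh


def measure(mesh: TriMesh) -> Morphometrics:
    """Full morphometric report: area, volume (if defined), counts, topology."""
    if mesh.is_empty:
        raise EmptyMeshError("cannot measure an empty mesh")
    wt = is_watertight(mesh)
    vol = enclosed_volume(mesh) if wt else None
    return Morphometrics(
        surface_area=surface_area(mesh),
        volume=vol,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        watertight=wt,
        n_components=len(_face_components(mesh.faces)),
    )


def merge(meshes) -> TriMesh:
    """Concatenate meshes into one (disjoint union; indices offset)."""
    meshes = list(meshes)
    if not meshes:
        raise EmptyMeshError("nothing to merge")
    verts = []
    faces = []
    off = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return TriMesh(np.concatenate(verts), np.concatenate(faces))
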