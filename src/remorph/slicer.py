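"""Slicing a mesh into segments of equal surface area or volume.

The cumulative measure below a cutting plane (original-surface area, or
capped volume) is monotone non-decreasing in the plane coordinate, so
each cut is found by bisection against its cumulative target k·M/N.
Volume mode caps the cut ends with triangulated cross-section polygons,
keeping watertight inputs watertight; surface-area mode leaves the cut
ends hollow and never counts caps toward the measure.

The error margin ε is the *relative* deviation of each segment's
measure from the equal share M/N — a scale-free contract: bisection
stops once the cumulative measure is within (ε/2)·(M/N) of its target,
which bounds every segment's deviation by ε.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._section import area_below, split_with_info, volume_below
from .core import (
    TriMesh,
    axis_index,
    face_areas,
    is_watertight,
    signed_volume,
    surface_area,
)
from .errors import NotWatertightError, SliceError

MAX_BISECTION_ITERATIONS = 200


@dataclass
class SliceSpec:
    """Slicing parameters: measure, segment count, axis, error margin."""

    mode: str  # "SA" | "V"
    n_segments: int
    axis: str = "z"
    error_margin: float = 1e-5

    def __post_init__(self):
        self.mode = str(self.mode).upper()
        if self.mode in ("VOL", "VOLUME"):
            self.mode = "V"
        if self.mode not in ("SA", "V"):
            raise SliceError("mode must be 'SA' (surface area) or 'V' (volume)")
        self.n_segments = int(self.n_segments)
        if self.n_segments < 2:
            raise SliceError("need at least 2 segments")
        self.error_margin = float(self.error_margin)
        if self.error_margin <= 0:
            raise SliceError("error margin must be positive")


@dataclass
class SliceResult:
    """Segments ascending along the axis plus achieved accuracy."""

    spec: SliceSpec
    segments: list[TriMesh]
    cut_coordinates: np.ndarray
    measures: np.ndarray  # per-segment SA (hollow) or V
    cap_areas: np.ndarray | None  # V mode: per-segment cap area
    achieved_max_relative_deviation: float

    @property
    def total_measure(self) -> float:
        return float(self.measures.sum())


def split_by_plane(
    mesh: TriMesh, axis, c: float, cap: bool = False
) -> tuple[TriMesh, TriMesh]:
    """Split by the plane ``coord[axis] == c`` into (lower, upper).

    Crossing triangles are split along the plane; vertices on the plane
    belong to both pieces' boundary; with ``cap`` each cross-section
    polygon is triangulated (ear clipping, holes supported) and added to
    both pieces with opposite orientation, so watertight inputs yield
    two watertight outputs.  Zero-area fragments are dropped.
    """
    lower, upper, _lf, _uf = split_with_info(mesh, axis, c, cap)
    return lower, upper


def cumulative_measure(mesh: TriMesh, mode: str, axis, c: float) -> float:
    """Measure of the part of the mesh at axis-coordinate ≤ c.

    SA mode: area of the original surface below c (crossing triangles
    split analytically; caps never counted).  V mode: enclosed volume of
    the capped region below c (watertight mesh required).  Monotone
    non-decreasing in c; equals the total measure at the axis maximum.
    """
    mode = SliceSpec(mode=mode, n_segments=2, axis="z").mode
    if mode == "SA":
        return area_below(mesh, axis, c)
    if not is_watertight(mesh):
        raise NotWatertightError(
            "volume-mode slicing requires a watertight mesh; "
            "this surface is open or inconsistently oriented"
        )
    return volume_below(mesh, axis, c)


def _find_cut(eval_cum, target: float, lo: float, hi: float, f_tol: float, k: int):
    """Bisection for eval_cum(c) == target within f_tol on [lo, hi]."""
    a, b = lo, hi
    for _ in range(MAX_BISECTION_ITERATIONS):
        c = 0.5 * (a + b)
        val = eval_cum(c)
        if abs(val - target) <= f_tol:
            return c
        if val < target:
            a = c
        else:
            b = c
    raise SliceError(
        f"cut {k} did not converge within {MAX_BISECTION_ITERATIONS} bisection "
        "iterations; the cumulative measure is locally flat at the target "
        "(e.g. a gap along the slicing axis)"
    )


def slice_equal(mesh: TriMesh, spec: SliceSpec) -> SliceResult:
    """Slice into ``spec.n_segments`` segments of equal SA or volume.

    Cuts c_1 < ... < c_{N−1} are found sequentially by bisection so that
    the cumulative measure at c_k is within (ε/2)·(M/N) of k·M/N; the
    mesh is then split successively at the cuts (caps in V mode only).
    Guarantees max_k |m_k − M/N| / (M/N) ≤ ε.
    """
    ax = axis_index(spec.axis)
    vals = mesh.vertices[:, ax]
    lo, hi = float(vals.min()), float(vals.max())
    if spec.mode == "V":
        if not is_watertight(mesh):
            raise NotWatertightError(
                "volume-mode slicing requires a watertight mesh; "
                "this surface is open or inconsistently oriented"
            )
        orient = 1.0 if signed_volume(mesh) >= 0 else -1.0

        def cum(c):
            return volume_below(mesh, ax, c, orient_sign=orient)

    else:

        def cum(c):
            return area_below(mesh, ax, c)

    total = cum(hi)
    if total <= 0:
        raise SliceError("total measure is zero; nothing to slice")
    share = total / spec.n_segments
    f_tol = 0.5 * spec.error_margin * share
    cuts = []
    prev = lo
    for k in range(1, spec.n_segments):
        c = _find_cut(cum, k * share, prev, hi, f_tol, k)
        if c <= prev:
            raise SliceError(f"cut {k} is not strictly increasing")
        cuts.append(c)
        prev = c

    cap = spec.mode == "V"
    segments: list[TriMesh] = []
    seg_flags: list[np.ndarray] = []
    rest = mesh
    rest_flags = np.zeros(mesh.n_faces, dtype=bool)
    for c in cuts:
        seg, rest, sflags, rest_flags = split_with_info(
            rest, ax, c, cap, face_flags=rest_flags
        )
        segments.append(seg)
        seg_flags.append(sflags)
    segments.append(rest)
    seg_flags.append(rest_flags)

    if spec.mode == "V":
        meas = np.array([s.volume for s in segments])
        cap_areas = np.array(
            [float(face_areas(s)[f].sum()) for s, f in zip(segments, seg_flags)]
        )
    else:
        meas = np.array([surface_area(s) for s in segments])
        cap_areas = None
    dev = float(np.max(np.abs(meas - share)) / share)
    return SliceResult(
        spec=spec,
        segments=segments,
        cut_coordinates=np.array(cuts),
        measures=meas,
        cap_areas=cap_areas,
        achieved_max_relative_deviation=dev,
    )
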