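"""Readers and writers: OBJ meshes, DAT point clouds, DAT run reports.

The DAT dialect is plain comma-separated ``x,y,z`` per line, no header
(the serial-section point-cloud convention); a ``delimiter`` option
tolerates whitespace-separated variants.  OBJ files are written with
1-based indices and six decimal places (sub-nanometre at µm scale), and
read with fan triangulation of >3-gons and OBJ-standard negative-index
resolution.  The decimal separator is always ``.`` regardless of locale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import PointCloud
from .core import TriMesh
from .errors import EmptyMeshError, FormatError

OBJ_DECIMALS = 6
DAT_DECIMALS = 6


def read_obj(path) -> TriMesh:
    """Read a Wavefront OBJ file as a triangle mesh.

    ``v`` lines become vertices; ``f`` lines with more than three
    indices are fan-triangulated from their first vertex; negative
    indices are resolved relative to the vertex count so far, per the
    OBJ standard; texture/normal sub-indices (``1/2/3``) are ignored.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise FormatError("vertex line needs 3 coordinates", lineno)
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError:
                    raise FormatError("non-numeric vertex coordinate", lineno) from None
            elif tag == "f":
                if len(parts) < 4:
                    raise FormatError("face line needs at least 3 indices", lineno)
                idx = []
                for tok in parts[1:]:
                    tok = tok.split("/")[0]
                    try:
                        i = int(tok)
                    except ValueError:
                        raise FormatError(
                            f"non-integer face index {tok!r}", lineno
                        ) from None
                    if i < 0:
                        i = len(vertices) + i  # relative to current vertex count
                    else:
                        i = i - 1
                    if not (0 <= i < len(vertices)):
                        raise FormatError(f"face index {tok} out of range", lineno)
                    idx.append(i)
                for k in range(1, len(idx) - 1):
                    faces.append((idx[0], idx[k], idx[k + 1]))
            # other tags (vn, vt, o, g, s, usemtl, ...) are ignored
    if not faces:
        raise FormatError(f"no faces found in {path}")
    return TriMesh(np.array(vertices), np.array(faces))


def write_obj(mesh: TriMesh, path) -> None:
    """Write a mesh as OBJ (1-based indices, fixed decimal precision)."""
    if mesh.is_empty:
        raise EmptyMeshError("refusing to write an empty mesh")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.{OBJ_DECIMALS}f} {v[1]:.{OBJ_DECIMALS}f} "
                     f"{v[2]:.{OBJ_DECIMALS}f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_pointcloud_dat(path, delimiter: str = ",") -> PointCloud:
    """Read a DAT surface point cloud: one ``x,y,z`` line per point.

    Surrounding whitespace is tolerated; order is preserved.  With
    ``delimiter=None`` whitespace-separated files are accepted.
    """
    path = Path(path)
    pts: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 comma-separated values, got {len(fields)}", lineno
                )
            try:
                pts.append([float(x) for x in fields])
            except ValueError:
                raise FormatError("non-numeric coordinate", lineno) from None
    if not pts:
        raise FormatError(f"no points found in {path}")
    return PointCloud(np.array(pts))


def write_pointcloud_dat(cloud: PointCloud, path) -> None:
    """Write a point cloud as comma-separated XYZ lines, input order."""
    if cloud.is_empty:
        raise EmptyMeshError("refusing to write an empty point cloud")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in cloud.points:
            fh.write(f"{p[0]:.{DAT_DECIMALS}f},{p[1]:.{DAT_DECIMALS}f},"
                     f"{p[2]:.{DAT_DECIMALS}f}\n")


@dataclass
class RunReport:
    """What a tool run did: parameters applied, wall time, measured values."""

    tool: str
    parameters: dict = field(default_factory=dict)
    elapsed_seconds: float = 0.0
    values: dict = field(default_factory=dict)

    _start: float | None = None

    def start(self) -> "RunReport":
        self._start = time.perf_counter()
        return self

    def stop(self) -> "RunReport":
        if self._start is not None:
            self.elapsed_seconds = time.perf_counter() - self._start
        return self


def write_report(report: RunReport, path) -> None:
    """Write a run report as human-readable ``key: value`` lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"tool: {report.tool}\n")
        for k, v in report.parameters.items():
            fh.write(f"{k}: {v}\n")
        fh.write(f"elapsed_seconds: {report.elapsed_seconds:.6f}\n")
        for k, v in report.values.items():
            if isinstance(v, float):
                fh.write(f"{k}: {v:.9g}\n")
            else:
                fh.write(f"{k}: {v}\n")


def new_run_folder(base, prefix: str = "run") -> Path:
    """Create and return a fresh ``<base>/<prefix>_NNN`` output folder.

    Outputs of each tool invocation land in their own new folder; the
    counter makes reruns deterministic in naming.
    """
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    n = 1
    while True:
        cand = base / f"{prefix}_{n:03d}"
        try:
            cand.mkdir()
            return cand
        except FileExistsError:
            n += 1
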