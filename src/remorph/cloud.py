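"""Surface point-cloud container.

A cell surface represented purely by ordered XYZ coordinates, optionally
grouped into circumvent stations: each point may carry an (axis, station)
label identifying the planar ring it belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RemorphError


@dataclass
class PointCloud:
    """Ordered XYZ points with optional ring labels.

    ``labels`` (optional): (N, 2) int array of (axis index, station
    index) per point, grouping points into circumvents.
    """

    points: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise RemorphError("point cloud contains non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1, 2)
            if len(self.labels) != len(self.points):
                raise RemorphError("labels must match points one-to-one")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    def subset(self, mask) -> "PointCloud":
        """Points selected by a boolean mask or index array, order kept."""
        mask = np.asarray(mask)
        labels = self.labels[mask] if self.labels is not None else None
        return PointCloud(self.points[mask], labels=labels)
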