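"""Categorical land-cover layers: raster and polygon backends.

The threat overlay emulates the CORINE-style convention the assessment
uses: artificial (1xx) and agricultural (2xx) classes count as
human-influence threats, except olive groves (223) and
agriculture-with-natural-vegetation / agro-forestry (243, 244), which are
(semi-)natural. Which codes count as threats is configuration, not logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

#: Default threat-class convention (CLC-style level 1 + 2 minus 223/243/244).
DEFAULT_THREAT_CLASSES = frozenset({111, 112, 121, 211, 221, 222, 231, 242}) - {223, 243, 244}

NODATA = -1


@dataclass
class LandCoverRaster:
    """Integer class-code raster on a regular grid in the analysis plane.

    ``codes[row, col]`` covers the pixel whose lower-left corner is
    ``(x_min + col*pixel_m, y_min + row*pixel_m)``; pixels are half-open.
    """

    codes: np.ndarray  # (nrows, ncols) int
    x_min: float
    y_min: float
    pixel_m: float
    threat_classes: frozenset[int] = DEFAULT_THREAT_CLASSES

    def class_at(self, x: float, y: float) -> int:
        col = int(np.floor((x - self.x_min) / self.pixel_m))
        row = int(np.floor((y - self.y_min) / self.pixel_m))
        if 0 <= row < self.codes.shape[0] and 0 <= col < self.codes.shape[1]:
            return int(self.codes[row, col])
        return NODATA

    def majority_class_in(self, xmin: float, ymin: float, xmax: float, ymax: float) -> int:
        """Most frequent class among pixels overlapping the box (ties by
        smaller code, for determinism); NODATA if no pixel overlaps."""
        c0 = max(0, int(np.floor((xmin - self.x_min) / self.pixel_m)))
        c1 = min(self.codes.shape[1], int(np.ceil((xmax - self.x_min) / self.pixel_m)))
        r0 = max(0, int(np.floor((ymin - self.y_min) / self.pixel_m)))
        r1 = min(self.codes.shape[0], int(np.ceil((ymax - self.y_min) / self.pixel_m)))
        if c0 >= c1 or r0 >= r1:
            return NODATA
        block = self.codes[r0:r1, c0:c1]
        values, counts = np.unique(block, return_counts=True)
        return int(values[np.argmax(counts)])  # np.unique sorts -> tie to smaller code

    def threat_fraction(self) -> float:
        return float(np.isin(self.codes, list(self.threat_classes)).mean())

    def to_csv(self, path: str | Path) -> None:
        nrows, ncols = self.codes.shape
        header = pd.DataFrame(
            {"x_min": [self.x_min], "y_min": [self.y_min], "pixel_m": [self.pixel_m],
             "nrows": [nrows], "ncols": [ncols],
             "threat_classes": [" ".join(map(str, sorted(self.threat_classes)))]}
        )
        with open(path, "w") as fh:
            header.to_csv(fh, index=False)
            np.savetxt(fh, self.codes, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandCoverRaster":
        with open(path) as fh:
            cols = fh.readline().strip().split(",")
            vals = fh.readline().strip().split(",")
            meta = dict(zip(cols, vals))
            codes = np.loadtxt(fh, dtype=int, delimiter=",", ndmin=2)
        return cls(
            codes=codes,
            x_min=float(meta["x_min"]),
            y_min=float(meta["y_min"]),
            pixel_m=float(meta["pixel_m"]),
            threat_classes=frozenset(int(t) for t in meta["threat_classes"].split()),
        )


@dataclass
class LandCoverPolygons:
    """Class-coded polygon mosaic; lookup is point-in-polygon."""

    polygons: list[Polygon]
    class_codes: list[int]
    threat_classes: frozenset[int] = DEFAULT_THREAT_CLASSES
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def class_at(self, x: float, y: float) -> int:
        if self._tree is None:
            object.__setattr__(self, "_tree", STRtree(self.polygons))
        pt = Point(x, y)
        for idx in self._tree.query(pt):
            if self.polygons[idx].covers(pt):
                return self.class_codes[idx]
        return NODATA
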