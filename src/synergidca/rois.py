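"""Named polygonal regions of interest and their structured-text format.

Coordinates are 0-based pixel coordinates with the origin at the top-left;
``x`` indexes columns and ``y`` rows.  A pixel belongs to a region when its
centre ``(x, y) = (col, row)`` falls inside the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .errors import FormatError

__all__ = ["ROISet"]


@dataclass
class ROISet:
    """A mapping of region labels (left, right, combined) to polygons."""

    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for label, verts in self.regions.items():
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise FormatError(
                    f"region {label!r} must be an (N>=3, 2) vertex array")
            cleaned[label] = arr
        self.regions = cleaned

    def labels(self) -> list[str]:
        return list(self.regions)

    def mask(self, label: str, height: int, width: int) -> np.ndarray:
        """Boolean membership mask: pixels whose centres fall inside."""
        poly = Polygon(self.regions[label])
        cols, rows = np.meshgrid(np.arange(width), np.arange(height))
        inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
        return inside.reshape(height, width)

    def validate_bounds(self, height: int, width: int) -> None:
        for label, verts in self.regions.items():
            if (verts[:, 0].min() < -0.5 or verts[:, 0].max() > width - 0.5
                    or verts[:, 1].min() < -0.5 or verts[:, 1].max() > height - 0.5):
                raise FormatError(
                    f"region {label!r} extends beyond the {height}x{width} frame")

    def write(self, path: str | Path) -> None:
        payload = {
            "origin": "top-left",
            "indexing": "0-based, x=column, y=row",
            "regions": {label: [[float(x), float(y)] for x, y in verts]
                        for label, verts in self.regions.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "ROISet":
        try:
            payload = yaml.safe_load(Path(path).read_text())
            regions = payload["regions"]
        except (yaml.YAMLError, KeyError, TypeError) as exc:
            raise FormatError(f"{path}: not a valid ROI file: {exc}") from exc
        return cls(regions={label: np.asarray(v, dtype=float)
                            for label, v in regions.items()})
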