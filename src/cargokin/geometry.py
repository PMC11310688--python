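"""Radial cell geometry: a centre point plus a closed boundary polygon.

The centre is the microtubule convergence point (the MTOC region); the
boundary is the cell outline. All radial metrics (alignment angles, edge
exclusion, radial intensity profiles, comet polarity) are defined relative
to this frame. Polygon predicates are delegated to shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = ["CellGeometry", "circular_cell"]


@dataclass
class CellGeometry:
    """Cell centre (µm) and simple closed boundary polygon (µm).

    The centre must lie strictly inside the boundary and the polygon must be
    star-shaped around it (every ray from the centre crosses the boundary
    once), so that "distance from the centre" is a well-defined radial
    coordinate.
    """

    center: tuple[float, float]
    boundary: np.ndarray  # (m, 2) vertices, closed implicitly

    def __post_init__(self) -> None:
        self.center = (float(self.center[0]), float(self.center[1]))
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (m, 2) vertex array")
        if self.boundary.shape[0] < 3:
            raise ValueError("boundary needs at least 3 vertices")
        poly = Polygon(self.boundary)
        if not poly.is_valid:
            raise ValueError("boundary polygon is not simple")
        if not poly.contains(Point(self.center)):
            raise ValueError("center must lie strictly inside the boundary")
        self._poly = poly

    @property
    def polygon(self) -> Polygon:
        return self._poly

    def contains(self, x: float, y: float) -> bool:
        return self._poly.covers(Point(x, y))

    def distance_to_boundary(self, x: float, y: float) -> float:
        """Distance (µm) from a point to the boundary polyline."""
        return float(self._poly.exterior.distance(Point(x, y)))

    def radius_at(self, x: float, y: float) -> float:
        """Distance (µm) from the cell centre."""
        return float(np.hypot(x - self.center[0], y - self.center[1]))

    def radial_unit(self, x: float, y: float) -> np.ndarray:
        """Outward unit vector of the radial axis through (x, y)."""
        v = np.array([x - self.center[0], y - self.center[1]])
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("radial axis undefined at the cell centre")
        return v / n

    def max_radius(self) -> float:
        """Largest centre-to-vertex distance (µm)."""
        d = self.boundary - np.asarray(self.center)
        return float(np.hypot(d[:, 0], d[:, 1]).max())

    # ---- JSON round trip -------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"center": list(self.center), "boundary": self.boundary.tolist()},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CellGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["center"]), np.asarray(d["boundary"]))


def circular_cell(radius: float, center=(0.0, 0.0), n_vertices: int = 64) -> CellGeometry:
    """Regular-polygon approximation of a circular cell of given radius (µm)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )
    return CellGeometry(center, verts)
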