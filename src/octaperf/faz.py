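"""Foveal avascular zone (FAZ) morphometry.

The FAZ is supplied as an ordered polygon delineation in mm coordinates
(the manual polygon-tool workflow); this module measures its area and
rasterizes it onto a scan grid for downstream masking.  The FAZ is
delineated in the superficial plexus only; the same region is reused as
the exclusion mask for all plexuses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .geometry import ScanGeometry

__all__ = ["FAZRegion", "polygon_area", "rasterize"]


def polygon_area(vertices) -> float:
    """Absolute (shoelace) area of a simple polygon, in mm².

    Orientation-independent.  Fewer than 3 vertices yields area 0 with a
    warning; a self-intersecting polygon is rejected.
    """
    v = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(v) < 3:
        warnings.warn("polygon has fewer than 3 vertices; area is 0", stacklevel=2)
        return 0.0
    ring = shapely.LinearRing(v)
    if not ring.is_simple:
        raise ValueError("polygon is self-intersecting")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass(frozen=True)
class FAZRegion:
    """A FAZ delineation: polygon vertices in mm plus derived area.

    ``area_mm2`` always equals the shoelace area of ``vertices_mm``.
    """

    vertices_mm: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_mm, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "vertices_mm", v)
        if len(v) >= 3 and not shapely.LinearRing(v).is_simple:
            raise ValueError("polygon is self-intersecting")

    @property
    def is_empty(self) -> bool:
        return len(self.vertices_mm) < 3

    @property
    def area_mm2(self) -> float:
        if self.is_empty:
            return 0.0
        return polygon_area(self.vertices_mm)

    def raster(self, geometry: ScanGeometry) -> np.ndarray:
        return rasterize(self, geometry)

    # -- JSON schema: {"vertices_mm": [[x, y], ...]} ------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"vertices_mm": self.vertices_mm.tolist()}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FAZRegion":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["vertices_mm"], dtype=float).reshape(-1, 2))

    @classmethod
    def empty(cls) -> "FAZRegion":
        return cls(np.empty((0, 2)))

    @classmethod
    def regular_polygon(
        cls, n_vertices: int, circumradius_mm: float, center_mm=(0.0, 0.0)
    ) -> "FAZRegion":
        ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
        v = np.stack(
            [center_mm[0] + circumradius_mm * np.cos(ang),
             center_mm[1] + circumradius_mm * np.sin(ang)],
            axis=1,
        )
        return cls(v)


def rasterize(faz: FAZRegion, geometry: ScanGeometry) -> np.ndarray:
    """Rasterize a FAZ polygon onto the scan grid.

    Pixel-centre rule: a pixel belongs to the FAZ iff its centre lies inside
    the *closed* polygon (boundary inclusive).  The raster area
    ``count * px_scale_mm**2`` converges to the shoelace area with grid
    refinement.
    """
    mask = np.zeros(geometry.shape, dtype=bool)
    if faz.is_empty:
        return mask
    poly = shapely.Polygon(faz.vertices_mm)
    minx, miny, maxx, maxy = poly.bounds
    lo, hi = -0.5 * geometry.px_scale_mm, geometry.extent_mm - 0.5 * geometry.px_scale_mm
    if maxx < lo or minx > hi or maxy < lo or miny > hi:
        warnings.warn("FAZ polygon lies outside the scan extent", stacklevel=2)
        return mask
    x, y = geometry.pixel_centers_mm()
    inside = shapely.intersects_xy(poly, x.ravel(), y.ravel())
    return inside.reshape(geometry.shape)
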