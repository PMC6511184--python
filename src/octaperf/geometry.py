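"""Scan geometry: the coordinate contract shared by every en-face image.

All en-face grids are square ``n_px x n_px`` rasters covering a physical
square of side ``extent_mm``.  Physical coordinates are millimetres with the
origin at the top-left *pixel centre*, x increasing rightward (columns) and
y increasing downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScanGeometry", "PRESETS"]

#: Cirrus-AngioPlex-like grid presets: extent (mm) -> pixels per side.
PRESETS: dict[float, int] = {3.0: 245, 6.0: 350}


@dataclass(frozen=True)
class ScanGeometry:
    """Physical extent and pixel grid of a square en-face scan.

    Parameters
    ----------
    extent_mm
        Side length of the scanned square in millimetres (3.0 and 6.0 are
        the device presets; any positive value is accepted).
    n_px
        Number of pixels per side.
    """

    extent_mm: float
    n_px: int

    def __post_init__(self) -> None:
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if int(self.n_px) != self.n_px or self.n_px <= 0:
            raise ValueError("n_px must be a positive integer")

    @property
    def px_scale_mm(self) -> float:
        """Pixel pitch in mm per pixel."""
        return self.extent_mm / self.n_px

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of every raster sharing this geometry."""
        return (self.n_px, self.n_px)

    @property
    def area_mm2(self) -> float:
        return self.extent_mm * self.extent_mm

    @property
    def px_area_mm2(self) -> float:
        return self.px_scale_mm * self.px_scale_mm

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate grids of pixel centres in mm.

        The top-left pixel centre sits at (0, 0); see module docstring.
        """
        coords = np.arange(self.n_px) * self.px_scale_mm
        x, y = np.meshgrid(coords, coords)
        return x, y

    @property
    def center_mm(self) -> tuple[float, float]:
        """Scan centre in the pixel-centre coordinate frame."""
        c = (self.n_px - 1) / 2.0 * self.px_scale_mm
        return (c, c)

    @classmethod
    def preset(cls, extent_mm: float) -> "ScanGeometry":
        """Device-like preset grid for a 3x3 or 6x6 mm scan."""
        try:
            n_px = PRESETS[float(extent_mm)]
        except KeyError:
            raise ValueError(
                f"no preset for extent {extent_mm!r}; use ScanGeometry(extent_mm, n_px)"
            ) from None
        return cls(float(extent_mm), n_px)
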