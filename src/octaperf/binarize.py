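"""Mean-threshold binarization of en-face angiograms.

Reimplements the five-step macro used by the study: (i/ii) reduce the image
to its red reference channel, (iii) apply a single global threshold at the
image mean, (iv/v) attach the FAZ exclusion mask.  The threshold is computed
over the *full* image, including FAZ pixels, because the macro thresholds
before the FAZ is painted.

The threshold rule is strict ``>``: a constant image yields zero vessels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .faz import FAZRegion, rasterize
from .geometry import ScanGeometry

__all__ = [
    "Angiogram",
    "BinaryAngiogram",
    "MaskedAngiogram",
    "to_reference_channel",
    "mean_threshold",
    "binarize",
    "apply_faz_mask",
    "THRESHOLD_METHODS",
]


@dataclass(frozen=True)
class Angiogram:
    """En-face slab image with intensities in [0, 255].

    ``pixels`` is (H, W) for gray or (H, W, 3) for RGB; dimensions must
    match ``geometry``.
    """

    pixels: np.ndarray
    geometry: ScanGeometry
    channel_layout: str = "gray"  # {"gray", "rgb"}

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if self.channel_layout == "gray":
            expected = self.geometry.shape
        elif self.channel_layout == "rgb":
            expected = (*self.geometry.shape, 3)
        else:
            raise ValueError(f"unsupported layout: {self.channel_layout!r}")
        if px.shape != expected:
            raise ValueError(
                f"pixel shape {px.shape} does not match geometry {expected}"
            )


@dataclass(frozen=True)
class BinaryAngiogram:
    """Binarized angiogram: True = perfused (white), False = background."""

    pixels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            raise ValueError("BinaryAngiogram pixels must be boolean")
        if px.shape != self.geometry.shape:
            raise ValueError("pixel shape does not match geometry")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class MaskedAngiogram:
    """Binary angiogram plus an exclusion mask (True = excluded/FAZ).

    Excluded pixels carry no perfusion meaning; downstream density ignores
    them entirely.
    """

    binary: BinaryAngiogram
    excluded: np.ndarray

    def __post_init__(self) -> None:
        exc = np.asarray(self.excluded)
        if exc.dtype != bool:
            raise ValueError("exclusion mask must be boolean")
        if exc.shape != self.binary.pixels.shape:
            raise ValueError("mask shape does not match binary image")
        object.__setattr__(self, "excluded", exc)


def to_reference_channel(img: Angiogram) -> Angiogram:
    """Reduce an angiogram to its red reference channel.

    RGB input returns the red channel; gray input is the identity (an
    already-gray source equals its red channel after 8-bit -> RGB
    replication).  Any other layout is rejected.
    """
    if img.channel_layout == "gray":
        return img
    if img.channel_layout == "rgb":
        return Angiogram(img.pixels[..., 0], img.geometry, "gray")
    raise ValueError(f"unsupported layout: {img.channel_layout!r}")


def mean_threshold(img: Angiogram) -> float:
    """Global threshold at the arithmetic mean of all pixel intensities."""
    if img.channel_layout != "gray":
        raise ValueError("mean_threshold expects a gray angiogram")
    if img.pixels.size == 0:
        raise ValueError("empty image")
    return float(np.mean(img.pixels, dtype=np.float64))


#: Pluggable threshold functions (gray Angiogram -> scalar threshold).
THRESHOLD_METHODS: dict[str, Callable[[Angiogram], float]] = {
    "mean": mean_threshold,
}


def binarize(img: Angiogram, threshold: float) -> BinaryAngiogram:
    """Foreground iff intensity is strictly greater than ``threshold``."""
    if img.channel_layout != "gray":
        raise ValueError("binarize expects a gray angiogram")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryAngiogram(np.asarray(img.pixels) > threshold, img.geometry)


def apply_faz_mask(binary: BinaryAngiogram, faz: FAZRegion | np.ndarray) -> MaskedAngiogram:
    """Attach the FAZ exclusion mask to a binary angiogram.

    ``faz`` may be a FAZRegion (rasterized on the image's geometry) or a
    precomputed boolean raster, which must match the image shape.
    """
    if isinstance(faz, FAZRegion):
        mask = rasterize(faz, binary.geometry)
    else:
        mask = np.asarray(faz)
        if mask.shape != binary.pixels.shape:
            raise ValueError("FAZ raster does not match image geometry")
        mask = mask.astype(bool)
    return MaskedAngiogram(binary, mask)
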