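"""Perfusion density: the headline FAZ-subtracted vessel-density metric.

Density is the fraction of perfused (white) pixels among all pixels outside
the FAZ exclusion mask — equivalently the mean of the binarized slab over
the region of interest (full scan minus FAZ).  It is dimensionless in
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .binarize import (
    Angiogram,
    MaskedAngiogram,
    apply_faz_mask,
    binarize,
    mean_threshold,
    to_reference_channel,
)
from .faz import FAZRegion
from .geometry import ScanGeometry

__all__ = ["PerfusionMeasurement", "perfusion_density", "measure_eye", "PLEXUSES"]

logger = logging.getLogger(__name__)

PLEXUSES = ("SCP", "DCP", "CC")


@dataclass(frozen=True)
class PerfusionMeasurement:
    """One per-eye, per-timepoint, per-plexus density measurement.

    ``faz_area_mm2`` is present only for the SCP (the FAZ is delineated in
    the superficial plexus only).
    """

    eye_id: str
    timepoint: str  # {"baseline", "month1"}
    plexus: str  # {"SCP", "DCP", "CC"}
    extent_mm: float
    density: float
    faz_area_mm2: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if (self.faz_area_mm2 is not None) != (self.plexus == "SCP"):
            raise ValueError("faz_area_mm2 is present iff plexus == 'SCP'")


def perfusion_density(m: MaskedAngiogram) -> float:
    """Foreground fraction among non-excluded pixels.

    Foreground pixels inside the exclusion mask are ignored outright — they
    count toward neither numerator nor denominator.
    """
    roi = ~m.excluded
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError("empty region of interest")
    n_fg = int(np.count_nonzero(m.binary.pixels & roi))
    return n_fg / n_roi


def measure_eye(
    images: Mapping[str, Angiogram],
    faz: FAZRegion,
    geometry: ScanGeometry,
    eye_id: str,
    timepoint: str,
    plexuses: tuple[str, ...] = PLEXUSES,
) -> list[PerfusionMeasurement]:
    """Run channel -> mean threshold -> binarize -> FAZ mask -> density per plexus.

    The SCP-delineated FAZ is applied to all three plexuses (the density is
    a peri-FAZ density throughout).  A missing plexus image produces a
    partial result with a logged warning.
    """
    faz_raster = faz.raster(geometry)
    out: list[PerfusionMeasurement] = []
    for plexus in plexuses:
        img = images.get(plexus)
        if img is None:
            logger.warning("eye %s %s: missing %s image", eye_id, timepoint, plexus)
            continue
        if img.geometry != geometry:
            raise ValueError(f"{plexus} image geometry does not match")
        gray = to_reference_channel(img)
        thr = mean_threshold(gray)
        masked = apply_faz_mask(binarize(gray, thr), faz_raster)
        out.append(
            PerfusionMeasurement(
                eye_id=eye_id,
                timepoint=timepoint,
                plexus=plexus,
                extent_mm=geometry.extent_mm,
                density=perfusion_density(masked),
                faz_area_mm2=faz.area_mm2 if plexus == "SCP" else None,
                threshold=thr,
            )
        )
    return out
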