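"""Axial slab segmentation of the three capillary plexuses.

Boundaries derive from the device-exported ILM and RPE surfaces by pure
arithmetic:

* OPL  = RPE - 110 um
* IPL  = ILM + 0.70 * (OPL - ILM)
* CC slab = [RPE + 29 um, RPE + 49 um)

Depth increases from vitreous to choroid; all boundaries are um from the
volume top.  Slabs use half-open depth intervals [inner, outer) so the
SCP [ILM, IPL) and DCP [IPL, OPL) partition [ILM, OPL) without
double-counting the IPL plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import Angiogram
from .geometry import ScanGeometry

__all__ = [
    "SurfaceSet",
    "SlabBoundaries",
    "SegmentationQC",
    "derive_boundaries",
    "validate_segmentation",
    "project_slab",
]

OPL_OFFSET_UM = 110.0
IPL_FRACTION = 0.70
CC_INNER_OFFSET_UM = 29.0
CC_OUTER_OFFSET_UM = 49.0


@dataclass(frozen=True)
class SurfaceSet:
    """Per-A-scan ILM and RPE depth maps in um."""

    z_ilm: np.ndarray
    z_rpe: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        ilm = np.asarray(self.z_ilm, dtype=float)
        rpe = np.asarray(self.z_rpe, dtype=float)
        if ilm.shape != rpe.shape:
            raise ValueError("ILM and RPE grids must share a shape")
        if ilm.shape != self.geometry.shape:
            raise ValueError("surface grids do not match geometry")
        object.__setattr__(self, "z_ilm", ilm)
        object.__setattr__(self, "z_rpe", rpe)


@dataclass(frozen=True)
class SlabBoundaries:
    """Derived plexus boundary grids (um) plus the ILM-OPL thickness grid."""

    z_ilm: np.ndarray
    z_ipl: np.ndarray
    z_opl: np.ndarray
    z_rpe: np.ndarray
    cc_inner: np.ndarray
    cc_outer: np.ndarray
    t_ilm_opl: np.ndarray
    geometry: ScanGeometry

    def slab_interval(self, slab: str) -> tuple[np.ndarray, np.ndarray]:
        """Half-open [inner, outer) depth grids for SCP, DCP or CC."""
        if slab == "SCP":
            return self.z_ilm, self.z_ipl
        if slab == "DCP":
            return self.z_ipl, self.z_opl
        if slab == "CC":
            return self.cc_inner, self.cc_outer
        raise ValueError(f"unknown slab {slab!r}")


@dataclass(frozen=True)
class SegmentationQC:
    """Per-A-scan boundary-ordering check; ok iff zero violations.

    The exclusion decision is left to the caller: the study excluded whole
    eyes, not pixels.
    """

    ok: bool
    violation_mask: np.ndarray
    reason: str


def derive_boundaries(s: SurfaceSet) -> SlabBoundaries:
    """Compute all slab boundaries from the two input surfaces.

    Pure arithmetic, no smoothing; degenerate or inverted boundaries are
    still computed and left for :func:`validate_segmentation` to flag.
    """
    z_opl = s.z_rpe - OPL_OFFSET_UM
    t = z_opl - s.z_ilm
    z_ipl = s.z_ilm + IPL_FRACTION * t
    return SlabBoundaries(
        z_ilm=s.z_ilm.copy(),
        z_ipl=z_ipl,
        z_opl=z_opl,
        z_rpe=s.z_rpe.copy(),
        cc_inner=s.z_rpe + CC_INNER_OFFSET_UM,
        cc_outer=s.z_rpe + CC_OUTER_OFFSET_UM,
        t_ilm_opl=t,
        geometry=s.geometry,
    )


def validate_segmentation(b: SlabBoundaries, s: SurfaceSet) -> SegmentationQC:
    """Flag A-scans whose boundary ordering or sign is invalid.

    An A-scan is a violation when ILM <= IPL <= OPL <= RPE fails or any
    boundary is negative.
    """
    if b.z_ilm.shape != s.z_ilm.shape:
        raise ValueError("boundaries do not match surface grids")
    ordering = (b.z_ilm <= b.z_ipl) & (b.z_ipl <= b.z_opl) & (b.z_opl <= b.z_rpe)
    nonneg = (b.z_ilm >= 0) & (b.z_ipl >= 0) & (b.z_opl >= 0) & (b.z_rpe >= 0)
    violations = ~(ordering & nonneg)
    n_bad = int(np.count_nonzero(violations))
    if n_bad == 0:
        return SegmentationQC(True, violations, "all A-scans valid")
    reasons = []
    if np.any(~ordering):
        reasons.append(
            f"boundary ordering ILM<=IPL<=OPL<=RPE violated at {int(np.count_nonzero(~ordering))} A-scans"
        )
    if np.any(~nonneg):
        reasons.append(f"negative boundary at {int(np.count_nonzero(~nonneg))} A-scans")
    return SegmentationQC(False, violations, "; ".join(reasons))


def project_slab(
    volume: np.ndarray,
    b: SlabBoundaries,
    slab: str,
    method: str = "max",
    z0_um: float = 0.0,
    dz_um: float = 1.0,
) -> Angiogram:
    """En-face projection of a 3-D intensity volume between slab boundaries.

    ``volume`` is (n_z, n_y, n_x) with voxel k at depth ``z0_um + k*dz_um``;
    voxels with depth in [inner, outer) of the chosen slab are aggregated
    per A-scan by ``max`` (default) or ``mean``.  A-scans whose slab is
    empty project to 0; a slab empty everywhere is an error.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D (depth, rows, cols)")
    inner, outer = b.slab_interval(slab)
    if vol.shape[1:] != inner.shape:
        raise ValueError("volume en-face shape does not match boundaries")
    depth = z0_um + dz_um * np.arange(vol.shape[0])
    in_slab = (depth[:, None, None] >= inner[None]) & (depth[:, None, None] < outer[None])
    counts = in_slab.sum(axis=0)
    if not counts.any():
        raise ValueError(f"{slab} slab lies entirely outside the volume")
    if method == "max":
        proj = np.where(in_slab, vol, -np.inf).max(axis=0)
        proj = np.where(counts > 0, proj, 0.0)
    elif method == "mean":
        with np.errstate(invalid="ignore"):
            proj = np.where(in_slab, vol, 0.0).sum(axis=0) / counts
        proj = np.where(counts > 0, proj, 0.0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return Angiogram(np.clip(proj, 0.0, 255.0), b.geometry, "gray")
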