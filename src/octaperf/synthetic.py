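"""Synthetic OCT-A generator with known ground truth.

Stands in for patient scans (which are not deposited): produces ILM/RPE
surface maps with a foveal deformation, binary vascular networks built by a
branching random walk, noisy grayscale renders, and paired
baseline/follow-up cohorts whose true densities are recorded in a ledger.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .binarize import Angiogram, BinaryAngiogram
from .density import PLEXUSES, measure_eye
from .faz import FAZRegion
from .geometry import ScanGeometry
from .slabs import SurfaceSet

__all__ = [
    "BranchParams",
    "EffectModel",
    "CohortParams",
    "SyntheticGroundTruth",
    "SyntheticCohort",
    "generate_surfaces",
    "generate_vessel_network",
    "render_angiogram",
    "generate_faz",
    "generate_cohort",
]

#: Maximal adhesion diameter for the "eligible VMT" preset (um).
MAX_ELIGIBLE_VMT_DIAMETER_UM = 1500.0


# ---------------------------------------------------------------------------
# parameter bundles


@dataclass(frozen=True)
class BranchParams:
    """Tuning knobs of the branching random-walk vessel model."""

    step_px: float = 1.0
    turn_sd_rad: float = 0.35
    steps_per_walk: int = 64
    #: probability of stroke widths 1..len px; weighted toward wide strokes
    #: so the blurred render stays stable under the mean threshold
    width_probs: tuple[float, ...] = (0, 0, 0, 0, 0.35, 0.30, 0.20, 0.15)
    fine_width: int = 5  # stroke width of the final fill-in walks
    branch_fraction: float = 0.6  # walkers seeded from existing vessels
    max_batches: int = 20_000


@dataclass(frozen=True)
class EffectModel:
    """Additive baseline -> follow-up changes injected into the cohort."""

    scp_shift: float = -0.014  # Table-3-like default
    dcp_shift: float = 0.0
    cc_shift: float = 0.0
    faz_shift_mm2: float = 0.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def shift(self, plexus: str) -> float:
        return {"SCP": self.scp_shift, "DCP": self.dcp_shift, "CC": self.cc_shift}[plexus]

    @classmethod
    def null(cls, noise_sd: float = 5.0) -> "EffectModel":
        return cls(0.0, 0.0, 0.0, 0.0, noise_sd)


@dataclass(frozen=True)
class CohortParams:
    """Population-level ground-truth parameters of the simulated cohort."""

    mean_density_vmt: Mapping[str, float] = field(
        default_factory=lambda: {"SCP": 0.427, "DCP": 0.434, "CC": 0.472}
    )
    mean_density_control: Mapping[str, float] = field(
        default_factory=lambda: {"SCP": 0.418, "DCP": 0.429, "CC": 0.500}
    )
    between_eye_sd: float = 0.027
    faz_area_vmt_mm2: tuple[float, float] = (0.103, 0.031)  # mean, SD
    faz_area_control_mm2: tuple[float, float] = (0.198, 0.074)
    age_vmt_years: tuple[float, float] = (59.2, 3.4)
    vmt_diameter_range_um: tuple[float, float] = (500.0, 1400.0)
    # 0.5 px keeps the mean-threshold pipeline effectively unbiased across
    # the density range, so injected effects are recovered without shrinkage
    blur_sigma_px: float = 0.5


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Per-eye generator ground truth (realized, not just targeted)."""

    true_density_scp: float
    true_density_dcp: float
    true_density_cc: float
    faz_polygon: np.ndarray
    faz_area_mm2: float
    vmt_adhesion_diameter_um: float
    seed: int


# ---------------------------------------------------------------------------
# surfaces


def generate_surfaces(
    geometry: ScanGeometry,
    foveal_pit_depth_um: float,
    vmt_peak_um: float,
    vmt_diameter_um: float,
    seed: int,
    ilm_base_um: float = 150.0,
    thickness_um: float = 310.0,
) -> SurfaceSet:
    """Smooth ILM/RPE depth grids (um) with a central pit and optional VMT.

    Depth increases posteriorly, so the foveal pit *increases* ILM depth at
    the scan centre; a VMT adhesion pulls the ILM anteriorly (depth
    decreases) over a compact disk of ``vmt_diameter_um``, opposing the pit.
    """
    if geometry.n_px <= 0:
        raise ValueError("empty geometry")
    if vmt_diameter_um < 0:
        raise ValueError("vmt_diameter_um must be >= 0")
    rng = np.random.default_rng(seed)
    x, y = geometry.pixel_centers_mm()
    cx, cy = geometry.center_mm
    r_mm = np.hypot(x - cx, y - cy)

    # foveal pit: Gaussian depression of the inner surface
    pit_sigma_mm = 0.35
    z_ilm = ilm_base_um + foveal_pit_depth_um * np.exp(-0.5 * (r_mm / pit_sigma_mm) ** 2)

    # VMT adhesion: raised-cosine anterior pull, exactly zero outside the disk
    if vmt_peak_um > 0 and vmt_diameter_um > 0:
        radius_mm = vmt_diameter_um / 2000.0
        profile = np.where(
            r_mm <= radius_mm,
            0.5 * (1.0 + np.cos(np.pi * r_mm / radius_mm)),
            0.0,
        )
        z_ilm = z_ilm - vmt_peak_um * profile

    # gentle seeded undulation (low-order cosines, a few um) plus RPE tilt
    kx, ky = rng.uniform(0.3, 1.2, 2)
    phix, phiy = rng.uniform(0, 2 * np.pi, 2)
    amp = rng.uniform(1.0, 4.0)
    und = amp * np.cos(2 * np.pi * kx * x / geometry.extent_mm + phix) * np.cos(
        2 * np.pi * ky * y / geometry.extent_mm + phiy
    )
    z_ilm = z_ilm + und
    tilt = rng.uniform(-3.0, 3.0, 2)
    z_rpe = (
        ilm_base_um
        + thickness_um
        + tilt[0] * (x - cx) / geometry.extent_mm
        + tilt[1] * (y - cy) / geometry.extent_mm
    )
    return SurfaceSet(z_ilm=z_ilm, z_rpe=np.broadcast_to(z_rpe, geometry.shape).copy(), geometry=geometry)


# ---------------------------------------------------------------------------
# vessel network


def _disk_offsets(width: int) -> list[tuple[int, int]]:
    """Pixel offsets of a stamped stroke cross-section of the given width."""
    if width <= 1:
        return [(0, 0)]
    if width == 2:
        return [(0, 0), (0, 1), (1, 0), (1, 1)]
    r = width / 2.0
    span = range(-(width // 2), width // 2 + 1)
    return [(dy, dx) for dy in span for dx in span if dy * dy + dx * dx <= r * r + 0.6]


_WIDTH_OFFSETS = {w: _disk_offsets(w) for w in range(1, 10)}


def _stamp(grid: np.ndarray, yi: np.ndarray, xi: np.ndarray, width: int) -> None:
    n = grid.shape[0]
    for dy, dx in _WIDTH_OFFSETS[width]:
        grid[np.clip(yi + dy, 0, n - 1), np.clip(xi + dx, 0, n - 1)] = True


def _walk_batch(
    rng: np.random.Generator,
    grid: np.ndarray,
    n_walkers: int,
    steps: int,
    params: BranchParams,
    widths: np.ndarray | None = None,
) -> None:
    """Advance ``n_walkers`` correlated random walks, stamping their strokes."""
    n = grid.shape[0]
    fg_y, fg_x = np.nonzero(grid)
    n_branch = 0
    if len(fg_y) and params.branch_fraction > 0:
        n_branch = int(round(n_walkers * params.branch_fraction))
    starts = np.empty((n_walkers, 2))
    if n_branch:
        idx = rng.integers(0, len(fg_y), n_branch)
        starts[:n_branch, 0] = fg_y[idx]
        starts[:n_branch, 1] = fg_x[idx]
    starts[n_branch:] = rng.uniform(0, n - 1, (n_walkers - n_branch, 2))

    theta0 = rng.uniform(0, 2 * np.pi, n_walkers)
    ang = theta0[:, None] + np.cumsum(
        rng.normal(0.0, params.turn_sd_rad, (n_walkers, steps)), axis=1
    )
    ys = starts[:, 0:1] + np.cumsum(params.step_px * np.sin(ang), axis=1)
    xs = starts[:, 1:2] + np.cumsum(params.step_px * np.cos(ang), axis=1)
    yi = np.clip(np.rint(ys), 0, n - 1).astype(np.intp)
    xi = np.clip(np.rint(xs), 0, n - 1).astype(np.intp)

    if widths is None:
        widths = 1 + rng.choice(len(params.width_probs), n_walkers, p=params.width_probs)
    for w in np.unique(widths):
        sel = widths == w
        _stamp(grid, yi[sel].ravel(), xi[sel].ravel(), int(w))


def generate_vessel_network(
    geometry: ScanGeometry,
    target_density: float,
    faz: FAZRegion,
    branch_params: BranchParams | None = None,
    seed: int = 0,
) -> BinaryAngiogram:
    """Grow a branching capillary-like network to a target pixel density.

    The network is densified batch-by-batch until the foreground fraction
    *outside the FAZ* reaches ``target_density`` (always within +-0.02, in
    practice much tighter); the FAZ interior is kept strictly avascular.
    """
    if not 0.0 < target_density < 1.0:
        raise ValueError("target_density must lie strictly between 0 and 1")
    params = branch_params or BranchParams()
    rng = np.random.default_rng(seed)
    grid = np.zeros(geometry.shape, dtype=bool)
    faz_mask = faz.raster(geometry)
    outside = ~faz_mask
    n_outside = int(outside.sum())
    if n_outside == 0:
        raise ValueError("no area outside FAZ")
    needed = target_density * n_outside

    # coarse phase: adaptive batches; fine phase: single short walks.
    # a stroke of width w paints ~w new px per px of advance (before overlap)
    mean_width = float(
        np.dot(1 + np.arange(len(params.width_probs)), params.width_probs)
    )
    px_per_walker = params.steps_per_walk * params.step_px * mean_width
    for _ in range(params.max_batches):
        current = int(np.count_nonzero(grid & outside))
        deficit = needed - current
        if deficit <= max(2.0, 0.002 * n_outside):
            break
        if deficit > 30 * params.steps_per_walk:
            n_walkers = max(1, min(256, int(0.6 * deficit / px_per_walker)))
            before = current
            _walk_batch(rng, grid, n_walkers, params.steps_per_walk, params)
            grid[faz_mask] = False
            gained = int(np.count_nonzero(grid & outside)) - before
            if gained > 0:
                px_per_walker = 0.5 * px_per_walker + 0.5 * gained / n_walkers
        else:
            steps = int(np.clip(deficit / (2 * params.fine_width), 4, params.steps_per_walk))
            _walk_batch(rng, grid, 1, steps, params, widths=np.array([params.fine_width]))
            grid[faz_mask] = False
    else:
        raise RuntimeError("vessel growth failed to reach target density")
    grid[faz_mask] = False
    return BinaryAngiogram(grid, geometry)


# ---------------------------------------------------------------------------
# rendering


def render_angiogram(
    truth: BinaryAngiogram,
    blur_sigma_px: float,
    noise_sd: float,
    seed: int = 0,
) -> Angiogram:
    """Grayscale render of a truth network: optional blur + Gaussian noise.

    With zero blur and zero noise, foreground maps to 255 and background to
    0 exactly, so the mean-threshold pipeline recovers the truth image.
    """
    if blur_sigma_px < 0 or noise_sd < 0:
        raise ValueError("blur_sigma_px and noise_sd must be >= 0")
    img = truth.pixels.astype(np.float64) * 255.0
    if blur_sigma_px > 0:
        img = gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return Angiogram(np.clip(img, 0.0, 255.0), truth.geometry, "gray")


# ---------------------------------------------------------------------------
# FAZ generation


def generate_faz(
    area_mm2: float,
    geometry: ScanGeometry,
    seed: int = 0,
    n_vertices: int = 12,
) -> FAZRegion:
    """Jittered circle-ish polygon of exactly ``area_mm2``, at scan centre."""
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    ang = ang + rng.uniform(-0.12, 0.12, n_vertices)
    radii = 1.0 + rng.uniform(-0.22, 0.22, n_vertices)
    v = np.stack([radii * np.cos(ang), radii * np.sin(ang)], axis=1)
    from .faz import polygon_area  # local import avoids cycle at module load

    v = v * np.sqrt(area_mm2 / polygon_area(v))
    cx, cy = geometry.center_mm
    return FAZRegion(v + np.array([cx, cy]))


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticCohort:
    """A paired baseline/follow-up cohort with full ground-truth ledger.

    ``images`` maps (eye_id, timepoint, plexus) -> Angiogram; ``fazes`` maps
    (eye_id, timepoint) -> FAZRegion; ``ledger`` is a tidy DataFrame with
    one row per image recording targeted and realized true densities.
    """

    geometry: ScanGeometry
    images: dict[tuple[str, str, str], Angiogram]
    truths: dict[tuple[str, str, str], BinaryAngiogram]
    fazes: dict[tuple[str, str], FAZRegion]
    surfaces: dict[str, SurfaceSet]
    ledger: pd.DataFrame
    ages: dict[str, float]
    groups: dict[str, str]
    seed: int

    def eye_ids(self) -> list[str]:
        return sorted(self.groups)

    def ground_truth(self, eye_id: str, timepoint: str) -> SyntheticGroundTruth:
        """Per-eye ground-truth record (realized densities, FAZ, adhesion)."""
        sub = self.ledger[
            (self.ledger["eye_id"] == eye_id) & (self.ledger["timepoint"] == timepoint)
        ].set_index("plexus")
        if sub.empty:
            raise KeyError(f"no ledger rows for {eye_id!r} at {timepoint!r}")
        faz = self.fazes[(eye_id, timepoint)]

        def density(plexus: str) -> float:
            return float(sub.loc[plexus, "true_density"]) if plexus in sub.index else np.nan

        return SyntheticGroundTruth(
            true_density_scp=density("SCP"),
            true_density_dcp=density("DCP"),
            true_density_cc=density("CC"),
            faz_polygon=faz.vertices_mm,
            faz_area_mm2=faz.area_mm2,
            vmt_adhesion_diameter_um=float(sub["vmt_adhesion_diameter_um"].iloc[0]),
            seed=self.seed,
        )

    def measure(self) -> pd.DataFrame:
        """Run the full measurement pipeline in memory; tidy CSV layout."""
        rows = []
        for eye_id in self.eye_ids():
            for timepoint in ("baseline", "month1"):
                imgs = {
                    p: self.images[k]
                    for p in PLEXUSES
                    if (k := (eye_id, timepoint, p)) in self.images
                }
                if not imgs:
                    continue
                faz = self.fazes[(eye_id, timepoint)]
                for m in measure_eye(
                    imgs, faz, self.geometry, eye_id, timepoint, tuple(imgs)
                ):
                    rows.append(
                        {
                            "eye_id": m.eye_id,
                            "group": self.groups[eye_id],
                            "age": self.ages[eye_id],
                            "timepoint": m.timepoint,
                            "plexus": m.plexus,
                            "extent_mm": m.extent_mm,
                            "density": m.density,
                            "faz_area_mm2": m.faz_area_mm2,
                            "threshold": m.threshold,
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> Path:
        """Write images (TIFF), FAZ polygons (JSON), cohort CSV and ledger."""
        import tifffile

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "faz").mkdir(parents=True, exist_ok=True)
        rows = []
        faz_paths: dict[tuple[str, str], str] = {}
        for (eye_id, timepoint), faz in sorted(self.fazes.items()):
            rel = f"faz/{eye_id}_{timepoint}.json"
            faz.to_json(out / rel)
            faz_paths[(eye_id, timepoint)] = rel
        for (eye_id, timepoint, plexus), img in sorted(self.images.items()):
            rel = f"images/{eye_id}_{timepoint}_{plexus}.tiff"
            tifffile.imwrite(
                out / rel, np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
            )
            rows.append(
                {
                    "eye_id": eye_id,
                    "group": self.groups[eye_id],
                    "age": self.ages[eye_id],
                    "timepoint": timepoint,
                    "plexus": plexus,
                    "extent_mm": self.geometry.extent_mm,
                    "n_px": self.geometry.n_px,
                    "image_path": rel,
                    "faz_path": faz_paths[(eye_id, timepoint)],
                }
            )
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
        self.ledger.to_json(out / "ledger.json", orient="records", indent=1)
        if self.surfaces:
            (out / "surfaces").mkdir(exist_ok=True)
            for eye_id, s in sorted(self.surfaces.items()):
                np.savetxt(out / "surfaces" / f"{eye_id}_ilm.csv", s.z_ilm, delimiter=",")
                np.savetxt(out / "surfaces" / f"{eye_id}_rpe.csv", s.z_rpe, delimiter=",")
        return out


def _eye_truth_densities(
    rng: np.random.Generator,
    means: Mapping[str, float],
    sd: float,
    plexuses: Sequence[str],
) -> dict[str, float]:
    return {
        p: float(np.clip(rng.normal(means[p], sd), 0.02, 0.98)) for p in plexuses
    }


def generate_cohort(
    n_eyes: int,
    geometry: ScanGeometry,
    effect: EffectModel | None = None,
    baseline_truth_params: CohortParams | None = None,
    seed: int = 0,
    include_controls: bool = True,
    plexuses: Sequence[str] = PLEXUSES,
    branch_params: BranchParams | None = None,
    with_surfaces: bool = False,
) -> SyntheticCohort:
    """Simulate a paired baseline -> 1-month cohort of VMT-like eyes.

    Per-eye true densities are drawn around the population means with the
    configured between-eye SD; the follow-up target is the baseline truth
    plus the per-plexus effect shift (controls are always unshifted).  All
    ground truth is recorded in the ledger; output is deterministic under
    ``seed``.
    """
    if n_eyes < 2:
        raise ValueError("n_eyes must be >= 2 (paired statistics need pairs)")
    effect = effect if effect is not None else EffectModel()
    params = baseline_truth_params or CohortParams()
    rng = np.random.default_rng(seed)

    images: dict[tuple[str, str, str], Angiogram] = {}
    truths: dict[tuple[str, str, str], BinaryAngiogram] = {}
    fazes: dict[tuple[str, str], FAZRegion] = {}
    surfaces: dict[str, SurfaceSet] = {}
    ages: dict[str, float] = {}
    groups: dict[str, str] = {}
    ledger_rows = []

    eye_specs: list[tuple[str, str, float]] = []  # (eye_id, group, age)
    for i in range(n_eyes):
        age = float(np.round(rng.normal(*params.age_vmt_years)))
        eye_specs.append((f"vmt{i + 1:02d}", "vmt", age))
    if include_controls:
        for i in range(n_eyes):
            # age-matched +-1 to the same-index study eye
            age = eye_specs[i][2] + float(rng.integers(-1, 2))
            eye_specs.append((f"ctl{i + 1:02d}", "control", age))

    for eye_id, group, age in eye_specs:
        groups[eye_id] = group
        ages[eye_id] = age
        vmt_diam = (
            float(rng.uniform(*params.vmt_diameter_range_um)) if group == "vmt" else 0.0
        )
        means = (
            params.mean_density_vmt if group == "vmt" else params.mean_density_control
        )
        base_d = _eye_truth_densities(rng, means, params.between_eye_sd, plexuses)
        faz_mean, faz_sd = (
            params.faz_area_vmt_mm2 if group == "vmt" else params.faz_area_control_mm2
        )
        base_faz_area = float(np.clip(rng.normal(faz_mean, faz_sd), 0.02, None))
        faz_seed = int(rng.integers(0, 2**31))
        if with_surfaces:
            surfaces[eye_id] = generate_surfaces(
                geometry,
                foveal_pit_depth_um=float(rng.uniform(60, 100)),
                vmt_peak_um=float(rng.uniform(40, 80)) if group == "vmt" else 0.0,
                vmt_diameter_um=vmt_diam,
                seed=int(rng.integers(0, 2**31)),
            )
        for timepoint in ("baseline", "month1"):
            faz_area = base_faz_area
            if timepoint == "month1" and group == "vmt":
                faz_area = max(0.02, base_faz_area + effect.faz_shift_mm2)
            faz = generate_faz(faz_area, geometry, seed=faz_seed)
            fazes[(eye_id, timepoint)] = faz
            realized: dict[str, float] = {}
            for plexus in plexuses:
                target = base_d[plexus]
                if timepoint == "month1" and group == "vmt":
                    target = target + effect.shift(plexus)
                if not 0.0 < target < 1.0:
                    raise ValueError("shifted density leaves (0, 1)")
                net_seed = int(rng.integers(0, 2**31))
                net = generate_vessel_network(
                    geometry, target, faz, branch_params, seed=net_seed
                )
                outside = ~faz.raster(geometry)
                true_d = float(net.pixels[outside].mean())
                realized[plexus] = true_d
                img = render_angiogram(
                    net,
                    params.blur_sigma_px,
                    effect.noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                )
                truths[(eye_id, timepoint, plexus)] = net
                images[(eye_id, timepoint, plexus)] = img
                ledger_rows.append(
                    {
                        "eye_id": eye_id,
                        "group": group,
                        "age": age,
                        "timepoint": timepoint,
                        "plexus": plexus,
                        "target_density": target,
                        "true_density": true_d,
                        "faz_area_mm2": faz.area_mm2,
                        "vmt_adhesion_diameter_um": vmt_diam,
                    }
                )

    return SyntheticCohort(
        geometry=geometry,
        images=images,
        truths=truths,
        fazes=fazes,
        surfaces=surfaces,
        ledger=pd.DataFrame(ledger_rows),
        ages=ages,
        groups=groups,
        seed=seed,
    )
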