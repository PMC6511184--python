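"""End-to-end orchestration: measure a cohort from disk, or simulate one
and push it through measurement and statistics in a single call.

Outputs are deterministic for fixed inputs and seed; QC-failed eyes are
excluded from the measurement table and listed in the run log (the study
excluded whole eyes for segmentation errors, not pixels).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binarize import (
    Angiogram,
    THRESHOLD_METHODS,
    apply_faz_mask,
    binarize,
    to_reference_channel,
)
from .density import perfusion_density
from .faz import FAZRegion
from .geometry import ScanGeometry
from .io import PipelineConfig, RunLog, read_image, read_surface_grid
from .slabs import SurfaceSet, derive_boundaries, validate_segmentation
from .stats import cohort_report_markdown, summarize_cohort
from .synthetic import CohortParams, EffectModel, generate_cohort

__all__ = ["run_measure", "run_end_to_end"]


def _row_geometry(row: pd.Series, fallback: ScanGeometry) -> ScanGeometry:
    if "extent_mm" in row and "n_px" in row and not pd.isna(row["n_px"]):
        return ScanGeometry(float(row["extent_mm"]), int(row["n_px"]))
    return fallback


def _eye_qc(base: Path, rows: pd.DataFrame, geometry: ScanGeometry, log: RunLog, eye_id: str) -> bool:
    """Run segmentation QC when surface grids are listed; True = keep eye."""
    if "ilm_path" not in rows.columns or rows["ilm_path"].isna().all():
        return True
    first = rows.iloc[0]
    try:
        s = SurfaceSet(
            read_surface_grid(base / str(first["ilm_path"])),
            read_surface_grid(base / str(first["rpe_path"])),
            geometry,
        )
    except Exception as exc:  # unreadable surface: record, keep the eye
        log.log_error(str(first.get("ilm_path")), f"surface read failed: {exc}")
        return True
    qc = validate_segmentation(derive_boundaries(s), s)
    log.qc[eye_id] = {"ok": qc.ok, "reason": qc.reason}
    return qc.ok


def run_measure(config: PipelineConfig) -> tuple[pd.DataFrame, RunLog]:
    """Measure every image listed in the cohort CSV.

    The CSV needs columns eye_id, group, timepoint, plexus, image_path,
    faz_path (paths relative to the CSV); optional age, extent_mm, n_px,
    ilm_path, rpe_path.  Per-file failures are recorded in the run log and
    the run continues.  Writes ``measurements.csv`` and ``runlog.json``.
    """
    if config.cohort_csv is None:
        raise ValueError("config.cohort_csv is required")
    csv_path = Path(config.cohort_csv)
    base = csv_path.parent
    table = pd.read_csv(csv_path)
    threshold_fn = THRESHOLD_METHODS[config.threshold_method]
    log = RunLog(seed=config.seed)
    rows_out = []
    for eye_id, eye_rows in table.groupby("eye_id", sort=True):
        geometry = _row_geometry(eye_rows.iloc[0], config.geometry())
        if not _eye_qc(base, eye_rows, geometry, log, str(eye_id)):
            continue
        for _, row in eye_rows.sort_values(["timepoint", "plexus"]).iterrows():
            img_path = base / str(row["image_path"])
            try:
                arr = read_image(img_path)
                layout = "rgb" if arr.ndim == 3 else "gray"
                img = Angiogram(arr.astype(float), geometry, layout)
                faz = FAZRegion.from_json(base / str(row["faz_path"]))
                gray = to_reference_channel(img)
                thr = threshold_fn(gray)
                masked = apply_faz_mask(binarize(gray, thr), faz)
                density = perfusion_density(masked)
            except Exception as exc:
                log.log_error(str(row["image_path"]), str(exc))
                continue
            is_scp = row["plexus"] == "SCP"
            rows_out.append(
                {
                    "eye_id": row["eye_id"],
                    "group": row.get("group", ""),
                    "age": row.get("age", np.nan),
                    "timepoint": row["timepoint"],
                    "plexus": row["plexus"],
                    "extent_mm": geometry.extent_mm,
                    "density": density,
                    "faz_area_mm2": faz.area_mm2 if is_scp else np.nan,
                    "threshold": thr,
                }
            )
            log.log_image(
                image=str(row["image_path"]),
                eye_id=str(row["eye_id"]),
                timepoint=str(row["timepoint"]),
                plexus=str(row["plexus"]),
                threshold=thr,
                density=density,
            )
    measurements = pd.DataFrame(rows_out)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measurements.to_csv(out / "measurements.csv", index=False, float_format="%.10g")
    log.to_json(out / "runlog.json")
    return measurements, log


def run_end_to_end(
    n_eyes: int = 16,
    extent_mm: float = 6.0,
    n_px: int | None = None,
    effect: EffectModel | None = None,
    params: CohortParams | None = None,
    seed: int = 0,
    out_dir: str | Path = "octaperf_out",
    include_controls: bool = True,
    with_surfaces: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate -> write -> measure -> cohort statistics, in one invocation.

    Returns (measurements, summary); everything is written under
    ``out_dir`` (images, cohort CSV, measurements, summary CSV, report).
    """
    out = Path(out_dir)
    geometry = ScanGeometry(extent_mm, n_px) if n_px else ScanGeometry.preset(extent_mm)
    cohort = generate_cohort(
        n_eyes,
        geometry,
        effect=effect,
        baseline_truth_params=params,
        seed=seed,
        include_controls=include_controls,
        with_surfaces=with_surfaces,
    )
    cohort.write(out)
    config = PipelineConfig(
        extent_mm=extent_mm,
        n_px=geometry.n_px,
        seed=seed,
        cohort_csv=str(out / "cohort.csv"),
        out_dir=str(out),
    )
    config.to_json(out / "config.json")
    measurements, _ = run_measure(config)
    summary = summarize_cohort(measurements)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    (out / "report.md").write_text(cohort_report_markdown(summary))
    return measurements, summary
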