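# octaperf

Quantification pipeline for OCT-angiography perfusion density, built around
the workflow used in studies of vitreomacular traction (VMT) before/after
intravitreal ocriplasmin: axial slab segmentation of three capillary
plexuses (SCP, DCP, choriocapillaris), mean-threshold binarization with
foveal-avascular-zone (FAZ) exclusion, FAZ-subtracted perfusion density,
and paired nonparametric cohort statistics. Because no patient scans are
publicly available, the package ships a synthetic OCT-A generator with a
full ground-truth ledger so every stage can be validated end to end.

## What's inside

| Module | Purpose |
|---|---|
| `octaperf.geometry` | `ScanGeometry`: physical extent / pixel-grid contract (3×3 → 245 px, 6×6 mm → 350 px presets) |
| `octaperf.slabs` | Slab boundaries from ILM/RPE surfaces (`OPL = RPE − 110 µm`, `IPL = ILM + 0.70·(OPL − ILM)`, CC = `[RPE+29, RPE+49)` µm), per-A-scan QC, en-face projection |
| `octaperf.binarize` | Red-reference-channel reduction, global mean threshold (strict `>`), FAZ exclusion masking |
| `octaperf.faz` | Polygon (shoelace) FAZ area in mm², pixel-center rasterization |
| `octaperf.density` | FAZ-subtracted perfusion density, per-eye measurement over all three plexuses |
| `octaperf.stats` | Exact/approximate Wilcoxon signed-rank, Mann-Whitney, Spearman; noncentral-t power; ±1-year age-matching check; cohort summary tables |
| `octaperf.synthetic` | Surface maps with foveal pit + VMT deformation, branching random-walk vessel networks, noisy renders, paired baseline→1-month cohorts with ground truth |
| `octaperf.pipeline` / `octaperf.cli` | Disk-based measurement runs, provenance logging, end-to-end orchestration |

## CLI

```bash
# simulate a 16-eye paired cohort (plus age-matched controls) at 6x6 mm
octaperf simulate --eyes 16 --extent 6 --effect-scp -0.014 --seed 1 --out runs/sim

# measure every image listed in the cohort CSV
octaperf measure --cohort runs/sim/cohort.csv --extent 6 --out runs/meas

# summary tables: mean ± SD, paired Wilcoxon, between-group Mann-Whitney
octaperf cohort --measurements runs/meas/measurements.csv --out runs/report

# or everything in one go
octaperf report --eyes 16 --extent 6 --effect-scp -0.014 --seed 1 --out runs/e2e
```

Images are lossless 8-bit TIFF/PNG (JPEG is accepted with a warning — lossy
compression perturbs the mean threshold). FAZ polygons are JSON vertex
lists in mm; measurements and summaries are tidy CSV; the run log records
the threshold used for every image so results are fully traceable.

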