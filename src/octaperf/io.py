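"""Image and table I/O plus run configuration and provenance logging.

Images are lossless 8-bit TIFF/PNG; JPEG is accepted with a logged warning
because lossy compression perturbs the mean threshold (a documented
reproducibility hazard of the original workflow, not a feature).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .geometry import ScanGeometry

__all__ = ["PipelineConfig", "RunLog", "read_image", "write_image", "read_surface_grid"]

logger = logging.getLogger(__name__)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit gray or RGB image; returns (H, W) or (H, W, 3) uint8."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".jpg", ".jpeg"}:
        logger.warning(
            "%s is JPEG; lossy compression perturbs the mean threshold", path.name
        )
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ValueError(f"{path.name}: unsupported layout (RGBA)")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path.name}: unsupported image shape {arr.shape}")
    return arr


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a grayscale or binary image losslessly (TIFF or PNG by suffix)."""
    path = Path(path)
    if pixels.dtype == bool:
        arr = (pixels * np.uint8(255)).astype(np.uint8)
    else:
        arr = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def read_surface_grid(path: str | Path) -> np.ndarray:
    """Read a 2-D float depth grid (um) from CSV or float TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, delimiter=",", dtype=float)


@dataclass
class PipelineConfig:
    """Serializable run configuration; survives a write/read round trip."""

    extent_mm: float = 6.0
    n_px: int | None = None  # None -> device preset for the extent
    threshold_method: str = "mean"
    projection_method: str = "max"
    seed: int = 0
    cohort_csv: str | None = None
    out_dir: str = "octaperf_out"
    report_markdown: bool = True

    def geometry(self) -> ScanGeometry:
        if self.n_px is None:
            return ScanGeometry.preset(self.extent_mm)
        return ScanGeometry(self.extent_mm, self.n_px)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RunLog:
    """Per-run provenance: thresholds, QC outcomes, errors, versions, seed.

    Every measurement row is traceable to an image entry here via its path.
    """

    seed: int
    entries: list[dict] = field(default_factory=list)
    qc: dict[str, dict] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)
    versions: dict[str, str] = field(default_factory=dict)
    started_utc: str = ""

    def __post_init__(self) -> None:
        if not self.versions:
            from . import __version__

            self.versions = {"octaperf": __version__, "numpy": np.__version__}
        if not self.started_utc:
            self.started_utc = datetime.now(timezone.utc).isoformat()

    def log_image(self, **kwargs) -> None:
        self.entries.append(kwargs)

    def log_error(self, path: str, message: str) -> None:
        self.errors.append({"path": path, "error": message})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
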