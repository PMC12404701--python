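"""Readers/writers for the pipeline's table formats, plus configuration.

All tables are UTF-8 comma-separated with ISO-8601 dates. Readers check
for required columns and raise listing anything missing; unknown extra
columns are tolerated with a warning so the deposited datasets' wider
column sets load unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

DETECTION_REQUIRED = ["transect_id", "frame", "taxon", "count", "confidence"]
DEPTH_REQUIRED = ["transect_id", "frame", "depth_m"]
OCCURRENCE_REQUIRED = [
    "transect_id", "taxon", "depth_m", "mean_count", "max_count", "frames_at_depth",
]
GBIF_REQUIRED = ["species", "decimalLatitude", "decimalLongitude"]
TRAIT_REQUIRED = ["taxon"]


def _read_checked(path, required: list[str], name: str, warn_extra: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} file {path} missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if warn_extra and extra:
        warnings.warn(f"{name} file {path} has unrecognized columns {extra}", stacklevel=2)
    return df


def read_detections(path) -> pd.DataFrame:
    return _read_checked(path, DETECTION_REQUIRED, "detection")


def read_depth_series(path) -> pd.DataFrame:
    df = _read_checked(path, DEPTH_REQUIRED, "depth series")
    bad = df["frame"].isna() | pd.to_numeric(df["frame"], errors="coerce").isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based plus header
        raise ValueError(f"malformed depth rows (non-numeric frame) at lines {lines}")
    df["frame"] = df["frame"].astype(int)
    return df


def read_occurrences(path) -> pd.DataFrame:
    return _read_checked(path, OCCURRENCE_REQUIRED, "occurrence")


def read_gbif(path) -> pd.DataFrame:
    """GBIF simple-CSV (tab- or comma-separated); individualCount stays
    missing (not zero) where absent."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in GBIF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"GBIF file {path} missing required columns: {missing}")
    if "individualCount" in df.columns:
        df["individualCount"] = pd.to_numeric(df["individualCount"], errors="coerce")
    return df


def read_traits(path) -> pd.DataFrame:
    return _read_checked(path, TRAIT_REQUIRED, "trait")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the field-standard defaults."""

    detections_path: str | None = None
    depths_path: str | None = None
    raster_path: str | None = None
    gbif_path: str | None = None
    traits_path: str | None = None
    out_dir: str = "benthotrend_out"
    simulate: bool = True  # generate inputs when paths are absent
    confidence_threshold: float = 0.60
    iou_min: float = 0.5
    max_cell_range_c: float = 2.0
    max_uncertainty_m: float = 100.0
    max_isolation_km: float = 3000.0
    thin_radius_km: float = 1.0
    percentiles: tuple[int, int, int] = (16, 50, 84)
    depth_window: tuple[float, float] = (0.0, 250.0)
    max_step_m: float = 10.0
    site: dict = field(
        default_factory=lambda: {
            "decimalLatitude": 58.87,
            "decimalLongitude": 11.05,
            "datasetName": "benthotrend-synthetic",
        }
    )
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.confidence_threshold <= 1):
            raise ValueError("confidence_threshold outside [0, 1]")
        if not (0 < self.iou_min <= 1):
            raise ValueError("iou_min outside (0, 1]")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["percentiles"] = list(d["percentiles"])
        d["depth_window"] = list(d["depth_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        if "depth_window" in d:
            d["depth_window"] = tuple(d["depth_window"])
        return cls(**d)
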