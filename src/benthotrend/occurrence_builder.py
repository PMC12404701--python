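"""Build per-transect, per-depth Darwin Core occurrences from detections.

Per-frame detector output is confidence-filtered (default threshold 0.60,
the operational threshold used when applying the detector to footage),
zero-expanded so every (frame, taxon) pair is present, joined to the
frame-depth map, and aggregated per (transect, taxon, integer depth) into
mean count per frame and max count. Absence records (mean 0) are retained:
zeros carry information for the trend models, and can be dropped on export.
"""

from __future__ import annotations

import hashlib
from datetime import date, timedelta

import numpy as np
import pandas as pd

DEFAULT_CONFIDENCE = 0.60

DETECTION_COLUMNS = ["transect_id", "frame", "taxon", "count", "confidence"]


def filter_by_confidence(
    detections: pd.DataFrame, threshold: float = DEFAULT_CONFIDENCE
) -> pd.DataFrame:
    """Drop detections with confidence below ``threshold`` (keeps >=)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"confidence threshold must lie in [0, 1], got {threshold}")
    return detections[detections["confidence"] >= threshold].reset_index(drop=True)


def zero_expand(
    detections: pd.DataFrame,
    taxa: list[str],
    frames: dict[object, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Expand to one row per (transect, frame, taxon), filling count 0.

    ``frames`` maps transect_id to its full frame list; without it, the
    frames observed in ``detections`` are used (frames in which nothing at
    all was detected are then unrepresentable — pass the frame-depth map's
    frames for a faithful expansion). Detections of a taxon outside
    ``taxa`` are an error. Idempotent on already-expanded input.
    """
    unknown = set(detections["taxon"]) - set(taxa)
    if unknown:
        raise ValueError(f"detections contain taxa not in the taxon list: {sorted(unknown)}")
    counts = (
        detections.groupby(["transect_id", "frame", "taxon"], as_index=False)["count"].sum()
        if len(detections)
        else pd.DataFrame(columns=["transect_id", "frame", "taxon", "count"])
    )
    if frames is None:
        frames = {
            t: g["frame"].unique() for t, g in detections.groupby("transect_id")
        }
    blocks = []
    for transect_id, frame_list in frames.items():
        frame_list = np.sort(np.unique(np.asarray(frame_list)))
        full = pd.MultiIndex.from_product(
            [frame_list, list(taxa)], names=["frame", "taxon"]
        ).to_frame(index=False)
        full.insert(0, "transect_id", transect_id)
        blocks.append(full)
    if not blocks:
        return pd.DataFrame(columns=["transect_id", "frame", "taxon", "count"])
    grid = pd.concat(blocks, ignore_index=True)
    out = grid.merge(counts, on=["transect_id", "frame", "taxon"], how="left")
    out["count"] = pd.to_numeric(out["count"], errors="coerce").fillna(0)
    if (out["count"] % 1 == 0).all():
        out["count"] = out["count"].astype(int)
    return out


def aggregate_by_depth(
    expanded: pd.DataFrame,
    frame_depths: pd.DataFrame,
    transects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean and max count per (transect, taxon, integer depth).

    ``frame_depths`` has columns ``transect_id, frame, depth_m, excluded``
    (the frame-depth map); excluded frames are dropped. A frame carrying
    detections but lacking a depth and not excluded is an error. The
    optional ``transects`` table (``transect_id, year, day_of_year``)
    is merged onto the result for the trend models.

    mean_count is total detections at the depth divided by the number of
    frames at the depth, so sum(mean_count * frames_at_depth) over depths
    conserves the transect's post-filter detection total per taxon.
    """
    fd = frame_depths[["transect_id", "frame", "depth_m", "excluded"]]
    merged = expanded.merge(fd, on=["transect_id", "frame"], how="left", indicator=True)
    orphan = merged["_merge"] == "left_only"
    if orphan.any():
        bad = merged.loc[orphan, ["transect_id", "frame"]].drop_duplicates()
        raise ValueError(
            f"{len(bad)} frame(s) have detections but no depth assignment, e.g. "
            f"{bad.iloc[0].to_dict()}"
        )
    merged = merged[~merged["excluded"].astype(bool)]
    grouped = merged.groupby(["transect_id", "taxon", "depth_m"], observed=True)
    records = grouped["count"].agg(
        mean_count="mean", max_count="max", frames_at_depth="size"
    ).reset_index()
    records["max_count"] = records["max_count"].astype(int)
    records["depth_m"] = records["depth_m"].astype(int)
    if transects is not None:
        records = records.merge(
            transects[["transect_id", "year", "day_of_year"]], on="transect_id", how="left"
        )
    return records


def _occurrence_id(dataset: str, transect_id, taxon: str, depth_m: int) -> str:
    key = f"{dataset}:{transect_id}:{taxon}:{depth_m}".encode()
    return hashlib.sha1(key).hexdigest()[:16]


def _event_date(year: int, day_of_year: int) -> str:
    return (date(int(year), 1, 1) + timedelta(days=int(day_of_year) - 1)).isoformat()


def to_darwin_core(
    records: pd.DataFrame,
    site: dict,
    *,
    include_absences: bool = True,
) -> pd.DataFrame:
    """Darwin Core occurrence table from aggregated depth records.

    ``site`` must supply ``decimalLatitude``, ``decimalLongitude`` and
    ``datasetName``. occurrenceIDs are deterministic hashes of
    (dataset, transect, taxon, depth). organismQuantity carries the mean
    detections per frame, individualCount the max count; records with
    mean 0 get occurrenceStatus "absent".
    """
    for key in ("decimalLatitude", "decimalLongitude", "datasetName"):
        if key not in site:
            raise ValueError(f"site metadata missing '{key}'")
    recs = records if include_absences else records[records["mean_count"] > 0]
    out = pd.DataFrame(
        {
            "occurrenceID": [
                _occurrence_id(site["datasetName"], t, x, d)
                for t, x, d in zip(recs["transect_id"], recs["taxon"], recs["depth_m"])
            ],
            "datasetName": site["datasetName"],
            "scientificName": recs["taxon"].to_numpy(),
            "eventDate": [
                _event_date(y, d) for y, d in zip(recs["year"], recs["day_of_year"])
            ],
            "decimalLatitude": site["decimalLatitude"],
            "decimalLongitude": site["decimalLongitude"],
            "minimumDepthInMeters": recs["depth_m"].to_numpy(),
            "maximumDepthInMeters": recs["depth_m"].to_numpy(),
            "organismQuantity": recs["mean_count"].to_numpy(),
            "organismQuantityType": "mean detections per frame",
            "individualCount": recs["max_count"].to_numpy(),
            "occurrenceStatus": np.where(recs["mean_count"] > 0, "present", "absent"),
        }
    )
    return out
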