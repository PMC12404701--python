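"""Abundance-weighted depth distributions and national comparisons.

A taxon's depth distribution is summarised by the 50th percentile of its
abundance-by-depth profile (median depth) and the 16th/84th percentiles —
the bounds of the central 68% of detections, i.e. mean +/- 1 sd were the
profile normal. Abundance is the mean detections per frame per metre of
depth; profiles from several transects are pooled frame-weighted, since a
per-frame rate is naturally supported by frame counts. The same percentile
statistic applied to a national occurrence download (depths repeated by
individualCount, missing counts treated as 1, the study's own dataset
excluded by its datasetKey) gives the comparison distribution.

Percentile convention: smallest depth whose cumulative abundance fraction
reaches q/100 (a lower-step inverse of the discrete CDF) — reproducible on
integer-metre data and invariant to positive scaling of abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PERCENTILES = (16, 50, 84)


@dataclass(frozen=True)
class DepthDistribution:
    """Median depth and central-68% bounds for one taxon."""

    taxon: str
    lower_m: float
    median_m: float
    upper_m: float
    source: str = "modeled"

    def __post_init__(self):
        if not (self.lower_m <= self.median_m <= self.upper_m):
            raise ValueError("depth percentiles must be ordered lower <= median <= upper")

    def interval(self) -> tuple[float, float]:
        return (self.lower_m, self.upper_m)

    def formatted(self) -> str:
        return f"{self.median_m:.0f} ({self.lower_m:.0f}-{self.upper_m:.0f})"


def pooled_abundance_profile(records: pd.DataFrame, taxon: str) -> pd.DataFrame:
    """Frame-weighted abundance-by-depth profile pooled across transects.

    abundance(d) = sum_t mean_count * frames_at_depth / sum_t frames_at_depth.
    Depths with no frame coverage are simply absent (not zero).
    """
    sub = records[records["taxon"] == taxon]
    if len(sub) == 0:
        raise ValueError(f"no records for taxon {taxon!r}")
    sub = sub.assign(total=sub["mean_count"] * sub["frames_at_depth"])
    g = sub.groupby("depth_m")[["total", "frames_at_depth"]].sum()
    return pd.DataFrame(
        {
            "depth_m": g.index.to_numpy(),
            "abundance": (g["total"] / g["frames_at_depth"]).to_numpy(),
            "frames": g["frames_at_depth"].to_numpy(),
        }
    )


def weighted_quantiles(values, weights, qs) -> np.ndarray:
    """Lower-step quantiles of a discrete weighted distribution.

    For each q in percent, returns the smallest value whose cumulative
    weight fraction is >= q/100.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("no detections: total weight is zero")
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cumfrac = np.cumsum(weights) / total
    out = np.empty(len(qs), dtype=float)
    for i, q in enumerate(qs):
        # tiny epsilon shields the >= comparison from cumsum round-off
        out[i] = values[np.searchsorted(cumfrac, q / 100.0 - 1e-12, side="left")]
    return out


def weighted_depth_percentiles(
    profile: pd.DataFrame,
    taxon: str | None = None,
    qs: tuple[int, ...] = DEFAULT_PERCENTILES,
    source: str = "modeled",
) -> DepthDistribution:
    """Depth distribution (16/50/84 by default) from an abundance profile."""
    lower, median, upper = weighted_quantiles(
        profile["depth_m"], profile["abundance"], sorted(qs)
    )
    return DepthDistribution(
        taxon=taxon or "", lower_m=lower, median_m=median, upper_m=upper, source=source
    )


def national_depth_percentiles(
    gbif: pd.DataFrame,
    species: list[str],
    taxon: str | None = None,
    exclude_dataset_key: str | None = None,
    qs: tuple[int, ...] = DEFAULT_PERCENTILES,
) -> DepthDistribution:
    """Depth distribution of a taxon from a national occurrence download.

    Rows for any of the taxon's ``species`` are pooled; the study's own
    records are removed via ``exclude_dataset_key``; occurrences missing
    individualCount count as 1; the depth of each occurrence is repeated
    individualCount times before taking percentiles.
    """
    sub = gbif[gbif["species"].isin(species)]
    if exclude_dataset_key is not None and "datasetKey" in sub.columns:
        sub = sub[sub["datasetKey"] != exclude_dataset_key]
    sub = sub[sub["depth"].notna()]
    if len(sub) == 0:
        raise ValueError(f"no occurrences with depth for species {species}")
    counts = pd.to_numeric(sub.get("individualCount"), errors="coerce").fillna(1)
    counts = counts.clip(lower=0)
    lower, median, upper = weighted_quantiles(sub["depth"], counts, sorted(qs))
    return DepthDistribution(
        taxon=taxon or "", lower_m=lower, median_m=median, upper_m=upper, source="national"
    )


def compare_intervals(
    modeled: DepthDistribution, national: DepthDistribution
) -> tuple[bool, str]:
    """Overlap of the central-68% intervals and the direction of mismatch.

    Intervals are closed: touching endpoints overlap. Direction is
    "deeper" / "shallower" (modeled relative to national) when disjoint,
    else "overlapping".
    """
    lo_m, hi_m = modeled.interval()
    lo_n, hi_n = national.interval()
    if hi_m >= lo_n and hi_n >= lo_m:
        return True, "overlapping"
    return False, "deeper" if lo_m > hi_n else "shallower"


def depth_distribution_table(distributions: list[DepthDistribution]) -> pd.DataFrame:
    """Summary table of "median (lower-upper)" strings per taxon and source."""
    rows = [
        {
            "taxon": d.taxon,
            "source": d.source,
            "median_m": d.median_m,
            "lower_m": d.lower_m,
            "upper_m": d.upper_m,
            "formatted": d.formatted(),
        }
        for d in distributions
    ]
    return pd.DataFrame(rows)
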