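"""Register sparse depth-overlay readings to every video frame.

The depth overlay of archived ROV footage is read at a regular frame
interval; readings may be missing or corrupt (character-recognition
misreads). The chain here is: validate readings against a plausibility
window and a step-outlier rule, linearly interpolate on frame index
between accepted readings (no extrapolation beyond the first/last one),
and round to integer metres (half away from zero). Frames outside the
accepted span, or masked out during habitat review, are flagged excluded
and dropped from downstream aggregation.

Defaults: plausibility window (0, 250] m, a little beyond the 247 m
maximum of the surveyed fjord; step-outlier threshold 10 m against both
neighbouring accepted readings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUS_PARSED = "parsed"
STATUS_MISSING = "missing"
STATUS_REJECTED = "rejected"

DEFAULT_WINDOW = (0.0, 250.0)
DEFAULT_MAX_STEP = 10.0


def validate_readings(
    readings: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    max_step_m: float = DEFAULT_MAX_STEP,
) -> pd.DataFrame:
    """Classify raw readings as parsed / missing / rejected (with reason).

    ``readings`` needs columns ``frame`` and ``depth_m`` sorted by frame;
    ``depth_m`` may contain NaN or non-numeric strings. A numeric reading
    is rejected when it falls outside the open/closed window
    ``(min, max]`` or when it jumps more than ``max_step_m`` from *every*
    neighbouring otherwise-valid reading (a lone spike between plausible
    values — the typical misread signature).
    """
    if "frame" not in readings.columns or "depth_m" not in readings.columns:
        raise ValueError("readings need columns 'frame' and 'depth_m'")
    frames = readings["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise ValueError("readings must be sorted by frame")
    lo, hi = window
    out = readings.copy().reset_index(drop=True)
    depth = pd.to_numeric(out["depth_m"], errors="coerce")
    status = np.full(len(out), STATUS_PARSED, dtype=object)
    reason = np.full(len(out), "", dtype=object)

    numeric = depth.notna().to_numpy()
    status[~numeric] = STATUS_MISSING
    reason[~numeric] = "non-numeric or empty"
    in_window = numeric & (depth.to_numpy() > lo) & (depth.to_numpy() <= hi)
    oow = numeric & ~in_window
    status[oow] = STATUS_REJECTED
    reason[oow] = f"outside plausibility window ({lo}, {hi}] m"

    # Step-outlier pass among window-valid readings: a spike is a reading
    # that jumps more than max_step_m from both neighbours while those
    # neighbours agree with each other (so a spike cannot drag down its
    # innocent neighbour); at the ends the single neighbour must itself
    # be locally consistent before it can condemn the endpoint.
    valid_idx = np.flatnonzero(in_window)
    vals = depth.to_numpy()[valid_idx]
    m = len(valid_idx)
    for k, i in enumerate(valid_idx):
        spike = False
        if 0 < k < m - 1:
            spike = (
                abs(vals[k] - vals[k - 1]) > max_step_m
                and abs(vals[k] - vals[k + 1]) > max_step_m
                and abs(vals[k - 1] - vals[k + 1]) <= 2 * max_step_m
            )
        elif k == 0 and m > 1:
            neighbour_ok = m < 3 or abs(vals[1] - vals[2]) <= max_step_m
            spike = abs(vals[0] - vals[1]) > max_step_m and neighbour_ok
        elif k == m - 1 and m > 1:
            neighbour_ok = m < 3 or abs(vals[m - 2] - vals[m - 3]) <= max_step_m
            spike = abs(vals[m - 1] - vals[m - 2]) > max_step_m and neighbour_ok
        if spike:
            status[i] = STATUS_REJECTED
            reason[i] = f"step outlier (> {max_step_m} m from both neighbours)"

    out["depth_m"] = depth
    out["status"] = status
    out["reason"] = reason
    return out


def interpolate_depths(validated: pd.DataFrame, frames) -> pd.Series:
    """Per-frame real-valued depth by linear interpolation on frame index.

    Frames outside the span of accepted (parsed) readings get NaN — no
    extrapolation. Requires at least two accepted readings.
    """
    acc = validated[validated["status"] == STATUS_PARSED]
    if len(acc) < 2:
        raise ValueError("need at least two accepted depth readings to interpolate")
    frames = np.asarray(list(frames))
    xf = acc["frame"].to_numpy(dtype=float)
    yf = acc["depth_m"].to_numpy(dtype=float)
    interp = np.interp(frames.astype(float), xf, yf)
    interp[(frames < xf[0]) | (frames > xf[-1])] = np.nan
    return pd.Series(interp, index=pd.Index(frames, name="frame"), name="depth_m")


def round_half_away(x):
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def assign_frame_depths(
    interpolated: pd.Series, exclusion_mask: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Integer frame-depth map with exclusion flags.

    ``exclusion_mask`` (boolean, aligned with the frame index) marks
    frames to drop — e.g. sections reviewed as wrong habitat. Frames with
    no interpolated depth (outside the reading span) are excluded too.
    """
    frames = interpolated.index.to_numpy()
    depth = interpolated.to_numpy(dtype=float)
    excluded = np.isnan(depth)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask, dtype=bool)
        if mask.shape != frames.shape:
            raise ValueError("exclusion mask must align with the frame index")
        excluded = excluded | mask
    depth_int = np.where(excluded, np.nan, round_half_away(depth))
    return pd.DataFrame(
        {
            "frame": frames,
            "depth_m": pd.array(depth_int, dtype="Int64"),
            "excluded": excluded,
        }
    )


def register_depths(
    readings: pd.DataFrame,
    frames,
    window: tuple[float, float] = DEFAULT_WINDOW,
    max_step_m: float = DEFAULT_MAX_STEP,
    exclusion_mask=None,
) -> pd.DataFrame:
    """Validate, interpolate and round in one pass; see the stage functions."""
    validated = validate_readings(readings, window=window, max_step_m=max_step_m)
    interp = interpolate_depths(validated, frames)
    return assign_frame_depths(interp, exclusion_mask)
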