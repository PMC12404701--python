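import numpy as np
import pandas as pd
import pytest

from benthotrend import depth_registration, occurrence_builder, synthetic_data


def records_from_survey(
    config: synthetic_data.SimulationConfig,
    mode: str = "poisson",
    confidence_threshold: float = 0.0,
):
    """Run a simulated survey through depth registration and aggregation."""
    detections, depth_series, truth = synthetic_data.simulate_survey(config, mode)
    maps = []
    for tid, g in depth_series.groupby("transect_id"):
        readings = g.sort_values("frame")[["frame", "depth_m"]].reset_index(drop=True)
        validated = depth_registration.validate_readings(readings)
        acc = validated[validated["status"] == depth_registration.STATUS_PARSED]
        frames = np.arange(int(acc["frame"].min()), int(acc["frame"].max()) + 1)
        fmap = depth_registration.assign_frame_depths(
            depth_registration.interpolate_depths(validated, frames)
        )
        fmap.insert(0, "transect_id", tid)
        maps.append(fmap)
    frame_depths = pd.concat(maps, ignore_index=True)
    kept = occurrence_builder.filter_by_confidence(detections, confidence_threshold)
    taxa = [t.name for t in config.taxa]
    frames_by_transect = {
        tid: g.loc[~g["excluded"], "frame"].to_numpy()
        for tid, g in frame_depths.groupby("transect_id")
    }
    expanded = occurrence_builder.zero_expand(kept, taxa, frames_by_transect)
    dates = pd.DataFrame(
        {
            "transect_id": [t.transect_id for t in config.transects],
            "year": [t.year for t in config.transects],
            "day_of_year": [t.day_of_year for t in config.transects],
        }
    )
    records = occurrence_builder.aggregate_by_depth(expanded, frame_depths, dates)
    return records, detections, frame_depths, truth


@pytest.fixture
def small_survey_config():
    """Three taxa, eight transects — fast but structurally complete."""
    taxa = [
        synthetic_data.TaxonSpec("shallow_coral", 30, 8, 1.2, year_slope=0.1, recall=0.9),
        synthetic_data.TaxonSpec("mid_anemone", 65, 10, 1.5, year_slope=-0.1, day_slope=0.1),
        synthetic_data.TaxonSpec("deep_sponge", 90, 7, 0.8, day2_slope=-0.05),
    ]
    transects = [
        synthetic_data.TransectSpec(f"T{i}", 2000 + 3 * i, 60 + 25 * i, 10.0, 105.0, 5.0)
        for i in range(8)
    ]
    return synthetic_data.SimulationConfig(
        taxa=taxa,
        transects=transects,
        depth_reading=synthetic_data.DepthReadingSpec(20, 0.05, 0.02),
        seed=42,
    )


@pytest.fixture
def survey_records(small_survey_config):
    return records_from_survey(small_survey_config)
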