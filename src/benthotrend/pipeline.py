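"""End-to-end runner: detections + depths -> trends and drivers.

Stage order: register-depth, build-occurrences, depth-profiles,
thermal-niche, trends, drivers. Each stage's outputs are written to the
configured directory and summarised in a manifest (seed, config hash,
per-stage row counts, output hashes) that suffices to reproduce the run
exactly. Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    depth_profiles,
    depth_registration,
    driver_analysis,
    io,
    occurrence_builder,
    synthetic_data,
    thermal_niche,
    trend_model,
)
from .raster import TemperatureRaster


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _transect_dates(transects: list[synthetic_data.TransectSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transect_id": [t.transect_id for t in transects],
            "year": [t.year for t in transects],
            "day_of_year": [t.day_of_year for t in transects],
        }
    )


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    cfg_yaml = out / "config.yaml"
    config.to_yaml(cfg_yaml)
    manifest["config_hash"] = _hash_file(cfg_yaml)

    # -- inputs: load or simulate ------------------------------------------
    sim = None
    if config.detections_path and config.depths_path:
        detections = io.read_detections(config.detections_path)
        depth_series = io.read_depth_series(config.depths_path)
        transect_dates = None
    elif config.simulate:
        sim = synthetic_data.default_survey_config(seed=config.seed)
        detections, depth_series, truth = synthetic_data.simulate_survey(sim)
        transect_dates = _transect_dates(sim.transects)
        truth.to_json(out / "truth.json")
    else:
        raise StageError("inputs", ValueError("no input paths and simulation disabled"))

    if transect_dates is None:
        # dates must travel with external detections as extra columns
        cols = {"transect_id", "year", "day_of_year"}
        if not cols.issubset(detections.columns):
            raise StageError(
                "inputs", ValueError("external detections need year/day_of_year columns")
            )
        transect_dates = detections[list(cols)].drop_duplicates()
        detections = detections[io.DETECTION_REQUIRED]

    # -- register-depth ----------------------------------------------------
    try:
        maps = []
        for tid, g in depth_series.groupby("transect_id"):
            readings = g.sort_values("frame")[["frame", "depth_m"]].reset_index(drop=True)
            validated = depth_registration.validate_readings(
                readings, window=config.depth_window, max_step_m=config.max_step_m
            )
            acc = validated[validated["status"] == depth_registration.STATUS_PARSED]
            frames = np.arange(int(acc["frame"].min()), int(acc["frame"].max()) + 1)
            fmap = depth_registration.assign_frame_depths(
                depth_registration.interpolate_depths(validated, frames)
            )
            fmap.insert(0, "transect_id", tid)
            maps.append(fmap)
        frame_depths = pd.concat(maps, ignore_index=True)
        manifest["stages"]["register-depth"] = {"rows": len(frame_depths)}
        io.write_table(frame_depths, out / "frame_depths.csv")
    except Exception as e:  # noqa: BLE001 - abort naming the stage
        raise StageError("register-depth", e) from e

    # -- build-occurrences -------------------------------------------------
    try:
        kept = occurrence_builder.filter_by_confidence(detections, config.confidence_threshold)
        taxa = sorted(set(detections["taxon"]))
        frames_by_transect = {
            tid: g.loc[~g["excluded"], "frame"].to_numpy()
            for tid, g in frame_depths.groupby("transect_id")
        }
        expanded = occurrence_builder.zero_expand(kept, taxa, frames_by_transect)
        records = occurrence_builder.aggregate_by_depth(expanded, frame_depths, transect_dates)
        dwc = occurrence_builder.to_darwin_core(records, config.site)
        manifest["stages"]["build-occurrences"] = {"rows": len(records)}
        io.write_table(records, out / "occurrence_records.csv")
        io.write_table(dwc, out / "darwin_core.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("build-occurrences", e) from e

    # -- depth-profiles ----------------------------------------------------
    try:
        dists = []
        for taxon in taxa:
            profile = depth_profiles.pooled_abundance_profile(records, taxon)
            if profile["abundance"].sum() > 0:
                dists.append(
                    depth_profiles.weighted_depth_percentiles(
                        profile, taxon, qs=config.percentiles
                    )
                )
        table = depth_profiles.depth_distribution_table(dists)
        manifest["stages"]["depth-profiles"] = {"rows": len(table)}
        io.write_table(table, out / "depth_distributions.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("depth-profiles", e) from e

    # -- thermal-niche -----------------------------------------------------
    try:
        if config.gbif_path and config.raster_path:
            occs = io.read_gbif(config.gbif_path)
            raster = TemperatureRaster.open(config.raster_path)
        elif sim is not None:
            occs, raster, niche_truth = synthetic_data.simulate_global_occurrences(sim)
        else:
            raise ValueError("thermal-niche needs gbif_path and raster_path")
        estimates, survivors, log = thermal_niche.estimate_niche(
            occs,
            raster,
            seed=np.random.default_rng(config.seed + 2),
            max_range_c=config.max_cell_range_c,
            max_uncertainty_m=config.max_uncertainty_m,
            max_isolation_km=config.max_isolation_km,
            thin_radius_km=config.thin_radius_km,
        )
        niche_df = pd.DataFrame(
            [
                {
                    "taxon": e.taxon,
                    "median_c": e.median_c,
                    "category": e.category,
                    "n_occurrences": e.n_occurrences,
                }
                for e in estimates
            ]
        )
        manifest["stages"]["thermal-niche"] = {
            "rows": len(niche_df),
            "removed": len(log.frame()),
        }
        io.write_table(niche_df, out / "niche_estimates.csv")
        io.write_table(log.frame(), out / "niche_filter_log.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("thermal-niche", e) from e

    # -- trends ------------------------------------------------------------
    try:
        taxon_fits = trend_model.fit_taxon_trends(records)
        traits = (
            io.read_traits(config.traits_path)
            if config.traits_path
            else synthetic_data.default_traits()
        )
        cat = niche_df.set_index("taxon")["category"]
        traits = traits.assign(
            temperature_category=traits["taxon"].map(cat).fillna("unknown")
        )
        trait_fits = trend_model.fit_trait_trends(records, traits)
        manifest["stages"]["trends"] = {
            "taxa": len(taxon_fits),
            "trait_categories": len(trait_fits),
        }
        io.write_table(trend_model.trend_table(taxon_fits), out / "taxon_trends.csv")
        io.write_table(trend_model.trend_table(trait_fits), out / "trait_trends.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("trends", e) from e

    # -- drivers -----------------------------------------------------------
    try:
        coefs = trend_model.year_coefficients(taxon_fits)
        medians = niche_df.set_index("taxon")["median_c"]
        results = [
            driver_analysis.regress_coefficients_on_temperature(coefs, medians)
        ]
        tix = traits.set_index("taxon")
        for col in ("size", "lifestyle"):
            if col in tix.columns and tix[col].nunique() == 2:
                results.append(
                    driver_analysis.wilcoxon_binary_trait(coefs, tix[col], driver=col)
                )
        driver_df = driver_analysis.driver_table(results)
        manifest["stages"]["drivers"] = {"tests": len(driver_df)}
        io.write_table(driver_df, out / "drivers.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("drivers", e) from e

    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _hash_file(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
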