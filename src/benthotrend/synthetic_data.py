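"""Seeded synthetic survey, benchmark and occurrence generators.

Everything downstream of the object detector is testable against known
truth by generating inputs with the statistical structure the analysis
assumes:

* ``simulate_survey`` — multi-year ROV transects over a depth gradient.
  Each taxon's expected detections per frame follow a log-linear rate
  with a Gaussian depth profile (unimodal, closed-form quantiles), a
  linear trend in scaled year and quadratic seasonality in scaled day of
  year. Counts are Poisson draws (or exact expected values in the
  noise-free "expected" mode, where fractional counts are allowed);
  detector imperfection is emulated by binomial thinning (recall) and
  binomial relabelling (confusion). Sparse depth readings are emitted at
  a fixed frame interval with dropouts and implausible misreads.
* ``simulate_detection_benchmark`` — ground-truth boxes and predictions
  with planted false positives / false negatives / class swaps, so the
  expected TP/FP/FN at any confidence threshold are exactly known.
* ``simulate_global_occurrences`` — occurrences placed on a synthetic
  temperature raster in cells drawn around a known thermal optimum, plus
  labelled contaminants triggering each niche filter (high coordinate
  uncertainty, high within-cell temperature range, spatial isolation,
  sub-kilometre clusters).

All randomness flows through one numpy Generator; a fixed seed gives
byte-identical output. TruthParameters stores the analytic depth
quantiles, the planted trend coefficients (on the simulated scale) and
the clean niche medians alongside every dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._geo import haversine_km
from .raster import TemperatureRaster

CONTAM_CLEAN = "clean"
CONTAM_UNCERTAINTY = "uncertainty"
CONTAM_CELL_RANGE = "cell_range"
CONTAM_ISOLATED = "isolated"


@dataclass
class TaxonSpec:
    """One taxon's abundance model and detector-noise parameters."""

    name: str
    depth_optimum_m: float
    depth_sd_m: float
    base_rate: float  # expected detections/frame at the optimum, covariates at 0
    year_slope: float = 0.0  # log-rate change per scaled year
    day_slope: float = 0.0
    day2_slope: float = 0.0
    recall: float = 1.0
    confusion: dict[str, float] = field(default_factory=dict)  # target taxon -> rate

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError(f"{self.name}: base_rate must be >= 0")
        if not (0.0 <= self.recall <= 1.0):
            raise ValueError(f"{self.name}: recall must lie in [0, 1]")
        if self.depth_sd_m <= 0:
            raise ValueError(f"{self.name}: depth_sd_m must be positive")
        if any(r < 0 or r > 1 for r in self.confusion.values()):
            raise ValueError(f"{self.name}: confusion rates must lie in [0, 1]")


@dataclass
class TransectSpec:
    """One filming pass: date and depth coverage."""

    transect_id: str
    year: int
    day_of_year: int
    depth_min_m: float
    depth_max_m: float
    frames_per_m: float = 10.0

    def __post_init__(self):
        if self.frames_per_m <= 0:
            raise ValueError(f"{self.transect_id}: frames_per_m must be positive")
        if self.depth_max_m <= self.depth_min_m:
            raise ValueError(f"{self.transect_id}: contradictory depth range")

    @property
    def n_frames(self) -> int:
        return max(1, int(round((self.depth_max_m - self.depth_min_m) * self.frames_per_m)))


@dataclass
class DepthReadingSpec:
    """Sparse depth-overlay sampling: interval, dropouts, misreads."""

    interval_frames: int = 25
    dropout_fraction: float = 0.0
    misread_fraction: float = 0.0
    misread_value: float = 999.0  # outside the (0, 250] plausibility window


@dataclass
class RasterSpec:
    """Synthetic global temperature grid: linear latitude gradient.

    Temperature runs from ``t_warm`` at the southern edge to ``t_cold``
    at the northern edge. Within-cell min/max-depth temperatures sit
    ``half_range_c`` either side of the mean; the last
    ``n_flagged_cols`` longitude columns instead get a
    ``flagged_range_c`` internal range, giving the range filter an
    unambiguous target.
    """

    lat_min: float = -75.0
    lat_max: float = 75.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    cell_deg: float = 0.5
    t_warm: float = 20.0
    t_cold: float = 0.0
    half_range_c: float = 0.25
    flagged_range_c: float = 3.0
    n_flagged_cols: int = 8

    def __post_init__(self):
        if self.cell_deg <= 0:
            raise ValueError("raster cell size must be positive")

    def lat_of_temperature(self, t: float) -> float:
        frac = (self.t_warm - t) / (self.t_warm - self.t_cold)
        return self.lat_min + frac * (self.lat_max - self.lat_min)


@dataclass
class NicheSpec:
    """One species' thermal niche and planted contaminant counts."""

    species: str
    optimum_c: float
    sd_c: float = 1.0
    n_occurrences: int = 200
    n_uncertainty: int = 0
    n_cell_range: int = 0
    n_isolated: int = 0
    cluster_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        if self.sd_c < 0 or self.n_occurrences < 0:
            raise ValueError(f"{self.species}: negative niche parameters")
        if self.n_isolated > 3:
            raise ValueError(
                f"{self.species}: at most 3 isolated contaminants can be placed "
                "pairwise > 3000 km apart on the default grid"
            )


@dataclass
class SimulationConfig:
    taxa: list[TaxonSpec] = field(default_factory=list)
    transects: list[TransectSpec] = field(default_factory=list)
    depth_reading: DepthReadingSpec = field(default_factory=DepthReadingSpec)
    raster: RasterSpec = field(default_factory=RasterSpec)
    niches: list[NicheSpec] = field(default_factory=list)
    confidence_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0


@dataclass
class TruthParameters:
    """Ground truth stored alongside every simulated dataset."""

    depth_quantiles: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    trend_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    niche_medians: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthParameters":
        with open(path) as fh:
            d = json.load(fh)
        d["depth_quantiles"] = {k: tuple(v) for k, v in d["depth_quantiles"].items()}
        return cls(**d)


def _scaled(values: np.ndarray) -> np.ndarray:
    """z-score with sample sd; all-zero when the column is constant."""
    sd = np.std(values, ddof=1) if len(values) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def transect_covariates(transects: list[TransectSpec]) -> pd.DataFrame:
    """Scaled year / day / day^2 per transect (the simulated scale)."""
    years = np.array([t.year for t in transects], dtype=float)
    days = np.array([t.day_of_year for t in transects], dtype=float)
    return pd.DataFrame(
        {
            "transect_id": [t.transect_id for t in transects],
            "year": years.astype(int),
            "day_of_year": days.astype(int),
            "year_s": _scaled(years),
            "day_s": _scaled(days),
            "day2_s": _scaled(days**2),
        }
    )


def frame_depths_true(transect: TransectSpec) -> np.ndarray:
    """True (noise-free) depth of every frame: linear descent over the range."""
    n = transect.n_frames
    step = (transect.depth_max_m - transect.depth_min_m) / n
    return transect.depth_min_m + (np.arange(n) + 0.5) * step


def expected_rate(taxon: TaxonSpec, depth_m: np.ndarray, year_s: float, day_s: float, day2_s: float) -> np.ndarray:
    """Expected detections per frame: log-linear trend x Gaussian depth shape."""
    shape = np.exp(-((depth_m - taxon.depth_optimum_m) ** 2) / (2.0 * taxon.depth_sd_m**2))
    trend = np.exp(
        taxon.year_slope * year_s + taxon.day_slope * day_s + taxon.day2_slope * day2_s
    )
    return taxon.base_rate * trend * shape


def simulate_survey(
    config: SimulationConfig, mode: str = "poisson"
) -> tuple[pd.DataFrame, pd.DataFrame, TruthParameters]:
    """Simulate detections and depth readings for every transect.

    Returns (detections, depth_series, truth). ``detections`` holds only
    rows with count > 0 (zero-expansion is a downstream step) with
    columns ``transect_id, frame, taxon, count, confidence``;
    ``depth_series`` has ``transect_id, frame, depth_m`` with dropouts
    omitted and misreads replaced by the implausible misread value. In
    ``mode="expected"`` counts are the exact (fractional) expected values
    ``rate * recall`` with confidence 1.0 and no confusion noise.
    """
    if mode not in ("poisson", "expected"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    cov = transect_covariates(config.transects)
    names = [t.name for t in config.taxa]

    det_rows: list[pd.DataFrame] = []
    depth_rows: list[pd.DataFrame] = []
    for t_i, transect in enumerate(config.transects):
        depths = frame_depths_true(transect)
        n = len(depths)
        ys, ds, d2s = cov.loc[t_i, ["year_s", "day_s", "day2_s"]]
        counts = {name: np.zeros(n) for name in names}
        for taxon in config.taxa:
            lam = expected_rate(taxon, depths, ys, ds, d2s)
            if mode == "expected":
                counts[taxon.name] += lam * taxon.recall
                continue
            raw = rng.poisson(lam)
            detected = rng.binomial(raw, taxon.recall) if taxon.recall < 1.0 else raw
            for target, rate in taxon.confusion.items():
                moved = rng.binomial(detected, rate)
                detected = detected - moved
                counts[target] += moved
            counts[taxon.name] += detected
        for name in names:
            c = counts[name]
            nz = np.flatnonzero(c > 0)
            if nz.size == 0:
                continue
            if mode == "expected":
                conf = np.ones(nz.size)
            else:
                lo, hi = config.confidence_range
                conf = rng.uniform(lo, hi, size=nz.size)
            det_rows.append(
                pd.DataFrame(
                    {
                        "transect_id": transect.transect_id,
                        "frame": nz,
                        "taxon": name,
                        "count": c[nz] if mode == "expected" else c[nz].astype(int),
                        "confidence": np.round(conf, 4),
                    }
                )
            )

        # sparse depth readings; first and last protected so the
        # interpolation span always covers the transect
        spec = config.depth_reading
        reading_frames = np.arange(0, n, spec.interval_frames)
        if reading_frames[-1] != n - 1:
            reading_frames = np.append(reading_frames, n - 1)
        values = depths[reading_frames].astype(float)
        u = rng.uniform(size=reading_frames.size)
        interior = (reading_frames != 0) & (reading_frames != n - 1)
        drop = (u < spec.dropout_fraction) & interior
        misread = (u >= spec.dropout_fraction) & (
            u < spec.dropout_fraction + spec.misread_fraction
        ) & interior
        values[misread] = spec.misread_value
        depth_rows.append(
            pd.DataFrame(
                {
                    "transect_id": transect.transect_id,
                    "frame": reading_frames[~drop],
                    "depth_m": np.round(values[~drop], 2),
                }
            )
        )

    detections = (
        pd.concat(det_rows, ignore_index=True)
        if det_rows
        else pd.DataFrame(columns=["transect_id", "frame", "taxon", "count", "confidence"])
    )
    depth_series = pd.concat(depth_rows, ignore_index=True)

    z = stats.norm.ppf([0.16, 0.5, 0.84])
    truth = TruthParameters(
        depth_quantiles={
            t.name: tuple(np.round(t.depth_optimum_m + z * t.depth_sd_m, 4)) for t in config.taxa
        },
        trend_coefficients={
            t.name: {"year_s": t.year_slope, "day_s": t.day_slope, "day2_s": t.day2_slope}
            for t in config.taxa
        },
    )
    return detections, depth_series, truth


def simulate_linear_abundance(
    X: pd.DataFrame | np.ndarray,
    beta: dict[str, float] | np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian response with planted coefficients on a given design.

    ``y = X beta + N(0, sigma)``; used for exact parameter-recovery and
    coverage checks of the trend model, where the fitted linear-Gaussian
    form is the true data-generating process (the Poisson survey path is
    log-linear and therefore deliberately misspecified for OLS).
    """
    if isinstance(beta, dict):
        if not isinstance(X, pd.DataFrame):
            raise ValueError("dict beta requires a DataFrame design")
        b = np.array([beta.get(c, 0.0) for c in X.columns], dtype=float)
    else:
        b = np.asarray(beta, dtype=float)
    Xa = np.asarray(X, dtype=float)
    return Xa @ b + rng.normal(0.0, sigma, size=Xa.shape[0])


def simulate_detection_benchmark(
    n_truth: int,
    n_classes: int,
    error_spec: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth boxes plus predictions with planted errors.

    ``error_spec`` keys (all default 0 / shown value): ``n_fp`` spurious
    predictions at ``fp_confidence`` (0.3) on otherwise empty images,
    ``n_fn`` truths with no prediction, ``n_swap`` predictions with a
    wrong class label, ``tp_confidence`` (1.0). Boxes are laid out on a
    non-overlapping grid (10 per image), so at any threshold the
    expected TP/FP/FN are known by construction.
    """
    if n_truth < 0:
        raise ValueError("n_truth must be >= 0")
    spec = {"n_fp": 0, "n_fn": 0, "n_swap": 0, "fp_confidence": 0.3, "tp_confidence": 1.0}
    spec.update(error_spec or {})
    if spec["n_fn"] + spec["n_swap"] > n_truth:
        raise ValueError("planted error counts exceed n_truth")
    if spec["n_swap"] > 0 and n_classes < 2:
        raise ValueError("class swaps need at least two classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = [f"taxon_{i:02d}" for i in range(n_classes)]

    rows = []
    for i in range(n_truth):
        rows.append(
            {
                "image_id": f"img_{i // 10:03d}",
                "label": classes[int(rng.integers(n_classes))],
                "x": float((i % 10) * 120),
                "y": float((i // 10 % 10) * 120),
                "w": float(rng.integers(40, 81)),
                "h": float(rng.integers(40, 81)),
            }
        )
    truths = pd.DataFrame(rows, columns=["image_id", "label", "x", "y", "w", "h"])

    preds = truths.copy()
    preds["confidence"] = spec["tp_confidence"]
    idx = rng.permutation(n_truth)
    fn_idx = idx[: spec["n_fn"]]
    swap_idx = idx[spec["n_fn"] : spec["n_fn"] + spec["n_swap"]]
    for i in swap_idx:
        others = [c for c in classes if c != preds.at[i, "label"]]
        preds.at[i, "label"] = others[int(rng.integers(len(others)))]
    preds = preds.drop(index=fn_idx).reset_index(drop=True)
    fp_rows = [
        {
            "image_id": f"fp_img_{k:03d}",
            "label": classes[int(rng.integers(n_classes))],
            "x": 0.0,
            "y": 0.0,
            "w": 50.0,
            "h": 50.0,
            "confidence": spec["fp_confidence"],
        }
        for k in range(spec["n_fp"])
    ]
    if fp_rows:
        preds = pd.concat([preds, pd.DataFrame(fp_rows)], ignore_index=True)
    return truths, preds


def build_raster(spec: RasterSpec) -> TemperatureRaster:
    """Materialize the synthetic temperature grid of a RasterSpec."""
    lat = np.arange(spec.lat_min + spec.cell_deg / 2, spec.lat_max, spec.cell_deg)
    lon = np.arange(spec.lon_min + spec.cell_deg / 2, spec.lon_max, spec.cell_deg)
    frac = (lat - spec.lat_min) / (spec.lat_max - spec.lat_min)
    t_mean = np.tile((spec.t_warm + frac * (spec.t_cold - spec.t_warm))[:, None], (1, lon.size))
    half = np.full_like(t_mean, spec.half_range_c)
    if spec.n_flagged_cols > 0:
        half[:, -spec.n_flagged_cols :] = spec.flagged_range_c / 2.0
    return TemperatureRaster.from_arrays(lat, lon, t_mean, t_mean + half, t_mean - half, spec.cell_deg)


def _place_in_band(
    rng: np.random.Generator,
    spec: RasterSpec,
    raster: TemperatureRaster,
    target_temps: np.ndarray,
    used_cells: set,
    n_free_cols: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinates for target temperatures, one point per cell."""
    lat_c = raster.data["lat"].to_numpy()
    lats, lons = [], []
    for t in target_temps:
        row = int(np.argmin(np.abs(lat_c - spec.lat_of_temperature(t))))
        for attempt in range(1000):
            col = int(rng.integers(n_free_cols))
            if (row, col) not in used_cells:
                break
            if attempt > 0 and attempt % 200 == 0:  # row effectively full
                row = int(np.clip(row + 1, 0, lat_c.size - 1))
        used_cells.add((row, col))
        jitter = rng.uniform(-0.2, 0.2, size=2) * spec.cell_deg
        lats.append(lat_c[row] + jitter[0])
        lons.append(raster.data["lon"].to_numpy()[col] + jitter[1])
    return np.array(lats), np.array(lons)


def simulate_global_occurrences(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TemperatureRaster, TruthParameters]:
    """Global occurrences around known thermal optima plus labelled contaminants.

    Clean points (one per grid cell, pairwise > 1 km apart) are placed in
    cells whose mean-depth temperature tracks draws from
    Normal(optimum, sd) truncated at 3 sd. Contaminants are labelled in
    the ``contaminant`` column so filter tests can assert exact removal
    sets; the truth records each species' clean median cell temperature.
    """
    rng = np.random.default_rng(config.seed + 1)
    spec = config.raster
    raster = build_raster(spec)
    n_free_cols = raster.data["lon"].size - spec.n_flagged_cols
    lat_c = raster.data["lat"].to_numpy()
    lon_c = raster.data["lon"].to_numpy()

    frames = []
    truth = TruthParameters()
    for niche in config.niches:
        used: set = set()
        lat_iso = spec.lat_min + 3.0
        band_edge = spec.lat_of_temperature(niche.optimum_c + 3 * niche.sd_c)
        if niche.n_isolated and (band_edge - lat_iso) * 111.19 < 3100:
            raise ValueError(
                f"{niche.species}: clean band too close to the isolated-contaminant "
                "latitude for a > 3000 km separation"
            )

        def band_points(n):
            t = rng.normal(niche.optimum_c, niche.sd_c, size=n)
            t = np.clip(t, niche.optimum_c - 3 * niche.sd_c, niche.optimum_c + 3 * niche.sd_c)
            return _place_in_band(rng, spec, raster, t, used, n_free_cols)

        lats, lons = band_points(niche.n_occurrences)
        unc = np.where(rng.uniform(size=niche.n_occurrences) < 0.5, 10.0, np.nan)
        parts = [
            pd.DataFrame(
                {
                    "species": niche.species,
                    "decimalLatitude": lats,
                    "decimalLongitude": lons,
                    "coordinateUncertaintyInMeters": unc,
                    "contaminant": CONTAM_CLEAN,
                }
            )
        ]
        truth.niche_medians[niche.species] = float(
            np.median(raster.lookup(lats, lons))
        )

        if niche.n_uncertainty:
            la, lo = band_points(niche.n_uncertainty)
            parts.append(
                pd.DataFrame(
                    {
                        "species": niche.species,
                        "decimalLatitude": la,
                        "decimalLongitude": lo,
                        "coordinateUncertaintyInMeters": rng.uniform(150, 1000, niche.n_uncertainty),
                        "contaminant": CONTAM_UNCERTAINTY,
                    }
                )
            )
        if niche.n_cell_range:
            t = rng.normal(niche.optimum_c, niche.sd_c, size=niche.n_cell_range)
            rows = [int(np.argmin(np.abs(lat_c - spec.lat_of_temperature(ti)))) for ti in t]
            cols = rng.choice(spec.n_flagged_cols, size=niche.n_cell_range, replace=False)
            parts.append(
                pd.DataFrame(
                    {
                        "species": niche.species,
                        "decimalLatitude": lat_c[rows],
                        "decimalLongitude": lon_c[n_free_cols + cols],
                        "coordinateUncertaintyInMeters": 10.0,
                        "contaminant": CONTAM_CELL_RANGE,
                    }
                )
            )
        if niche.n_isolated:
            iso_lons = -180.0 + 120.0 * np.arange(niche.n_isolated) + 10.0
            parts.append(
                pd.DataFrame(
                    {
                        "species": niche.species,
                        "decimalLatitude": lat_iso,
                        "decimalLongitude": iso_lons,
                        "coordinateUncertaintyInMeters": 10.0,
                        "contaminant": CONTAM_ISOLATED,
                    }
                )
            )
        for j, k in enumerate(niche.cluster_sizes):
            la, lo = band_points(1)
            offs = rng.uniform(-0.004, 0.004, size=(k, 2))
            parts.append(
                pd.DataFrame(
                    {
                        "species": niche.species,
                        "decimalLatitude": la[0] + offs[:, 0],
                        "decimalLongitude": lo[0] + offs[:, 1],
                        "coordinateUncertaintyInMeters": 10.0,
                        "contaminant": f"cluster_{j}",
                    }
                )
            )
        frames.append(pd.concat(parts, ignore_index=True))

    occs = pd.concat(frames, ignore_index=True)
    occs["year"] = rng.integers(2000, 2020, size=len(occs))
    return occs, raster, truth


def default_survey_config(seed: int = 0, frames_per_m: float = 10.0) -> SimulationConfig:
    """Study-shaped default: six taxa spanning the 7-105 m gradient,
    transects 1997-2023 (sparser before 2009, denser after 2015)."""
    taxa = [
        TaxonSpec("Alcyonium digitatum", 17, 6, 1.0, year_slope=0.04, day_slope=-0.09, day2_slope=0.13, recall=0.9),
        TaxonSpec("Caryophyllia smithii", 36, 7, 0.8, year_slope=0.09, day_slope=0.09, recall=0.9),
        TaxonSpec("Protanthea simplex", 70, 10, 2.0, year_slope=0.10, day_slope=0.15, day2_slope=-0.10, recall=0.85),
        TaxonSpec("Geodia barretti", 71, 12, 0.5, year_slope=-0.15, recall=0.9),
        TaxonSpec("Acesta excavata", 90, 8, 0.4, year_slope=-0.10, recall=0.9),
        TaxonSpec("Munida spp.", 94, 7, 0.6, year_slope=0.08, day_slope=0.07, recall=0.85),
    ]
    transects = []
    i = 0
    for year in list(range(1997, 2010)) + [y for y in range(2015, 2024) for _ in range(3)]:
        day = 60 + (i * 37) % 240
        dmin, dmax = (7.0, 105.0) if i % 3 else (30.0, 105.0)
        transects.append(TransectSpec(f"T{i:03d}", year, day, dmin, dmax, frames_per_m))
        i += 1
    niches = [
        NicheSpec("Geodia barretti", 5.5, 1.0, 300, 5, 5, 2, (10,)),
        NicheSpec("Acesta excavata", 6.5, 1.0, 300, 5, 5, 2, (10,)),
        NicheSpec("Munida spp.", 8.0, 1.0, 300, 5, 5, 2, (10,)),
        NicheSpec("Protanthea simplex", 9.5, 1.0, 300, 5, 5, 2, (10,)),
        NicheSpec("Alcyonium digitatum", 10.0, 1.0, 300, 5, 5, 2, (10,)),
        NicheSpec("Caryophyllia smithii", 11.5, 1.0, 300, 5, 5, 2, (10,)),
    ]
    return SimulationConfig(
        taxa=taxa,
        transects=transects,
        depth_reading=DepthReadingSpec(25, 0.05, 0.02),
        niches=niches,
        seed=seed,
    )


def default_traits() -> pd.DataFrame:
    """Size and lifestyle assignments for the default community."""
    rows = [
        ("Alcyonium digitatum", "large", "sessile suspension feeder"),
        ("Caryophyllia smithii", "small", "sessile suspension feeder"),
        ("Protanthea simplex", "small", "sessile suspension feeder"),
        ("Geodia barretti", "large", "sessile suspension feeder"),
        ("Acesta excavata", "large", "sessile suspension feeder"),
        ("Munida spp.", "small", "mobile scavenger"),
    ]
    return pd.DataFrame(rows, columns=["taxon", "size", "lifestyle"])
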