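"""GLM abundance trends on scaled predictors.

Each occurrence record (one taxon at one integer depth of one transect)
carries an abundance — the mean detections per frame — together with the
transect's year, day of year and the record's depth. The trend model is a
Gaussian identity-link GLM (ordinary least squares) of z-scored abundance
on z-scored year, day, day^2, sqrt(depth) and depth: the year coefficient
is the taxon's abundance trend, the day terms absorb quadratic
seasonality, and the two depth terms absorb the depth profile. A count
family is not applicable once the response is scaled to a continuous
z-score, hence the Gaussian fit.

day^2 is computed on the raw day of year and then scaled as its own
predictor; all scalings use the sample standard deviation (ddof=1), and
scaling parameters are retained so new data can be projected onto the
same scale. Absence records (mean 0) are part of the fit.

Trait-level trends sum the member taxa's mean counts within each
(transect, depth) record before scaling — the trait group's pooled
per-frame rate — and refit the same design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

PREDICTORS = ["year_s", "day_s", "day2_s", "sqrtdepth_s", "depth_s"]


@dataclass
class DesignMatrix:
    """Scaled predictor matrix plus the scaling parameters used."""

    X: pd.DataFrame  # const + PREDICTORS
    scaling: dict[str, tuple[float, float]]  # raw column -> (mean, sd)

    @property
    def n(self) -> int:
        return len(self.X)


def _zscore(x: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"constant column {name!r}: cannot scale (sd = 0)")
    return (x - mean) / sd, mean, sd


def build_design_matrix(records: pd.DataFrame) -> DesignMatrix:
    """Design matrix of scaled year, day, day^2, sqrt(depth), depth.

    ``records`` needs columns year, day_of_year, depth_m. Raises on any
    constant predictor, naming the column.
    """
    raw = {
        "year": records["year"].to_numpy(dtype=float),
        "day": records["day_of_year"].to_numpy(dtype=float),
        "day2": records["day_of_year"].to_numpy(dtype=float) ** 2,
        "sqrtdepth": np.sqrt(records["depth_m"].to_numpy(dtype=float)),
        "depth": records["depth_m"].to_numpy(dtype=float),
    }
    cols, scaling = {}, {}
    for (name, x), scaled_name in zip(raw.items(), PREDICTORS):
        cols[scaled_name], mean, sd = _zscore(x, name)
        scaling[name] = (mean, sd)
    X = pd.DataFrame(cols, index=records.index)
    X.insert(0, "const", 1.0)
    return DesignMatrix(X=X, scaling=scaling)


@dataclass
class TrendFit:
    """OLS coefficients, standard errors and p-values for one response."""

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    degenerate: bool = False  # zero residual variance

    def summary_row(self) -> dict:
        row = {"response": self.response, "n": self.n}
        for term in self.params.index:
            if term == "const":
                continue
            row[term] = format_estimate(self.params[term], self.bse[term], self.pvalues[term])
        return row


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_estimate(est: float, se: float, p: float) -> str:
    """"estimate (SE)" with significance stars at 0.05 / 0.01 / 0.001."""
    return f"{est:.2f} ({se:.2f}){significance_stars(p)}"


def fit_abundance_trend(
    design: DesignMatrix,
    response: np.ndarray | pd.Series,
    label: str = "",
    scale_response: bool = True,
) -> TrendFit:
    """Gaussian identity-link fit of (optionally z-scored) abundance.

    Standard errors use the unbiased residual variance; p-values are
    two-sided t-tests. A response fitting exactly (zero residual
    variance) is flagged degenerate: its SEs are 0 and p-values NaN.
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != design.n:
        raise ValueError("response length does not match design rows")
    if scale_response:
        y, _, _ = _zscore(y, "response")
    model = sm.OLS(y, design.X)
    res = model.fit()
    if np.linalg.matrix_rank(design.X.to_numpy()) < design.X.shape[1]:
        raise ValueError("singular design matrix")
    degenerate = bool(res.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))))
    pvals = res.pvalues.copy()
    if degenerate:
        pvals[:] = np.nan
    return TrendFit(
        response=label,
        params=res.params,
        bse=res.bse,
        pvalues=pvals,
        n=design.n,
        degenerate=degenerate,
    )


def fit_taxon_trends(records: pd.DataFrame, scale_response: bool = True) -> dict[str, TrendFit]:
    """One trend fit per taxon on its own records (shared design shape)."""
    fits = {}
    for taxon, g in records.groupby("taxon"):
        design = build_design_matrix(g)
        fits[str(taxon)] = fit_abundance_trend(
            design, g["mean_count"], label=str(taxon), scale_response=scale_response
        )
    return fits


TRAIT_COLUMNS = ["size", "lifestyle", "temperature_category"]


def fit_trait_trends(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    trait_columns: list[str] | None = None,
    scale_response: bool = True,
) -> dict[str, TrendFit]:
    """Trend fit per trait category (e.g. "size=small", "lifestyle=...").

    ``traits`` maps taxon to its categories (columns ``taxon`` plus the
    trait columns). Member taxa's mean counts are summed within each
    (transect, depth) record; empty categories are skipped.
    """
    trait_columns = trait_columns or [c for c in TRAIT_COLUMNS if c in traits.columns]
    missing = set(records["taxon"]) - set(traits["taxon"])
    if missing:
        raise ValueError(f"taxa without trait assignment: {sorted(missing)}")
    merged = records.merge(traits, on="taxon", how="left")
    fits = {}
    for col in trait_columns:
        for level, g in merged.groupby(col):
            pooled = (
                g.groupby(["transect_id", "depth_m", "year", "day_of_year"], as_index=False)[
                    "mean_count"
                ].sum()
            )
            if len(pooled) == 0:
                continue
            label = f"{col}={level}"
            design = build_design_matrix(pooled)
            fits[label] = fit_abundance_trend(
                design, pooled["mean_count"], label=label, scale_response=scale_response
            )
    return fits


def trend_table(fits: dict[str, TrendFit]) -> pd.DataFrame:
    """"estimate (SE)" summary table, one row per response."""
    return pd.DataFrame([f.summary_row() for f in fits.values()])


def year_coefficients(fits: dict[str, TrendFit]) -> pd.Series:
    """The abundance coefficient (scaled-year term) of each fit."""
    return pd.Series({k: f.params["year_s"] for k, f in fits.items()}, name="year_s")
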