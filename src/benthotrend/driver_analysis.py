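"""Trait drivers of taxon-specific abundance trends.

Given each taxon's abundance coefficient (the scaled-year term of its
trend GLM), two tests identify traits that predict it:

* a simple linear regression of the coefficients on median preferred
  temperature — standardized by default, so the slope equals the Pearson
  correlation r;
* a Wilcoxon rank-sum test between the two levels of a binary trait
  (size, lifestyle), exact by full rank-sum enumeration when both groups
  have at most 10 members and there are no ties, otherwise a normal
  approximation with continuity and tie corrections.

All tests are two-sided; no multiplicity correction is applied across
the three drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_GROUP = 10


@dataclass(frozen=True)
class DriverResult:
    """Outcome of one driver test."""

    driver: str
    test: str  # "linear_regression" | "wilcoxon_rank_sum"
    p_value: float
    estimate: float | None = None
    std_error: float | None = None
    r: float | None = None
    statistic: float | None = None  # rank-sum of the first group
    group_medians: dict | None = None
    method: str | None = None  # "exact" | "normal_approx"


def regress_coefficients_on_temperature(
    year_coefs: pd.Series,
    medians: pd.Series,
    standardize: bool = True,
    driver: str = "median_temperature",
) -> DriverResult:
    """Linear regression of abundance coefficients on median temperature.

    Pairs taxa by index. With ``standardize`` both variables are z-scored
    (sample sd), so the slope estimate equals Pearson r; the standard
    error and two-sided t-test p-value refer to the (possibly
    standardized) slope.
    """
    common = year_coefs.index.intersection(medians.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired taxa for the regression")
    y = year_coefs.loc[common].to_numpy(dtype=float)
    x = medians.loc[common].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    lr = stats.linregress(x, y)
    return DriverResult(
        driver=driver,
        test="linear_regression",
        estimate=float(lr.slope),
        std_error=float(lr.stderr),
        r=r,
        p_value=float(lr.pvalue),
    )


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) group assignments.

    p = 2 * min(P(W <= w), P(W >= w)) capped at 1, where W is the
    rank-sum of the first group under the null of exchangeable labels.
    """
    n = len(ranks)
    le = ge = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    total = comb(n, n1)
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_binary_trait(
    year_coefs: pd.Series,
    labels: pd.Series,
    driver: str = "trait",
) -> DriverResult:
    """Wilcoxon rank-sum test of abundance coefficients between two groups.

    ``labels`` assigns each taxon to one of exactly two levels; both must
    be non-empty. Midranks handle ties. Exact enumeration is used when
    both groups have <= 10 members and the data are tie-free; otherwise
    the normal approximation with continuity and tie correction. A fully
    tied sample yields p = 1.
    """
    common = year_coefs.index.intersection(labels.index)
    y = year_coefs.loc[common].to_numpy(dtype=float)
    lab = labels.loc[common]
    levels = sorted(pd.unique(lab))
    if len(levels) != 2:
        raise ValueError(f"binary trait expected, got levels {levels}")
    g1 = y[(lab == levels[0]).to_numpy()]
    g2 = y[(lab == levels[1]).to_numpy()]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both trait groups must be non-empty")

    ranks = stats.rankdata(np.concatenate([g1, g2]))
    n1, n2 = len(g1), len(g2)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(np.concatenate([g1, g2]))) < n1 + n2

    if not has_ties and n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        p = _exact_rank_sum_p(ranks, n1, w)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        method = "normal_approx"

    return DriverResult(
        driver=driver,
        test="wilcoxon_rank_sum",
        statistic=w,
        p_value=float(min(p, 1.0)),
        group_medians={
            str(levels[0]): float(np.median(g1)),
            str(levels[1]): float(np.median(g2)),
        },
        method=method,
    )


def driver_table(results: list[DriverResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "driver": r.driver,
                "test": r.test,
                "estimate": r.estimate,
                "std_error": r.std_error,
                "r": r.r,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
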