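"""Inferential layer: seasonal contrasts, latitudinal regressions, and
regional comparisons of park-level change metrics.

Seasonal contrasts use a normality gate (Shapiro-Wilk on each sample at
α = 0.05): a two-sided two-sample t-test when both samples look normal, a
Wilcoxon rank-sum (Mann-Whitney, R's W convention: the U statistic of the
first sample) otherwise. Latitudinal trends are simple OLS regressions of a
park metric on latitude with Alaska parks excluded (the data gap at high
latitudes lies outside the study area). Regional contrasts use one-way
fixed-effects ANOVA across the seven administrative regions with a
median-centered Levene screen for heteroscedasticity (reported, not
blocking), plus per-region rank-sum tests of each region against all other
parks. No multiple-testing correction is applied by default; Holm-adjusted
p-values are available as an option.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import REGIONS, TestResult, ValidationError

logger = logging.getLogger("avichange")

#: Exact rank-sum p-values when both samples are at most this large;
#: otherwise the normal approximation with continuity correction.
EXACT_WILCOXON_MAX_N = 25


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValidationError(f"{name}: empty sample")
    return arr


def _wilcoxon_method(n1: int, n2: int) -> str:
    return "exact" if (n1 <= EXACT_WILCOXON_MAX_N and n2 <= EXACT_WILCOXON_MAX_N) else "asymptotic"


def _direction(x: np.ndarray, y: np.ndarray, p: float, alpha: float) -> str:
    """Direction of y relative to x when significant, by medians."""
    if p >= alpha:
        return "ns"
    my, mx = np.median(y), np.median(x)
    if my == mx:  # fall back to means for tied medians
        my, mx = y.mean(), x.mean()
    return "higher" if my > mx else "lower"


def compare_seasons(
    summer_values,
    winter_values,
    alpha: float = 0.05,
    paired: bool = False,
) -> TestResult:
    """Compare a park metric between seasons.

    ``direction`` reports the winter sample relative to summer. With
    ``paired=True`` the samples must align park-by-park and the paired
    t-test / Wilcoxon signed-rank forms are used instead of the two-sample
    forms (the unpaired form is the default reporting convention).
    """
    x = _as_array(summer_values, "summer")
    y = _as_array(winter_values, "winter")
    if x.size < 3 or y.size < 3:
        raise ValidationError("compare_seasons needs n >= 3 per sample for the normality gate")
    sw_x = stats.shapiro(x)
    sw_y = stats.shapiro(y)
    normal = sw_x.pvalue >= 0.05 and sw_y.pvalue >= 0.05
    details = {
        "shapiro_p_summer": float(sw_x.pvalue),
        "shapiro_p_winter": float(sw_y.pvalue),
        "paired": paired,
        "alpha": alpha,
    }
    if paired and x.size != y.size:
        raise ValidationError("paired comparison needs equal-length, aligned samples")
    if normal:
        if paired:
            res = stats.ttest_rel(x, y)
            df = float(x.size - 1)
        else:
            res = stats.ttest_ind(x, y)
            df = float(x.size + y.size - 2)
        return TestResult(
            test_name="t_test", statistic=float(res.statistic), p_value=float(res.pvalue),
            df=df, direction=_direction(x, y, float(res.pvalue), alpha), details=details,
        )
    if paired:
        res = stats.wilcoxon(x, y)
        name = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=_wilcoxon_method(x.size, y.size)
        )
        name = "wilcoxon_rank_sum"
    return TestResult(
        test_name=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        direction=_direction(x, y, float(res.pvalue), alpha), details=details,
    )


def latitude_regression(
    park_summaries: pd.DataFrame,
    park_metas: pd.DataFrame,
    metric: str,
    exclude_regions: set[str] = frozenset({"Alaska"}),
) -> TestResult:
    """OLS of a park metric on latitude, excluding the given regions.

    The statistic reported is the t statistic of the slope; slope,
    intercept and sample size travel in ``details``.
    """
    merged = park_summaries.merge(
        park_metas[["park_id", "region", "latitude"]], on="park_id", how="inner"
    )
    merged = merged[~merged["region"].isin(set(exclude_regions))].dropna(subset=[metric, "latitude"])
    if len(merged) < 3:
        raise ValidationError(f"latitude regression needs >= 3 parks, got {len(merged)}")
    lat = merged["latitude"].to_numpy(dtype=float)
    y = merged[metric].to_numpy(dtype=float)
    if np.ptp(lat) == 0:
        raise ValidationError("latitude regression: zero latitude variance")
    res = stats.linregress(lat, y)
    n = lat.size
    t_stat = res.slope / res.stderr if res.stderr > 0 else math.inf * np.sign(res.slope)
    return TestResult(
        test_name="ols",
        statistic=float(t_stat),
        p_value=float(res.pvalue),
        df=float(n - 2),
        r_squared=float(res.rvalue**2),
        details={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "metric": metric,
            "n_parks": n,
            "excluded_regions": sorted(exclude_regions),
        },
    )


def regional_anova(
    park_summaries: pd.DataFrame,
    park_metas: pd.DataFrame,
    metric: str,
) -> TestResult:
    """One-way fixed-effects ANOVA of a park metric across regions.

    Regions with fewer than 2 parks are excluded with a warning (they carry
    no within-group variance). A median-centered Levene heteroscedasticity
    screen is reported in ``details`` alongside the F test.
    """
    merged = park_summaries.merge(
        park_metas[["park_id", "region"]], on="park_id", how="inner"
    ).dropna(subset=[metric])
    groups = []
    for region in REGIONS:
        vals = merged.loc[merged["region"] == region, metric].to_numpy(dtype=float)
        if vals.size == 1:
            logger.warning("regional ANOVA: region %s has a single park; excluded", region)
            continue
        if vals.size >= 2:
            groups.append(vals)
    if len(groups) < 2:
        raise ValidationError("regional ANOVA needs >= 2 regions with >= 2 parks each")
    k = len(groups)
    n = sum(g.size for g in groups)
    f_res = stats.f_oneway(*groups)
    lev = stats.levene(*groups, center="median")
    return TestResult(
        test_name="anova",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        df=(float(k - 1), float(n - k)),
        details={
            "metric": metric,
            "n_regions": k,
            "n_parks": n,
            "levene_statistic": float(lev.statistic),
            "levene_p": float(lev.pvalue),
        },
    )


def region_vs_overall(
    park_summaries: pd.DataFrame,
    park_metas: pd.DataFrame,
    metric: str,
    region: str,
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided rank-sum test of one region's parks against all other parks.

    ``direction`` reports whether the region sits higher or lower than the
    rest of the system when the test is significant.
    """
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}; allowed: {REGIONS}")
    merged = park_summaries.merge(
        park_metas[["park_id", "region"]], on="park_id", how="inner"
    ).dropna(subset=[metric])
    inside = merged.loc[merged["region"] == region, metric].to_numpy(dtype=float)
    outside = merged.loc[merged["region"] != region, metric].to_numpy(dtype=float)
    if inside.size < 3:
        raise ValidationError(f"region {region}: needs >= 3 parks, got {inside.size}")
    if outside.size == 0:
        raise ValidationError("no parks outside the region to compare against")
    res = stats.mannwhitneyu(
        inside, outside, alternative="two-sided",
        method=_wilcoxon_method(inside.size, outside.size),
    )
    p = float(res.pvalue)
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=p,
        direction=_direction(outside, inside, p, alpha),
        details={"metric": metric, "region": region, "n_region": inside.size,
                 "n_other": outside.size, "alpha": alpha},
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default in the
    pipeline, matching uncorrected per-test reporting)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
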