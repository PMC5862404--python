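"""Per-key suitability trend regression and five-way classification.

For each species x park x season x RCP key, the 12 suitability values
(4 GCMs x 3 periods) are pooled into one ordinary least-squares regression
of suitability on calendar year, y = β₀ + β₁·year, so the fit captures the
average trend across the climate-model ensemble. Two criteria then classify
the key:

1. the sign and significance of β₁ (improving / stable / worsening), and
2. whether the across-GCM mean suitability crosses the species' TSS-derived
   threshold between the present and mid-century (potential colonization
   upward; potential extirpation downward — the latter only as a subset of a
   significantly worsening trend).

A species is retained for park-level analysis only if its climate is
suitable in the park at present or by mid-century (the inclusion rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CELLS_PER_KEY,
    KEY_COLUMNS,
    PERIOD_MID,
    PERIOD_PRESENT,
    PERIODS,
    TrendFit,
    ValidationError,
)

logger = logging.getLogger("avichange")

#: Calendar-year midpoints of the three periods (default time coding).
MIDPOINT_YEARS: dict[str, float] = {"present": 2005.0, "2011-2040": 2025.5, "2041-2070": 2055.5}
#: Ordinal alternative (0, 1, 2) for sensitivity checks.
ORDINAL_YEARS: dict[str, float] = {p: float(i) for i, p in enumerate(PERIODS)}

#: Residual variance below this fraction of total variance counts as a
#: numerically perfect fit.
_PERFECT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class ClassifierSettings:
    """Knobs of the trend classifier.

    alpha
        Two-sided significance level for the slope test (field default 0.05).
    period_years
        Map period label -> numeric time value used as the regressor.
    zero_variance_policy
        How degenerate fits report p: 'flat1_perfect0' (the default and only
        policy) sets p = 1 for constant input (slope exactly 0, nothing to
        test) and p = 0 for a perfect non-constant fit.
    colonization_requires_significance
        If True, an upward threshold crossing must also carry a
        significantly positive slope to count as potential colonization.
        Off by default: the crossing itself defines colonization.
    """

    alpha: float = 0.05
    period_years: dict[str, float] = field(default_factory=lambda: dict(MIDPOINT_YEARS))
    zero_variance_policy: str = "flat1_perfect0"
    colonization_requires_significance: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        years = [self.period_years[p] for p in PERIODS]
        if not (years[0] < years[1] < years[2]):
            raise ValidationError("period_years must be strictly increasing in period order")
        if self.zero_variance_policy != "flat1_perfect0":
            raise ValidationError(f"unknown zero_variance_policy {self.zero_variance_policy!r}")


def fit_trend(records: pd.DataFrame, settings: ClassifierSettings | None = None) -> TrendFit:
    """OLS fit of suitability on time for the records of one key.

    ``records`` needs ``period`` and ``suitability`` columns (normally the
    12 rows of one species x park x season x RCP key). GCM replicates are
    pooled; the present- and mid-period across-GCM means are returned
    alongside the slope for the crossing rules.
    """
    settings = settings or ClassifierSettings()
    period = records["period"].to_numpy()
    y = records["suitability"].to_numpy(dtype=float)
    if np.unique(period).size < 2:
        raise ValidationError("fit_trend requires at least 2 distinct time periods")
    if ((y < 0) | (y > 1)).any():
        raise ValidationError("suitability values outside [0, 1]")
    present = y[period == PERIOD_PRESENT]
    mid = y[period == PERIOD_MID]
    if present.size == 0 or mid.size == 0:
        raise ValidationError("fit_trend requires both present and mid-century records")

    x = np.array([settings.period_years[p] for p in period], dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant input: zero slope by construction, nothing to test
        slope, intercept, p = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
        if ss_res <= _PERFECT_FIT_RTOL * ss_tot:
            p = 0.0 if slope != 0.0 else 1.0
        else:
            p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
    return TrendFit(
        slope=slope,
        intercept=intercept,
        p_value=p,
        n_points=int(y.size),
        present_mean=float(present.mean()),
        mid_mean=float(mid.mean()),
    )


def classify(fit: TrendFit, threshold: float, settings: ClassifierSettings | None = None) -> str:
    """Five-way classification of one fitted trajectory.

    Decision order: upward crossing first (potential colonization), then
    downward crossing with a significant negative slope (potential
    extirpation), then the trend test alone (improving / worsening /
    stable). A downward crossing without slope significance falls through
    to the trend test — extirpation is strictly a subset of worsening.
    """
    settings = settings or ClassifierSettings()
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold {threshold} not strictly inside (0, 1)")
    significant = fit.p_value < settings.alpha
    if fit.present_mean < threshold and fit.mid_mean >= threshold:
        if not settings.colonization_requires_significance or (significant and fit.slope > 0):
            return "potential_colonization"
    if (
        fit.present_mean >= threshold
        and fit.mid_mean < threshold
        and fit.slope < 0
        and significant
    ):
        return "potential_extirpation"
    if significant and fit.slope > 0:
        return "improving"
    if significant and fit.slope < 0:
        return "worsening"
    return "stable"


def species_included(fit: TrendFit, threshold: float) -> bool:
    """Inclusion rule: climate suitable at present or by mid-century."""
    return fit.present_mean >= threshold or fit.mid_mean >= threshold


def detect_year_round(
    summer_fit: TrendFit,
    winter_fit: TrendFit,
    summer_threshold: float,
    winter_threshold: float,
) -> bool:
    """A species that could become a year-round resident of the park:
    currently suitable in summer only, projected to become suitable in
    winter by mid-century."""
    return (
        summer_fit.present_mean >= summer_threshold
        and winter_fit.present_mean < winter_threshold
        and winter_fit.mid_mean >= winter_threshold
    )


def classify_all(
    suitability: pd.DataFrame,
    thresholds: pd.DataFrame,
    settings: ClassifierSettings | None = None,
    permissive: bool = False,
    drop_excluded: bool = True,
) -> pd.DataFrame:
    """Fit and classify every (species, park, season, rcp) key.

    Parameters
    ----------
    permissive
        Incomplete keys (fewer than 12 GCM x period cells) are a hard error
        by default; with ``permissive=True`` they are dropped with a logged
        warning instead. Regression on fewer points silently changes the
        inference, so dropping is the only downgrade offered.
    drop_excluded
        Keep only species passing the inclusion rule (the default, matching
        downstream park summaries); with False, all keys are returned with
        their ``included`` flag.

    Returns a DataFrame with the key columns plus category, slope,
    intercept, p_value, n_points, present_mean, mid_mean, threshold and
    included.
    """
    settings = settings or ClassifierSettings()
    if suitability.empty:
        return pd.DataFrame(
            columns=KEY_COLUMNS
            + ["category", "slope", "intercept", "p_value", "n_points",
               "present_mean", "mid_mean", "threshold", "included"]
        )

    counts = suitability.groupby(KEY_COLUMNS, sort=False, observed=True).size()
    incomplete = counts[counts != CELLS_PER_KEY]
    df = suitability
    if len(incomplete):
        if not permissive:
            raise ValidationError(
                f"{len(incomplete)} key(s) lack the full {CELLS_PER_KEY} GCM x period cells, "
                f"e.g. {list(incomplete.index[:5])}; pass permissive=True to drop them"
            )
        logger.warning("dropping %d incomplete key(s) (permissive mode)", len(incomplete))
        keep = counts[counts == CELLS_PER_KEY].index
        df = suitability.set_index(KEY_COLUMNS).loc[keep].reset_index()

    thr = thresholds.set_index(["species_id", "season"])["threshold"]
    need = df[["species_id", "season"]].drop_duplicates()
    missing = [tuple(r) for r in need.itertuples(index=False) if tuple(r) not in thr.index]
    if missing:
        raise ValidationError(
            f"no threshold for {len(missing)} (species, season) pair(s): {sorted(missing)[:10]}"
        )

    year_map = settings.period_years
    rows = []
    for key, grp in df.groupby(KEY_COLUMNS, sort=True, observed=True):
        fit = fit_trend(grp, settings)
        threshold = float(thr.loc[(key[0], key[2])])
        rows.append(
            dict(
                zip(KEY_COLUMNS, key),
                category=classify(fit, threshold, settings),
                slope=fit.slope,
                intercept=fit.intercept,
                p_value=fit.p_value,
                n_points=fit.n_points,
                present_mean=fit.present_mean,
                mid_mean=fit.mid_mean,
                threshold=threshold,
                included=species_included(fit, threshold),
            )
        )
    out = pd.DataFrame(rows)
    if drop_excluded:
        out = out[out["included"]].reset_index(drop=True)
    return out


def year_round_table(classifications: pd.DataFrame) -> pd.DataFrame:
    """Flag species x park x RCP keys meeting the year-round criterion.

    Requires classification rows (with present_mean/mid_mean/threshold) for
    both seasons of a key; keys with a season missing are skipped with a
    logged warning count. Returns columns species_id, park_id, rcp,
    year_round.
    """
    if classifications.empty:
        return pd.DataFrame(columns=["species_id", "park_id", "rcp", "year_round"])
    pivot_cols = ["present_mean", "mid_mean", "threshold"]
    wide = classifications.pivot_table(
        index=["species_id", "park_id", "rcp"],
        columns="season",
        values=pivot_cols,
        aggfunc="first",
        observed=True,
    )
    rows = []
    n_skipped = 0
    for key, row in wide.iterrows():
        try:
            s_present = row[("present_mean", "summer")]
            s_thr = row[("threshold", "summer")]
            w_present = row[("present_mean", "winter")]
            w_mid = row[("mid_mean", "winter")]
            w_thr = row[("threshold", "winter")]
        except KeyError:
            n_skipped += 1
            continue
        if any(pd.isna(v) for v in (s_present, s_thr, w_present, w_mid, w_thr)):
            n_skipped += 1
            continue
        flag = (s_present >= s_thr) and (w_present < w_thr) and (w_mid >= w_thr)
        rows.append({"species_id": key[0], "park_id": key[1], "rcp": key[2], "year_round": flag})
    if n_skipped:
        logger.warning("year-round detection skipped %d key(s) missing a season", n_skipped)
    return pd.DataFrame(rows, columns=["species_id", "park_id", "rcp", "year_round"])


def with_settings(settings: ClassifierSettings, **changes) -> ClassifierSettings:
    """Return a copy of ``settings`` with fields replaced."""
    return replace(settings, **changes)
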