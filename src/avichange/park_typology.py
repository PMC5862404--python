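"""Relative park trend groups from colonization/extirpation proportions.

Plotting each park's proportion of potential colonizations against its
proportion of potential extirpations (by convention for summer under the
high-emissions pathway), the plane is divided into five sectors by cohort
quantiles of the two axes:

* ``intermediate_change`` — within the interquartile box on both axes
  (within a quartile of the median along each);
* ``high_turnover`` — above the median on both axes (outside the box);
* ``high_colonization`` / ``high_extirpation`` — above the median on one
  axis only;
* ``low_change`` — at or below the median on both axes.

Labels are relative to the cohort, not absolute rates: the same park can
change groups when the cohort changes. An alternative rotated-diamond
intermediate region (L1 ball inscribed in the interquartile box) is
available behind the ``geometry`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PARK_TREND_GROUPS, ValidationError

logger = logging.getLogger("avichange")


@dataclass(frozen=True)
class TypologyThresholds:
    """Cohort quantiles of the two typology axes."""

    median_col: float
    median_ext: float
    q1_col: float
    q3_col: float
    q1_ext: float
    q3_ext: float

    def __post_init__(self) -> None:
        if not (self.q1_col <= self.median_col <= self.q3_col):
            raise ValidationError("colonization quartiles out of order")
        if not (self.q1_ext <= self.median_ext <= self.q3_ext):
            raise ValidationError("extirpation quartiles out of order")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def compute_typology_thresholds(park_summaries: pd.DataFrame) -> TypologyThresholds:
    """Medians and quartiles of prop_colonization / prop_extirpation across
    parks (linear interpolation of order statistics)."""
    df = park_summaries.dropna(subset=["prop_colonization", "prop_extirpation"])
    if len(df) < 4:
        raise ValidationError(
            f"typology needs >= 4 parks with defined proportions, got {len(df)}"
        )
    pc = df["prop_colonization"].to_numpy(dtype=float)
    pe = df["prop_extirpation"].to_numpy(dtype=float)
    q1c, medc, q3c = np.quantile(pc, [0.25, 0.5, 0.75])
    q1e, mede, q3e = np.quantile(pe, [0.25, 0.5, 0.75])
    return TypologyThresholds(
        median_col=float(medc), median_ext=float(mede),
        q1_col=float(q1c), q3_col=float(q3c),
        q1_ext=float(q1e), q3_ext=float(q3e),
    )


def assign_group(
    prop_colonization: float,
    prop_extirpation: float,
    thresholds: TypologyThresholds,
    geometry: str = "rectangle",
) -> str:
    """Sector label for one park.

    The intermediate region is evaluated first; the remaining plane splits
    by the two medians with ties (exact equality with a median) resolving to
    the low-change side.
    """
    pc, pe, t = prop_colonization, prop_extirpation, thresholds
    if np.isnan(pc) or np.isnan(pe):
        raise ValidationError("undefined proportions cannot be assigned a trend group")
    if _in_intermediate(pc, pe, t, geometry):
        return "intermediate_change"
    if pc > t.median_col and pe > t.median_ext:
        return "high_turnover"
    if pc > t.median_col:
        return "high_colonization"
    if pe > t.median_ext:
        return "high_extirpation"
    return "low_change"


def _in_intermediate(pc: float, pe: float, t: TypologyThresholds, geometry: str) -> bool:
    if geometry == "rectangle":
        return (t.q1_col <= pc <= t.q3_col) and (t.q1_ext <= pe <= t.q3_ext)
    if geometry == "diamond":
        # rotated square (L1 ball) inscribed in the interquartile box;
        # degenerate half-widths collapse the test to exact-median equality
        hw_c = max(t.q3_col - t.median_col, t.median_col - t.q1_col)
        hw_e = max(t.q3_ext - t.median_ext, t.median_ext - t.q1_ext)
        dc = abs(pc - t.median_col) / hw_c if hw_c > 0 else (0.0 if pc == t.median_col else np.inf)
        de = abs(pe - t.median_ext) / hw_e if hw_e > 0 else (0.0 if pe == t.median_ext else np.inf)
        return dc + de <= 1.0
    raise ValidationError(f"unknown intermediate-region geometry {geometry!r}")


def classify_parks(
    park_summaries: pd.DataFrame,
    season: str | None = "summer",
    rcp: str | None = "RCP8.5",
    geometry: str = "rectangle",
) -> tuple[pd.DataFrame, TypologyThresholds]:
    """Label every park of one (season, rcp) stratum with its trend group.

    ``park_summaries`` may contain several strata; ``season``/``rcp`` select
    one (pass None to accept pre-filtered input, which must then be a single
    stratum). Parks with undefined proportions are excluded with a warning.

    Returns ``(groups, thresholds)`` where ``groups`` has columns park_id,
    group, prop_colonization, prop_extirpation.
    """
    df = park_summaries
    if season is not None:
        df = df[df["season"] == season]
    if rcp is not None:
        df = df[df["rcp"] == rcp]
    strata = df[["season", "rcp"]].drop_duplicates()
    if len(strata) == 0:
        raise ValidationError("no park summaries in the requested (season, rcp) stratum")
    if len(strata) > 1:
        raise ValidationError(
            f"typology requires a single (season, rcp) stratum, found {len(strata)}"
        )
    defined = df.dropna(subset=["prop_colonization", "prop_extirpation"])
    if len(defined) < len(df):
        logger.warning(
            "typology: excluding %d park(s) with undefined proportions", len(df) - len(defined)
        )
    thresholds = compute_typology_thresholds(defined)
    groups = pd.DataFrame(
        {
            "park_id": defined["park_id"].to_numpy(),
            "group": [
                assign_group(pc, pe, thresholds, geometry=geometry)
                for pc, pe in zip(defined["prop_colonization"], defined["prop_extirpation"])
            ],
            "prop_colonization": defined["prop_colonization"].to_numpy(),
            "prop_extirpation": defined["prop_extirpation"].to_numpy(),
        }
    ).reset_index(drop=True)
    counts = groups["group"].value_counts().reindex(PARK_TREND_GROUPS, fill_value=0)
    logger.info("park trend groups: %s", counts.to_dict())
    return groups, thresholds
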