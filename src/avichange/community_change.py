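"""Park-level community-change metrics from per-species classifications.

Species lists for the present and mid-century are built per park under the
assumption that every potential colonization and extirpation is realized;
turnover between the two lists is the binary (presence/absence) Bray-Curtis
dissimilarity, which for 0/1 data equals

    BC = (|P \\ F| + |F \\ P|) / (|P| + |F|)
       = (n_col + n_ext) / (2 * richness_present + n_col - n_ext),

0 meaning no change and 1 complete turnover. Per-park summaries carry
colonization/extirpation counts and proportions (denominator: present
richness), the future:present richness ratio, the realization fraction
(extirpations per colonization), and the count of potential year-round
resident species; the system-wide summary aggregates them per season x RCP.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .data_model import ValidationError

logger = logging.getLogger("avichange")

PARK_SUMMARY_COLUMNS = [
    "park_id", "season", "rcp", "richness_present", "richness_future",
    "n_colonization", "n_extirpation", "prop_colonization", "prop_extirpation",
    "bray_curtis", "richness_ratio", "realization_fraction", "n_year_round",
]


def species_lists(classifications: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Present and projected future species sets for one park/season/rcp.

    Present list: species whose across-GCM present-period mean meets their
    threshold. Future list: the present list minus potential extirpations
    plus potential colonizations.
    """
    _require_single_group(classifications)
    present = set(
        classifications.loc[
            classifications["present_mean"] >= classifications["threshold"], "species_id"
        ]
    )
    ext = set(
        classifications.loc[classifications["category"] == "potential_extirpation", "species_id"]
    )
    col = set(
        classifications.loc[classifications["category"] == "potential_colonization", "species_id"]
    )
    return present, (present - ext) | col


def bray_curtis_binary(present_set: set, future_set: set) -> float:
    """Binary Bray-Curtis (= Sørensen) dissimilarity between two species sets.

    Undefined (NaN) when both sets are empty.
    """
    n_total = len(present_set) + len(future_set)
    if n_total == 0:
        logger.warning("Bray-Curtis undefined: both species lists empty")
        return math.nan
    unshared = len(present_set - future_set) + len(future_set - present_set)
    return unshared / n_total


def summarize_park(
    classifications: pd.DataFrame,
    n_year_round: int = 0,
) -> dict:
    """Build one ParkSummary row from the classifications of one
    (park, season, rcp) group.

    Proportions use present richness as the denominator; with zero present
    richness they are flagged undefined (NaN) and the caller excludes the
    park from cross-park means. ``n_year_round`` is the count of potential
    year-round residents for the park's RCP (season-independent).
    """
    park_id, season, rcp = _require_single_group(classifications)
    present, future = species_lists(classifications)
    n_col = int((classifications["category"] == "potential_colonization").sum())
    n_ext = int((classifications["category"] == "potential_extirpation").sum())
    richness_present = len(present)
    richness_future = len(future)
    assert richness_future == richness_present - n_ext + n_col, "richness identity violated"
    if richness_present == 0:
        logger.warning(
            "park %s (%s, %s): zero present richness; proportions undefined", park_id, season, rcp
        )
        prop_col = prop_ext = ratio = math.nan
    else:
        prop_col = n_col / richness_present
        prop_ext = n_ext / richness_present
        ratio = richness_future / richness_present
    return {
        "park_id": park_id,
        "season": season,
        "rcp": rcp,
        "richness_present": richness_present,
        "richness_future": richness_future,
        "n_colonization": n_col,
        "n_extirpation": n_ext,
        "prop_colonization": prop_col,
        "prop_extirpation": prop_ext,
        "bray_curtis": bray_curtis_binary(present, future),
        "richness_ratio": ratio,
        "realization_fraction": (n_ext / n_col) if n_col > 0 else math.nan,
        "n_year_round": int(n_year_round),
    }


def summarize_parks(
    classifications: pd.DataFrame,
    year_round: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-park summaries for every (park, season, rcp) group present.

    ``year_round`` is the flag table from
    :func:`avichange.trend_classifier.year_round_table`; counts are per
    (park, rcp) and attached to both seasons' rows.
    """
    if classifications.empty:
        return pd.DataFrame(columns=PARK_SUMMARY_COLUMNS)
    yr_counts: dict[tuple[str, str], int] = {}
    if year_round is not None and len(year_round):
        yr_counts = (
            year_round[year_round["year_round"]]
            .groupby(["park_id", "rcp"], observed=True)
            .size()
            .to_dict()
        )
    rows = []
    for (park, season, rcp), grp in classifications.groupby(
        ["park_id", "season", "rcp"], sort=True, observed=True
    ):
        rows.append(summarize_park(grp, n_year_round=yr_counts.get((park, rcp), 0)))
    return pd.DataFrame(rows, columns=PARK_SUMMARY_COLUMNS)


def systemwide_summary(park_summaries: pd.DataFrame) -> pd.DataFrame:
    """Cross-park aggregates per (season, rcp).

    Means carry the standard error of the mean (sample sd / sqrt(n)). The
    ">25%" park counts use strict inequality; the colonizations-exceed-
    extirpations count compares raw species counts. Parks with undefined
    proportions (zero present richness) are excluded from proportion-based
    aggregates with a logged count; parks with no colonizations are excluded
    from the mean realization fraction likewise.
    """
    if park_summaries.empty:
        raise ValidationError("systemwide_summary: no park summaries provided")
    rows = []
    for (season, rcp), grp in park_summaries.groupby(["season", "rcp"], sort=True, observed=True):
        defined = grp[grp["prop_colonization"].notna()]
        n_undef = len(grp) - len(defined)
        if n_undef:
            logger.warning(
                "systemwide (%s, %s): excluding %d park(s) with undefined proportions",
                season, rcp, n_undef,
            )
        n = len(defined)
        realization = grp["realization_fraction"].dropna()
        if len(realization) < len(grp):
            logger.info(
                "systemwide (%s, %s): %d park(s) with no colonizations excluded from "
                "mean realization fraction", season, rcp, len(grp) - len(realization),
            )
        row = {"season": season, "rcp": rcp, "n_parks": n}
        for metric in ("bray_curtis", "prop_extirpation", "prop_colonization"):
            vals = defined[metric].dropna()
            row[f"mean_{metric}"] = float(vals.mean()) if len(vals) else math.nan
            row[f"se_{metric}"] = _sem(vals)
        for metric in ("n_colonization", "n_extirpation", "n_year_round"):
            row[f"mean_{metric}"] = float(grp[metric].mean())
            row[f"se_{metric}"] = _sem(grp[metric])
        row["n_parks_ext_gt25"] = int((defined["prop_extirpation"] > 0.25).sum())
        row["n_parks_col_gt25"] = int((defined["prop_colonization"] > 0.25).sum())
        row["n_parks_col_exceed_ext"] = int((grp["n_colonization"] > grp["n_extirpation"]).sum())
        for count_col in ("n_parks_ext_gt25", "n_parks_col_gt25"):
            row[f"pct{count_col[1:]}"] = 100.0 * row[count_col] / n if n else math.nan
        row["pct_parks_col_exceed_ext"] = 100.0 * row["n_parks_col_exceed_ext"] / len(grp)
        row["mean_richness_ratio"] = float(defined["richness_ratio"].mean()) if n else math.nan
        row["mean_realization_fraction"] = (
            float(realization.mean()) if len(realization) else math.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _sem(values) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return math.nan
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


def _require_single_group(classifications: pd.DataFrame) -> tuple[str, str, str]:
    if classifications.empty:
        raise ValidationError("expected classifications for exactly one (park, season, rcp) group")
    keys = classifications[["park_id", "season", "rcp"]].drop_duplicates()
    if len(keys) != 1:
        raise ValidationError(
            f"expected one (park, season, rcp) group, found {len(keys)}: "
            f"{keys.to_records(index=False)[:5]}"
        )
    return tuple(keys.iloc[0])
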