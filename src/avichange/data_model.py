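"""Domain vocabulary, validation, and CSV readers/writers.

The analysis operates on three long-format input tables:

* ``suitability`` — one climate-suitability value (a species distribution
  model output in [0, 1]) per species x park x season x emissions pathway
  (RCP) x climate model (GCM) x time period;
* ``thresholds`` — the species- and season-specific suitability cut-point
  (TSS-derived) that divides suitable from unsuitable climate;
* ``parks`` — park metadata: administrative region and coordinates.

Tables travel as :class:`pandas.DataFrame` objects with canonical column
names and validated categorical levels; the dataclasses below carry the
per-key regression evidence and classification results between stages.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("avichange")

# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

SEASONS: tuple[str, ...] = ("summer", "winter")

RCPS: tuple[str, ...] = ("RCP2.6", "RCP8.5")
_RCP_ALIASES: dict[str, str] = {
    "rcp2.6": "RCP2.6", "2.6": "RCP2.6", "26": "RCP2.6", "rcp26": "RCP2.6",
    "rcp8.5": "RCP8.5", "8.5": "RCP8.5", "85": "RCP8.5", "rcp85": "RCP8.5",
}

#: The four CMIP5 ensemble members whose spread the trend regression pools.
GCMS: tuple[str, ...] = ("CanESM2", "CESM1-CAM5", "HadGEM2-ES", "MIROC-ESM")

#: Canonical period labels, in temporal order: the present-day baseline
#: (2000-2010), an intermediate window used only to steady the trend
#: estimate, and the mid-century projection window.
PERIODS: tuple[str, ...] = ("present", "2011-2040", "2041-2070")
PERIOD_PRESENT, PERIOD_NEAR, PERIOD_MID = PERIODS
_PERIOD_ALIASES: dict[str, str] = {
    "present": PERIOD_PRESENT, "2000-2010": PERIOD_PRESENT, "baseline": PERIOD_PRESENT,
    "near": PERIOD_NEAR, "2011-2040": PERIOD_NEAR,
    "mid": PERIOD_MID, "2041-2070": PERIOD_MID, "mid-century": PERIOD_MID,
}

#: The seven National Park Service administrative regions.
REGIONS: tuple[str, ...] = (
    "Alaska", "Pacific West", "Intermountain", "Midwest",
    "Southeast", "National Capital", "Northeast",
)

SUITABILITY_COLUMNS = ["species_id", "park_id", "season", "rcp", "gcm", "period", "suitability"]
THRESHOLD_COLUMNS = ["species_id", "season", "threshold"]
PARK_COLUMNS = ["park_id", "park_name", "region", "latitude", "longitude"]

#: Grouping key identifying one trend-regression problem.
KEY_COLUMNS = ["species_id", "park_id", "season", "rcp"]

#: Number of (GCM, period) cells a complete key must carry: 4 x 3.
CELLS_PER_KEY = len(GCMS) * len(PERIODS)

TREND_CATEGORIES: tuple[str, ...] = (
    "improving", "stable", "worsening", "potential_extirpation", "potential_colonization",
)

PARK_TREND_GROUPS: tuple[str, ...] = (
    "high_turnover", "high_colonization", "high_extirpation",
    "intermediate_change", "low_change",
)


class Season(str, enum.Enum):
    SUMMER = "summer"
    WINTER = "winter"


class ValidationError(ValueError):
    """An input table violates the documented schema or value constraints."""


# --------------------------------------------------------------------------
# Result dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendFit:
    """OLS evidence for one species x park x season x RCP trajectory.

    ``slope`` is in suitability units per year; ``present_mean`` and
    ``mid_mean`` are across-GCM mean suitabilities in the baseline and
    mid-century periods and drive the threshold-crossing rules.
    """

    slope: float
    intercept: float
    p_value: float
    n_points: int
    present_mean: float
    mid_mean: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        for name in ("present_mean", "mid_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} {v} outside [0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one inferential test in the comparative-statistics layer."""

    test_name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] | float | None = None
    r_squared: float | None = None
    direction: str | None = None  # 'higher' | 'lower' | 'ns'
    details: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": _scalar(self.statistic),
            "p_value": _scalar(self.p_value),
            "df": list(self.df) if isinstance(self.df, tuple) else _scalar(self.df),
            "r_squared": _scalar(self.r_squared),
            "direction": self.direction,
        }
        if self.details:
            d["details"] = {k: _scalar(v) for k, v in self.details.items()}
        return d


def _scalar(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# --------------------------------------------------------------------------
# Normalisation helpers
# --------------------------------------------------------------------------

def normalize_season(value: str) -> str:
    s = str(value).strip().lower()
    if s not in SEASONS:
        raise ValidationError(f"unknown season {value!r}; allowed: {SEASONS}")
    return s


def normalize_rcp(value: str) -> str:
    s = str(value).strip()
    if s in RCPS:
        return s
    canon = _RCP_ALIASES.get(s.lower())
    if canon is None:
        raise ValidationError(f"unknown RCP {value!r}; allowed: {RCPS}")
    return canon


def normalize_period(value: str) -> str:
    canon = _PERIOD_ALIASES.get(str(value).strip().lower())
    if canon is None:
        raise ValidationError(f"unknown period {value!r}; allowed: {PERIODS}")
    return canon


def normalize_region(value: str) -> str:
    s = str(value).strip()
    for region in REGIONS:
        if s.lower() == region.lower():
            return region
    raise ValidationError(f"unknown region {value!r}; allowed: {REGIONS}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename source-dialect columns to canonical names (canonical <- source)."""
    if not column_map:
        return df
    return df.rename(columns={src: canon for canon, src in column_map.items()})


def _row_label(df: pd.DataFrame, idx) -> str:
    # +2: header line plus 1-based counting, so messages point at file lines
    return f"row {int(idx) + 2}"


# --------------------------------------------------------------------------
# Suitability table
# --------------------------------------------------------------------------

def validate_suitability(df: pd.DataFrame, valid_gcms: tuple[str, ...] = GCMS) -> pd.DataFrame:
    """Validate and canonicalise a suitability table in place-free fashion."""
    _require_columns(df, SUITABILITY_COLUMNS, "suitability table")
    out = df.loc[:, SUITABILITY_COLUMNS].copy()
    out["species_id"] = out["species_id"].astype(str)
    out["park_id"] = out["park_id"].astype(str)
    for col, fn in (("season", normalize_season), ("rcp", normalize_rcp), ("period", normalize_period)):
        try:
            out[col] = out[col].map(fn)
        except ValidationError as exc:
            bad = next(i for i, v in out[col].items() if _safe_fails(fn, v))
            raise ValidationError(f"suitability table {_row_label(out, bad)}, column {col!r}: {exc}") from None
    unknown_gcm = ~out["gcm"].astype(str).isin(valid_gcms)
    if unknown_gcm.any():
        idx = out.index[unknown_gcm][0]
        raise ValidationError(
            f"suitability table {_row_label(out, idx)}: unknown GCM "
            f"{out.loc[idx, 'gcm']!r}; allowed: {tuple(valid_gcms)}"
        )
    out["gcm"] = out["gcm"].astype(str)
    out["suitability"] = pd.to_numeric(out["suitability"], errors="coerce")
    bad = out["suitability"].isna() | (out["suitability"] < 0) | (out["suitability"] > 1)
    if bad.any():
        idx = out.index[bad][0]
        raise ValidationError(
            f"suitability table {_row_label(out, idx)}: suitability "
            f"{df.loc[idx, 'suitability']!r} outside [0, 1]"
        )
    full_key = KEY_COLUMNS + ["gcm", "period"]
    dup = out.duplicated(subset=full_key, keep=False)
    if dup.any():
        keys = out.loc[dup, full_key].drop_duplicates().head(5).to_records(index=False)
        raise ValidationError(f"suitability table: duplicate (species, park, season, rcp, gcm, period) keys, e.g. {list(keys)}")
    return out.reset_index(drop=True)


def _safe_fails(fn, v) -> bool:
    try:
        fn(v)
        return False
    except ValidationError:
        return True


def read_suitability_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    valid_gcms: tuple[str, ...] = GCMS,
) -> pd.DataFrame:
    """Read and validate a long-format suitability CSV.

    Parameters
    ----------
    path
        CSV with (possibly dialect-named) columns for species, park, season,
        RCP, GCM, period and suitability.
    column_map
        Optional mapping ``{canonical_name: source_name}`` absorbing header
        differences between data dialects.
    """
    df = pd.read_csv(path)
    return validate_suitability(_apply_column_map(df, column_map), valid_gcms=valid_gcms)


def write_suitability_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_suitability(df).to_csv(path, index=False, lineterminator="\n")


def audit_completeness(suitability: pd.DataFrame) -> pd.DataFrame:
    """Count (GCM, period) cells found per key, out of the expected 12.

    Returns one row per (species, park, season, rcp) with ``n_cells`` and
    ``complete`` columns; downstream policy decides what to do with
    incomplete keys.
    """
    counts = (
        suitability.groupby(KEY_COLUMNS, sort=True, observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    counts["complete"] = counts["n_cells"] == CELLS_PER_KEY
    return counts


# --------------------------------------------------------------------------
# Threshold table
# --------------------------------------------------------------------------

def validate_thresholds(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, THRESHOLD_COLUMNS, "threshold table")
    out = df.loc[:, THRESHOLD_COLUMNS].copy()
    out["species_id"] = out["species_id"].astype(str)
    out["season"] = out["season"].map(normalize_season)
    out["threshold"] = pd.to_numeric(out["threshold"], errors="coerce")
    bad = out["threshold"].isna() | (out["threshold"] <= 0) | (out["threshold"] >= 1)
    if bad.any():
        idx = out.index[bad][0]
        raise ValidationError(
            f"threshold table {_row_label(out, idx)}: threshold "
            f"{df.loc[idx, 'threshold']!r} not strictly inside (0, 1)"
        )
    dup = out.duplicated(subset=["species_id", "season"], keep=False)
    if dup.any():
        keys = out.loc[dup, ["species_id", "season"]].drop_duplicates().to_records(index=False)
        raise ValidationError(f"threshold table: duplicate (species, season) keys: {list(keys)}")
    return out.reset_index(drop=True)


def read_thresholds(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    return validate_thresholds(_apply_column_map(pd.read_csv(path), column_map))


def write_thresholds(df: pd.DataFrame, path: str | Path) -> None:
    validate_thresholds(df).to_csv(path, index=False, lineterminator="\n")


def missing_thresholds(suitability: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """(species, season) pairs present in the suitability table but lacking a
    threshold — reported, never silently dropped."""
    need = suitability[["species_id", "season"]].drop_duplicates()
    have = thresholds[["species_id", "season"]].drop_duplicates()
    merged = need.merge(have, how="left", indicator=True)
    return (
        merged.loc[merged["_merge"] == "left_only", ["species_id", "season"]]
        .sort_values(["species_id", "season"])
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# Park metadata table
# --------------------------------------------------------------------------

def validate_parks(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PARK_COLUMNS, "park table")
    out = df.loc[:, PARK_COLUMNS].copy()
    out["park_id"] = out["park_id"].astype(str)
    out["park_name"] = out["park_name"].astype(str)
    try:
        out["region"] = out["region"].map(normalize_region)
    except ValidationError as exc:
        raise ValidationError(f"park table: {exc}") from None
    out["latitude"] = pd.to_numeric(out["latitude"], errors="coerce")
    # Longitude is stored signed (negative = west of Greenwich).
    out["longitude"] = pd.to_numeric(out["longitude"], errors="coerce")
    bad = out["latitude"].isna() | (out["latitude"] < 24) | (out["latitude"] > 72)
    if bad.any():
        idx = out.index[bad][0]
        raise ValidationError(
            f"park table {_row_label(out, idx)}: latitude "
            f"{df.loc[idx, 'latitude']!r} outside [24, 72] degrees N"
        )
    dup = out.duplicated(subset=["park_id"], keep=False)
    if dup.any():
        raise ValidationError(
            f"park table: duplicate park_id values: {sorted(out.loc[dup, 'park_id'].unique())}"
        )
    return out.reset_index(drop=True)


def read_parks(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    return validate_parks(_apply_column_map(pd.read_csv(path), column_map))


def write_parks(df: pd.DataFrame, path: str | Path) -> None:
    validate_parks(df).to_csv(path, index=False, lineterminator="\n")
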