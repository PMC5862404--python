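"""Synthetic suitability ensembles with planted ground-truth trend classes.

Every downstream stage (trend regression, five-way classification, turnover,
typology, comparative statistics) is testable without any external data by
generating species x park suitability trajectories whose trend class is known
by construction.

For each species x park x season x RCP key the generator draws a planted
class, builds a deterministic linear mean trajectory ``m(year)`` positioned
relative to the species' suitability threshold ``t`` so that a correct
classifier must recover the class, then adds independent Gaussian noise per
GCM x period (clipped to [0, 1]):

* ``improving`` / ``worsening`` — slope ±``slope_scale``, with both the
  present and mid-century means kept at least half the 50.5-year excursion
  away from ``t`` on the same side, so no crossing rule fires;
* ``stable`` — zero slope, mean kept away from ``t`` by the same margin;
* ``potential_colonization`` — the mean crosses ``t`` upward, from
  ``t − Δ/2`` at present to ``t + Δ/2`` at mid-century (Δ = slope_scale x
  span);
* ``potential_extirpation`` — the mirror image, slope −``slope_scale``.

Structural draws (classes, thresholds, trajectory positions) and noise draws
come from separate seeded streams, so scenarios that differ only in
``noise_sd`` share identical mean trajectories and perfectly correlated
noise — the recovery-vs-noise curve is monotone by construction, not by luck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    GCMS,
    PARK_COLUMNS,
    PERIODS,
    RCPS,
    REGIONS,
    SEASONS,
    SUITABILITY_COLUMNS,
    TREND_CATEGORIES,
    ValidationError,
)

logger = logging.getLogger("avichange")

#: Calendar-year midpoints of the three periods (matches the classifier).
PERIOD_YEARS: dict[str, float] = {"present": 2005.0, "2011-2040": 2025.5, "2041-2070": 2055.5}
_SPAN = PERIOD_YEARS["2041-2070"] - PERIOD_YEARS["present"]  # 50.5 years

#: Park counts by region in the studied protected-area system, used as the
#: default region weights: Alaska, Pacific West, Intermountain, Midwest,
#: Southeast, National Capital, Northeast.
REGION_PARK_COUNTS: dict[str, int] = {
    "Alaska": 16, "Pacific West": 39, "Intermountain": 82, "Midwest": 36,
    "Southeast": 44, "National Capital": 18, "Northeast": 39,
}

#: Typical latitude bands (degrees N) per region. Alaska sits strictly above
#: 54°N so that the Alaska-exclusion rule in the latitudinal regressions is
#: always exercised on synthetic cohorts.
REGION_LATITUDE_BANDS: dict[str, tuple[float, float]] = {
    "Alaska": (55.0, 68.0), "Pacific West": (32.5, 49.0), "Intermountain": (31.0, 49.0),
    "Midwest": (36.5, 49.0), "Southeast": (25.0, 37.0), "National Capital": (38.5, 39.7),
    "Northeast": (38.0, 47.0),
}

#: Typical longitude bands (signed degrees, negative = west).
REGION_LONGITUDE_BANDS: dict[str, tuple[float, float]] = {
    "Alaska": (-164.0, -131.0), "Pacific West": (-124.5, -115.0),
    "Intermountain": (-117.0, -102.0), "Midwest": (-104.0, -82.0),
    "Southeast": (-94.5, -75.5), "National Capital": (-77.5, -76.8),
    "Northeast": (-80.5, -68.0),
}

#: Default planted-class probabilities, in TREND_CATEGORIES order
#: (improving, stable, worsening, potential_extirpation,
#: potential_colonization). Crossing classes carry weight ~0.2 each, echoing
#: typical per-park colonization/extirpation proportions under a
#: high-emissions pathway; stable is the minority class because by
#: mid-century most trajectories trend detectably in that regime.
DEFAULT_CLASS_MIX: tuple[float, ...] = (0.25, 0.10, 0.25, 0.20, 0.20)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    ``slope_scale`` is the magnitude of the planted trend in suitability
    units per year for non-stable classes; ``noise_sd`` is the standard
    deviation of the additive per-GCM-per-period Gaussian noise (both
    dimensionless suitability units).
    """

    n_parks: int = 30
    n_species: int = 40
    seasons: tuple[str, ...] = SEASONS
    rcps: tuple[str, ...] = RCPS
    class_mix: tuple[float, ...] = DEFAULT_CLASS_MIX
    noise_sd: float = 0.01
    threshold_range: tuple[float, float] = (0.25, 0.75)
    slope_scale: float = 0.002
    seed: int = 0
    n_gcm: int = field(default=4, init=False)

    def __post_init__(self) -> None:
        if self.n_parks < 1 or self.n_species < 1:
            raise ValidationError("n_parks and n_species must be positive")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (5,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("class_mix must be 5 nonnegative probabilities summing to 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.slope_scale <= 0:
            raise ValidationError("slope_scale must be > 0")
        lo, hi = self.threshold_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("threshold_range must lie strictly inside (0, 1)")
        # Geometry feasibility: every class needs room for the full
        # excursion Δ plus the Δ/2 safety margin on at least one side of any
        # drawn threshold.
        delta = self.slope_scale * _SPAN
        if lo < 1.5 * delta and hi > 1 - 1.5 * delta:
            raise ValidationError(
                f"infeasible geometry: threshold_range {self.threshold_range} leaves no room "
                f"for a {delta:.3f} suitability excursion over {_SPAN:.1f} years on either side"
            )

    @property
    def delta(self) -> float:
        """Planted present-to-mid-century excursion |m(mid) − m(present)|."""
        return self.slope_scale * _SPAN


def _child(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stream])


def generate_park_metadata(
    n_parks: int,
    region_weights: Mapping[str, float] | None = None,
    latitude_by_region: Mapping[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    require_all_regions: bool = False,
) -> pd.DataFrame:
    """Generate a park metadata table with region counts apportioned from
    ``region_weights`` by deterministic largest-remainder rounding.

    With the default weights (the real per-region park counts) and
    ``n_parks=274`` the apportionment reproduces the counts exactly.
    """
    weights = dict(region_weights) if region_weights is not None else dict(REGION_PARK_COUNTS)
    unknown = set(weights) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region(s) in weights: {sorted(unknown)}")
    w = np.array([float(weights.get(r, 0.0)) for r in REGIONS])
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("region weights must be nonnegative and not all zero")
    n_positive = int((w > 0).sum())
    if require_all_regions and n_parks < n_positive:
        raise ValidationError(
            f"n_parks={n_parks} cannot cover all {n_positive} positively weighted regions"
        )
    quotas = n_parks * w / w.sum()
    counts = np.floor(quotas).astype(int)
    # largest fractional remainders win the leftover seats; ties break by
    # REGIONS order (stable argsort)
    leftover = n_parks - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:leftover]] += 1

    lat_bands = dict(REGION_LATITUDE_BANDS)
    if latitude_by_region:
        lat_bands.update(latitude_by_region)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    k = 0
    for region, n in zip(REGIONS, counts):
        lat_lo, lat_hi = lat_bands[region]
        lon_lo, lon_hi = REGION_LONGITUDE_BANDS[region]
        for _ in range(n):
            k += 1
            rows.append(
                {
                    "park_id": f"P{k:03d}",
                    "park_name": f"Synthetic Park {k:03d}",
                    "region": region,
                    "latitude": round(float(rng.uniform(lat_lo, lat_hi)), 4),
                    "longitude": round(float(rng.uniform(lon_lo, lon_hi)), 4),
                }
            )
    return pd.DataFrame(rows, columns=PARK_COLUMNS)


def _sample_outside(rng: np.random.Generator, lo: float, hi: float, gap_lo: float, gap_hi: float) -> float:
    """Uniform draw from [lo, hi] excluding (gap_lo, gap_hi), via one uniform."""
    left = max(0.0, min(gap_lo, hi) - lo)
    right = max(0.0, hi - max(gap_hi, lo))
    if left + right <= 0:
        raise ValidationError("infeasible geometry: no admissible stable mean")
    u = rng.uniform(0.0, left + right)
    return lo + u if u <= left else max(gap_hi, lo) + (u - left)


def _plant_trajectory(
    rng: np.random.Generator, planted: str, t: float, delta: float
) -> tuple[float, float]:
    """Return (m_present, m_mid) for one key given its planted class."""
    margin = delta / 2.0
    lo, hi = 0.01, 0.99
    if planted == "stable":
        m = _sample_outside(rng, lo, hi, t - margin, t + margin)
        return m, m
    if planted == "potential_colonization":
        return t - margin, t + margin
    if planted == "potential_extirpation":
        return t + margin, t - margin
    if planted == "improving":
        # both endpoints on one side of t; choose a feasible side
        above = (t + margin, hi - delta)       # m_present range, m_mid = m_present + delta
        below = (lo, t - margin - delta)
        side = _choose_side(rng, above, below)
        m_present = rng.uniform(*side)
        return m_present, m_present + delta
    if planted == "worsening":
        above = (t + margin + delta, hi)       # m_mid = m_present - delta stays above t
        below = (lo + delta, t - margin)
        side = _choose_side(rng, above, below)
        m_present = rng.uniform(*side)
        return m_present, m_present - delta
    raise ValidationError(f"unknown planted class {planted!r}")


def _choose_side(rng, a: tuple[float, float], b: tuple[float, float]) -> tuple[float, float]:
    feas_a, feas_b = a[0] < a[1], b[0] < b[1]
    pick = rng.uniform()  # always consumed, keeps the draw count class-invariant
    if feas_a and feas_b:
        return a if pick < 0.5 else b
    if feas_a:
        return a
    if feas_b:
        return b
    raise ValidationError("infeasible geometry: threshold too close to both bounds")


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(suitability, thresholds, parks, truth)`` tables.

    ``truth`` carries one row per key with the planted class, the true slope
    in suitability/year, the true present-period mean, and the threshold the
    trajectory was positioned against. Identical config (including seed)
    yields identical tables.
    """
    rng_struct = _child(config.seed, 1)
    rng_noise = _child(config.seed, 2)
    rng_parks = _child(config.seed, 3)

    parks = generate_park_metadata(config.n_parks, seed=rng_parks)
    species = [f"SP{i:04d}" for i in range(1, config.n_species + 1)]
    seasons = tuple(config.seasons)
    rcps = tuple(config.rcps)

    thr_rows = []
    thr_lookup: dict[tuple[str, str], float] = {}
    lo, hi = config.threshold_range
    for sp in species:
        for season in seasons:
            t = float(rng_struct.uniform(lo, hi))
            thr_rows.append({"species_id": sp, "season": season, "threshold": round(t, 6)})
            thr_lookup[(sp, season)] = round(t, 6)
    thresholds = pd.DataFrame(thr_rows)

    delta = config.delta
    years = np.array([PERIOD_YEARS[p] for p in PERIODS])
    keys = [
        (sp, park, season, rcp)
        for sp in species
        for park in parks["park_id"]
        for season in seasons
        for rcp in rcps
    ]
    n_keys = len(keys)
    classes = rng_struct.choice(len(TREND_CATEGORIES), size=n_keys, p=np.asarray(config.class_mix))

    m_present = np.empty(n_keys)
    m_mid = np.empty(n_keys)
    for i, (sp, park, season, rcp) in enumerate(keys):
        t = thr_lookup[(sp, season)]
        m_present[i], m_mid[i] = _plant_trajectory(
            rng_struct, TREND_CATEGORIES[classes[i]], t, delta
        )
    true_slope = (m_mid - m_present) / _SPAN
    # mean trajectory evaluated at the three period midpoints: (n_keys, 3)
    means = m_present[:, None] + true_slope[:, None] * (years[None, :] - years[0])

    # noise drawn from its own stream: (n_keys, 3 periods, 4 GCMs)
    z = rng_noise.standard_normal((n_keys, len(PERIODS), len(GCMS)))
    values = np.clip(means[:, :, None] + config.noise_sd * z, 0.0, 1.0)

    key_arr = np.array(keys, dtype=object)
    suit = pd.DataFrame(
        {
            "species_id": np.repeat(key_arr[:, 0], len(PERIODS) * len(GCMS)),
            "park_id": np.repeat(key_arr[:, 1], len(PERIODS) * len(GCMS)),
            "season": np.repeat(key_arr[:, 2], len(PERIODS) * len(GCMS)),
            "rcp": np.repeat(key_arr[:, 3], len(PERIODS) * len(GCMS)),
            "gcm": np.tile(np.repeat(GCMS, 1), n_keys * len(PERIODS)),
            "period": np.tile(np.repeat(PERIODS, len(GCMS)), n_keys),
            "suitability": values.reshape(-1).round(6),
        },
        columns=SUITABILITY_COLUMNS,
    )

    truth = pd.DataFrame(
        {
            "species_id": key_arr[:, 0],
            "park_id": key_arr[:, 1],
            "season": key_arr[:, 2],
            "rcp": key_arr[:, 3],
            "planted_class": [TREND_CATEGORIES[c] for c in classes],
            "true_slope": true_slope.round(10),
            "true_present_mean": m_present.round(6),
            "threshold": [thr_lookup[(sp, se)] for sp, _, se, _ in keys],
        }
    )
    logger.info(
        "generated scenario: %d keys (%d species x %d parks x %d seasons x %d RCPs), noise_sd=%g",
        n_keys, config.n_species, config.n_parks, len(seasons), len(rcps), config.noise_sd,
    )
    return suit, thresholds, parks, truth
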