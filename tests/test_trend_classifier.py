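import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avichange.data_model import GCMS, PERIODS, TrendFit, ValidationError
from avichange.trend_classifier import (
    MIDPOINT_YEARS,
    ClassifierSettings,
    classify,
    classify_all,
    detect_year_round,
    fit_trend,
    species_included,
    year_round_table,
)

from conftest import make_key_df, ols_closed_form


def _fit(present_mean, mid_mean, slope, p):
    return TrendFit(slope=slope, intercept=0.0, p_value=p, n_points=12,
                    present_mean=present_mean, mid_mean=mid_mean)


# ---------------------------------------------------------------- fit_trend

def test_constant_input_gives_zero_slope_p_one():
    df = make_key_df({p: [0.5] * 4 for p in PERIODS})
    fit = fit_trend(df)
    assert fit.slope == 0.0
    assert fit.p_value == 1.0
    assert fit.present_mean == fit.mid_mean == 0.5


def test_noiseless_line_recovered_exactly():
    years = MIDPOINT_YEARS
    df = make_key_df({p: [0.1 + 0.002 * (years[p] - 2005)] * 4 for p in PERIODS})
    fit = fit_trend(df)
    assert fit.slope == pytest.approx(0.002, abs=1e-14)
    assert fit.p_value == 0.0  # perfect non-constant fit
    assert classify(fit, threshold=0.05) == "improving"


@pytest.mark.parametrize("seed", range(25))
def test_slope_matches_closed_form_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = {p: rng.uniform(0, 1, size=4) for p in PERIODS}
    df = make_key_df(vals)
    fit = fit_trend(df)
    x = np.array([MIDPOINT_YEARS[p] for p in df["period"]])
    slope, intercept, p = ols_closed_form(x, df["suitability"].to_numpy())
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.intercept == pytest.approx(intercept, abs=1e-9)
    assert fit.p_value == pytest.approx(p, abs=1e-10)


def test_fit_requires_two_periods_and_bounded_values():
    with pytest.raises(ValidationError, match="2 distinct"):
        fit_trend(make_key_df({"present": [0.5] * 4}))
    bad = make_key_df({p: [0.5] * 4 for p in PERIODS})
    bad.loc[0, "suitability"] = 1.2
    with pytest.raises(ValidationError, match="outside"):
        fit_trend(bad)


def test_ordinal_time_coding_scales_slope():
    from avichange.trend_classifier import ORDINAL_YEARS

    years = MIDPOINT_YEARS
    df = make_key_df({p: [0.2 + 0.002 * (years[p] - 2005)] * 4 for p in PERIODS})
    fit = fit_trend(df, ClassifierSettings(period_years=ORDINAL_YEARS))
    # unequal calendar spacing means ordinal coding is a genuinely different
    # regressor; slope must be positive but not 0.002-per-unit
    assert fit.slope > 0
    assert fit.slope != pytest.approx(0.002)


# ----------------------------------------------------------------- classify

def test_downward_crossing_with_significant_decline_is_extirpation():
    fit = _fit(present_mean=0.6, mid_mean=0.2, slope=-0.008, p=0.001)
    assert classify(fit, threshold=0.4) == "potential_extirpation"


def test_upward_crossing_is_colonization_regardless_of_p():
    fit = _fit(present_mean=0.3, mid_mean=0.5, slope=0.004, p=0.9)
    assert classify(fit, threshold=0.4) == "potential_colonization"
    strict = ClassifierSettings(colonization_requires_significance=True)
    assert classify(fit, threshold=0.4, settings=strict) == "stable"


def test_constant_above_threshold_is_stable():
    fit = _fit(present_mean=0.5, mid_mean=0.5, slope=0.0, p=1.0)
    assert classify(fit, threshold=0.4) == "stable"


def test_nonsignificant_downward_crossing_falls_back_to_trend_test():
    """Extirpation is a subset of worsening: without slope significance a
    downward crossing classifies by the trend test alone."""
    fit = _fit(present_mean=0.45, mid_mean=0.35, slope=-0.002, p=0.4)
    assert classify(fit, threshold=0.4) == "stable"
    fit_sig = _fit(present_mean=0.45, mid_mean=0.35, slope=-0.002, p=0.01)
    assert classify(fit_sig, threshold=0.4) == "potential_extirpation"


def test_extirpation_without_crossing_is_worsening():
    """Same significant decline, threshold below both endpoints: worsening."""
    fit = _fit(present_mean=0.6, mid_mean=0.4, slope=-0.004, p=0.001)
    assert classify(fit, threshold=0.3) == "worsening"
    assert classify(fit, threshold=0.5) == "potential_extirpation"


def test_alpha_limits_govern_reachable_categories():
    improving = _fit(present_mean=0.5, mid_mean=0.6, slope=0.002, p=0.04)
    near_one = ClassifierSettings(alpha=1 - 1e-9)
    tiny = ClassifierSettings(alpha=1e-12)
    # alpha -> 1: any nonzero slope is significant, stable unreachable
    assert classify(improving, 0.2, near_one) == "improving"
    # alpha -> 0: only crossing rules and stable survive
    assert classify(improving, 0.2, tiny) == "stable"
    crossing = _fit(present_mean=0.3, mid_mean=0.5, slope=0.004, p=0.04)
    assert classify(crossing, 0.4, tiny) == "potential_colonization"


# -------------------------------------------------------- inclusion / year-round

@given(
    present=st.floats(0, 1, allow_nan=False),
    mid=st.floats(0, 1, allow_nan=False),
    threshold=st.floats(0.01, 0.99, allow_nan=False),
)
@settings(max_examples=200, derandomize=True)
def test_inclusion_rule_matches_brute_force(present, mid, threshold):
    fit = _fit(present_mean=present, mid_mean=mid, slope=0.0, p=1.0)
    expected = (present >= threshold) or (mid >= threshold)
    assert species_included(fit, threshold) == expected


def test_year_round_detection_cases():
    summer = _fit(present_mean=0.6, mid_mean=0.6, slope=0.0, p=1.0)
    winter_colonizing = _fit(present_mean=0.3, mid_mean=0.5, slope=0.004, p=0.01)
    winter_already = _fit(present_mean=0.5, mid_mean=0.6, slope=0.002, p=0.01)
    assert detect_year_round(summer, winter_colonizing, 0.4, 0.4)
    assert not detect_year_round(summer, winter_already, 0.4, 0.4)
    summer_unsuitable = _fit(present_mean=0.2, mid_mean=0.2, slope=0.0, p=1.0)
    assert not detect_year_round(summer_unsuitable, winter_colonizing, 0.4, 0.4)


# ------------------------------------------------------------- classify_all

def _thresholds_for(suit, value=0.4):
    keys = suit[["species_id", "season"]].drop_duplicates()
    return keys.assign(threshold=value)


def test_classify_all_recovers_noiseless_truth(noiseless_scenario):
    suit, thr, _, truth = noiseless_scenario
    cls = classify_all(suit, thr, drop_excluded=False)
    merged = cls.merge(truth, on=["species_id", "park_id", "season", "rcp"])
    assert len(merged) == len(truth)
    assert (merged["category"] == merged["planted_class"]).all()


def test_classify_all_empty_input_gives_empty_output():
    empty = pd.DataFrame(columns=["species_id", "park_id", "season", "rcp", "gcm", "period", "suitability"])
    thr = pd.DataFrame(columns=["species_id", "season", "threshold"])
    assert classify_all(empty, thr).empty


def test_classify_all_invariant_to_row_and_gcm_permutation(small_scenario):
    suit, thr, _, _ = small_scenario
    base = classify_all(suit, thr)
    shuffled = suit.sample(frac=1.0, random_state=0).reset_index(drop=True)
    relabeled = shuffled.assign(
        gcm=shuffled["gcm"].map(dict(zip(GCMS, np.roll(GCMS, 1))))
    )
    for variant in (shuffled, relabeled):
        out = classify_all(variant, thr)
        pd.testing.assert_frame_equal(
            base.sort_values(["species_id", "park_id", "season", "rcp"]).reset_index(drop=True),
            out.sort_values(["species_id", "park_id", "season", "rcp"]).reset_index(drop=True),
        )


def test_classify_all_missing_threshold_errors(small_scenario):
    suit, thr, _, _ = small_scenario
    with pytest.raises(ValidationError, match="SP0001"):
        classify_all(suit, thr[thr["species_id"] != "SP0001"])


def test_classify_all_incomplete_key_policy(small_scenario):
    suit, thr, _, truth = small_scenario
    damaged = suit.iloc[1:]  # drop one cell of one key
    with pytest.raises(ValidationError, match="permissive"):
        classify_all(damaged, thr)
    out = classify_all(damaged, thr, permissive=True, drop_excluded=False)
    assert len(out) == len(truth) - 1


def test_excluded_species_dropped_by_default(small_scenario):
    suit, thr, _, _ = small_scenario
    full = classify_all(suit, thr, drop_excluded=False)
    default = classify_all(suit, thr)
    assert len(default) == int(full["included"].sum())
    assert default["included"].all()


def test_year_round_table_counts_match_manual(small_scenario):
    suit, thr, _, _ = small_scenario
    full = classify_all(suit, thr, drop_excluded=False)
    yr = year_round_table(full)
    wide = full.pivot_table(
        index=["species_id", "park_id", "rcp"], columns="season",
        values=["present_mean", "mid_mean", "threshold"], aggfunc="first",
    )
    manual = (
        (wide[("present_mean", "summer")] >= wide[("threshold", "summer")])
        & (wide[("present_mean", "winter")] < wide[("threshold", "winter")])
        & (wide[("mid_mean", "winter")] >= wide[("threshold", "winter")])
    )
    got = yr.set_index(["species_id", "park_id", "rcp"])["year_round"]
    assert got.sort_index().equals(manual.sort_index())
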