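import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from avichange.community_change import (
    bray_curtis_binary,
    species_lists,
    summarize_park,
    summarize_parks,
    systemwide_summary,
)
from avichange.data_model import ValidationError
from avichange.trend_classifier import classify_all, year_round_table


def _cls_frame(rows, park="P1", season="summer", rcp="RCP8.5"):
    """Classification rows for one park group from (species, category,
    present_suitable) triples."""
    data = []
    for species, category, present_suitable in rows:
        data.append(
            {
                "species_id": species, "park_id": park, "season": season, "rcp": rcp,
                "category": category,
                "present_mean": 0.6 if present_suitable else 0.2,
                "mid_mean": 0.6 if category != "potential_extirpation" else 0.2,
                "threshold": 0.4,
                "included": True,
            }
        )
    return pd.DataFrame(data)


def _vector_oracle(present_set, future_set):
    """Independent vector-form Bray-Curtis on 0/1 abundance vectors."""
    universe = sorted(present_set | future_set)
    u = np.array([s in present_set for s in universe], dtype=float)
    v = np.array([s in future_set for s in universe], dtype=float)
    return float(scipy_braycurtis(u, v))


def test_species_lists_set_algebra():
    cls = _cls_frame(
        [("A", "stable", True), ("B", "improving", True),
         ("C", "potential_extirpation", True), ("D", "potential_colonization", False)]
    )
    present, future = species_lists(cls)
    assert present == {"A", "B", "C"}
    assert future == {"A", "B", "D"}


def test_species_lists_no_change():
    cls = _cls_frame([("A", "stable", True), ("B", "worsening", True)])
    present, future = species_lists(cls)
    assert present == future == {"A", "B"}


def test_species_lists_match_brute_force_reconstruction():
    rng = np.random.default_rng(0)
    categories = ["improving", "stable", "worsening", "potential_extirpation",
                  "potential_colonization"]
    for _ in range(50):
        rows = []
        for i in range(rng.integers(1, 20)):
            cat = categories[rng.integers(5)]
            suitable = cat != "potential_colonization" and rng.uniform() < 0.8
            rows.append((f"S{i}", cat, suitable))
        present, future = species_lists(_cls_frame(rows))
        expected_present = {s for s, c, suit in rows if suit}
        expected_future = (
            expected_present
            - {s for s, c, _ in rows if c == "potential_extirpation"}
        ) | {s for s, c, _ in rows if c == "potential_colonization"}
        assert present == expected_present
        assert future == expected_future


def test_bray_curtis_identical_and_disjoint():
    assert bray_curtis_binary({"A", "B"}, {"A", "B"}) == 0.0
    assert bray_curtis_binary({"A", "B"}, {"C"}) == 1.0
    assert bray_curtis_binary({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(1 / 3)


def test_bray_curtis_both_empty_is_undefined():
    assert math.isnan(bray_curtis_binary(set(), set()))


@given(
    present=st.sets(st.integers(0, 30), min_size=1, max_size=20),
    future=st.sets(st.integers(0, 30), max_size=20),
)
@settings(max_examples=200, derandomize=True)
def test_bray_curtis_matches_vector_form_oracle(present, future):
    got = bray_curtis_binary(present, future)
    assert got == pytest.approx(_vector_oracle(present, future), abs=1e-12)
    assert 0.0 <= got <= 1.0


def test_bray_curtis_monotone_in_change_counts():
    """Holding richness fixed, adding one more colonization (or extirpation)
    never decreases turnover."""
    richness = 30
    present = {f"S{i}" for i in range(richness)}
    for n_ext in range(0, 10):
        for n_col in range(0, 10):
            def bc(ne, nc):
                future = (present - {f"S{i}" for i in range(ne)}) | {f"N{i}" for i in range(nc)}
                return bray_curtis_binary(present, future)

            assert bc(n_ext, n_col + 1) >= bc(n_ext, n_col)
            assert bc(n_ext + 1, n_col) >= bc(n_ext, n_col)


def test_summarize_park_hand_computed_example():
    """100 present species, 28 colonizations, 20 extirpations."""
    rows = (
        [(f"P{i}", "stable", True) for i in range(80)]
        + [(f"E{i}", "potential_extirpation", True) for i in range(20)]
        + [(f"C{i}", "potential_colonization", False) for i in range(28)]
    )
    summary = summarize_park(_cls_frame(rows))
    assert summary["richness_present"] == 100
    assert summary["richness_future"] == 108
    assert summary["prop_colonization"] == pytest.approx(0.28)
    assert summary["prop_extirpation"] == pytest.approx(0.20)
    assert summary["richness_ratio"] == pytest.approx(1.08)
    assert summary["bray_curtis"] == pytest.approx(48 / 208)
    assert summary["realization_fraction"] == pytest.approx(20 / 28)


def test_summarize_park_zero_change():
    summary = summarize_park(_cls_frame([("A", "stable", True), ("B", "improving", True)]))
    assert summary["bray_curtis"] == 0.0
    assert summary["prop_colonization"] == 0.0
    assert summary["richness_ratio"] == 1.0


def test_realization_fraction_undefined_without_colonizations():
    rows = [("A", "stable", True)] + [(f"E{i}", "potential_extirpation", True) for i in range(3)]
    summary = summarize_park(_cls_frame(rows))
    assert math.isnan(summary["realization_fraction"])


def test_zero_present_richness_flags_proportions():
    summary = summarize_park(_cls_frame([("A", "potential_colonization", False)]))
    assert summary["richness_present"] == 0
    assert math.isnan(summary["prop_colonization"])
    assert summary["bray_curtis"] == 1.0  # empty -> {A} is complete turnover


def test_conservation_identity_on_synthetic_cohort(small_scenario):
    suit, thr, _, _ = small_scenario
    cls = classify_all(suit, thr, drop_excluded=False)
    summaries = summarize_parks(
        cls[cls["included"]].reset_index(drop=True), year_round=year_round_table(cls)
    )
    assert len(summaries)
    lhs = summaries["richness_future"]
    rhs = summaries["richness_present"] - summaries["n_extirpation"] + summaries["n_colonization"]
    assert lhs.equals(rhs)
    defined = summaries["bray_curtis"].dropna()
    assert defined.between(0, 1).all()


def test_systemwide_mean_and_se_hand_checked():
    summaries = pd.DataFrame(
        {
            "park_id": ["P1", "P2"], "season": ["summer"] * 2, "rcp": ["RCP8.5"] * 2,
            "richness_present": [10, 10], "richness_future": [10, 10],
            "n_colonization": [2, 3], "n_extirpation": [2, 3],
            "prop_colonization": [0.2, 0.3], "prop_extirpation": [0.2, 0.3],
            "bray_curtis": [0.2, 0.3], "richness_ratio": [1.0, 1.0],
            "realization_fraction": [1.0, 1.0], "n_year_round": [1, 3],
        }
    )
    agg = systemwide_summary(summaries).iloc[0]
    assert agg["mean_bray_curtis"] == pytest.approx(0.25)
    assert agg["se_bray_curtis"] == pytest.approx(0.05)
    assert agg["mean_n_year_round"] == pytest.approx(2.0)
    assert agg["n_parks_col_exceed_ext"] == 0


def test_systemwide_identical_parks_have_zero_se():
    summaries = pd.DataFrame(
        {
            "park_id": ["P1", "P2", "P3"], "season": ["winter"] * 3, "rcp": ["RCP2.6"] * 3,
            "richness_present": [10] * 3, "richness_future": [10] * 3,
            "n_colonization": [1] * 3, "n_extirpation": [0] * 3,
            "prop_colonization": [0.1] * 3, "prop_extirpation": [0.0] * 3,
            "bray_curtis": [0.05] * 3, "richness_ratio": [1.1] * 3,
            "realization_fraction": [0.0] * 3, "n_year_round": [0] * 3,
        }
    )
    agg = systemwide_summary(summaries).iloc[0]
    assert agg["se_bray_curtis"] == pytest.approx(0.0, abs=1e-15)


def test_quarter_threshold_is_strict():
    """A park at exactly 25% colonization does not count as 'more than 25%'."""
    summaries = pd.DataFrame(
        {
            "park_id": ["P1", "P2"], "season": ["summer"] * 2, "rcp": ["RCP8.5"] * 2,
            "richness_present": [4, 4], "richness_future": [5, 6],
            "n_colonization": [1, 2], "n_extirpation": [0, 0],
            "prop_colonization": [0.25, 0.5], "prop_extirpation": [0.0, 0.0],
            "bray_curtis": [0.1, 0.2], "richness_ratio": [1.25, 1.5],
            "realization_fraction": [0.0, 0.0], "n_year_round": [0, 0],
        }
    )
    agg = systemwide_summary(summaries).iloc[0]
    assert agg["n_parks_col_gt25"] == 1


def test_systemwide_invariant_to_park_order(small_scenario):
    suit, thr, _, _ = small_scenario
    cls = classify_all(suit, thr)
    summaries = summarize_parks(cls)
    a = systemwide_summary(summaries)
    b = systemwide_summary(summaries.sample(frac=1.0, random_state=1))
    pd.testing.assert_frame_equal(a, b)


def test_systemwide_empty_errors():
    with pytest.raises(ValidationError):
        systemwide_summary(pd.DataFrame(columns=["season", "rcp"]))
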