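"""Outcome adjudication, free-days arithmetic, exact tests and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sepsig import (
    OutcomeRecord,
    classify_cci,
    compare_groups,
    fisher_exact_2x2,
    format_count_pct,
    free_days,
    rxc_exact_test,
)
from sepsig.outcomes import (
    OutcomeError,
    days_between,
    format_median_iqr,
    outcomes_from_frame,
    outcomes_to_frame,
)

from oracles import fisher_enumeration, free_days_by_day_count


def record(**kw):
    defaults = dict(
        patient_id="p", death_day=None, icu_los=5, hospital_los=10,
        ventilator_days=2, rrt_days=0,
        day14_sofa={"cardiovascular": 0, "respiratory": 0, "cns": 0,
                    "liver": 0, "coagulation": 0, "renal": 0},
    )
    defaults.update(kw)
    return OutcomeRecord(**defaults)


# -- CCI adjudication ------------------------------------------------------

def test_early_death_wins():
    assert classify_cci(record(death_day=10)) == "early_death"
    assert classify_cci(record(death_day=14)) == "early_death"  # 'within 14 d' inclusive


def test_cci_cardiovascular_gate():
    sofa = {"cardiovascular": 1, "respiratory": 0, "cns": 0,
            "liver": 0, "coagulation": 0, "renal": 0}
    assert classify_cci(record(icu_los=15, day14_sofa=sofa)) == "CCI"


def test_cci_other_system_gate_requires_two():
    sofa = {"cardiovascular": 0, "respiratory": 1, "cns": 0,
            "liver": 0, "coagulation": 0, "renal": 0}
    assert classify_cci(record(icu_los=20, day14_sofa=sofa)) == "non_CCI"
    sofa["renal"] = 2
    assert classify_cci(record(icu_los=20, day14_sofa=sofa)) == "CCI"


def test_short_stay_is_non_cci():
    assert classify_cci(record(icu_los=10)) == "non_CCI"


def test_long_stay_without_sofa_errors():
    with pytest.raises(OutcomeError, match="day-14 SOFA"):
        classify_cci(record(icu_los=15, day14_sofa=None))


def test_late_death_goes_through_cci_gates():
    sofa = {"cardiovascular": 2, "respiratory": 0, "cns": 0,
            "liver": 0, "coagulation": 0, "renal": 0}
    assert classify_cci(record(death_day=20, icu_los=20, day14_sofa=sofa)) == "CCI"


def test_adjudication_is_a_partition():
    rng = np.random.default_rng(0)
    cats = set()
    for _ in range(200):
        death = int(rng.integers(1, 40)) if rng.random() < 0.3 else None
        sofa = {s: int(rng.integers(0, 5)) for s in
                ("cardiovascular", "respiratory", "cns", "liver", "coagulation", "renal")}
        rec = record(death_day=death, icu_los=int(rng.integers(0, 30)), day14_sofa=sofa)
        cats.add(classify_cci(rec))
    assert cats <= {"early_death", "CCI", "non_CCI"}
    assert cats == {"early_death", "CCI", "non_CCI"}


# -- free days -------------------------------------------------------------

def test_free_days_survivor_without_outcome_gets_horizon():
    assert free_days(0, None) == 28


def test_free_days_death_censoring_hand_value():
    assert free_days(4, 10) == 6  # min(28,10) - 4


def test_free_days_clamped_at_zero():
    assert free_days(40, None) == 0


def test_free_days_exhaustive_grid_matches_day_count_oracle():
    for outcome in range(0, 41):
        for death in [None, *range(1, 41)]:
            got = free_days(outcome, death)
            want = free_days_by_day_count(outcome, death)
            assert got == want, (outcome, death)
            assert 0 <= got <= 28


def test_free_days_negative_inputs_rejected():
    with pytest.raises(OutcomeError):
        free_days(-1, None)
    with pytest.raises(OutcomeError):
        free_days(1, -2)


def test_days_between_truncates_partial_days():
    assert days_between("2020-01-01 06:00", "2020-01-15 05:00") == 13
    assert days_between("2020-01-01 06:00", "2020-01-15 07:00") == 14


# -- exact tests -----------------------------------------------------------

def test_fisher_balanced_table_is_one():
    assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_extreme_table_hand_enumeration():
    # only the two perfectly unbalanced tables are as extreme: 2/C(10,5)
    assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-7)


def test_fisher_zero_margin_rejected():
    with pytest.raises(OutcomeError, match="margin"):
        fisher_exact_2x2(0, 0, 3, 4)


def test_fisher_matches_enumeration_all_small_tables():
    for n in range(2, 13):
        for a in range(0, n + 1):
            for b in range(0, n - a + 1):
                for c in range(0, n - a - b + 1):
                    d = n - a - b - c
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    got = fisher_exact_2x2(a, b, c, d)
                    want = fisher_enumeration(a, b, c, d)
                    assert got == pytest.approx(want, rel=1e-7, abs=1e-12), (a, b, c, d)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(0, 8), st.integers(0, 8), st.integers(1, 8))
def test_fisher_invariant_to_row_and_column_swap(a, b, c, d):
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    p = fisher_exact_2x2(a, b, c, d)
    assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-9)
    assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-9)


def test_rxc_enumeration_agrees_with_fisher_on_2x2():
    assert rxc_exact_test([[3, 1], [1, 4]]) == pytest.approx(
        fisher_exact_2x2(3, 1, 1, 4)
    )


def test_rxc_exact_three_levels():
    # independence: uniform 2x3 table should not be surprising
    p = rxc_exact_test([[3, 3, 3], [3, 3, 3]])
    assert p == pytest.approx(1.0, abs=1e-9)
    # strong association should be
    assert rxc_exact_test([[8, 0, 1], [0, 8, 1]]) < 0.001


def test_rxc_monte_carlo_close_to_exact():
    table = [[6, 2, 4], [3, 7, 5]]
    exact = rxc_exact_test(table, max_exact_n=30)
    mc = rxc_exact_test(table, max_exact_n=5, seed=1, n_mc=40_000)
    assert mc == pytest.approx(exact, abs=0.02)


# -- summaries and comparisons --------------------------------------------

def test_count_percent_rendering_matches_table_style():
    assert format_count_pct(6, 18) == "6 (33)"
    assert format_count_pct(11, 18) == "11 (61)"
    assert format_count_pct(0, 18) == "0 (0)"


def test_median_iqr_rendering():
    assert format_median_iqr([28] * 10) == "28 (28, 28)"


def test_compare_groups_identical_categoricals_p_one():
    data = pd.DataFrame({"flag": [True, False] * 10})
    group = np.array([1] * 10 + [2] * 10)
    # perfectly balanced across groups
    data["flag"] = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
    rows = compare_groups(data, group)
    assert rows[0].test == "fisher_exact"
    assert rows[0].p_value == pytest.approx(1.0)
    assert rows[0].group_summaries["1"] == "5 (50)"


def test_compare_groups_large_shift_significant():
    rng = np.random.default_rng(2)
    a = rng.standard_normal(50)
    b = rng.standard_normal(50) + 5
    data = pd.DataFrame({"marker": np.concatenate([a, b])})
    rows = compare_groups(data, np.array([1] * 50 + [2] * 50))
    assert rows[0].test == "wilcoxon"
    assert rows[0].p_value < 0.001


def test_compare_groups_normality_screen_switches_to_t():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({"x": rng.standard_normal(60)})
    group = np.array([1, 2] * 30)
    rows = compare_groups(data, group, normality_screen=True)
    assert rows[0].test == "t_test"


def test_compare_groups_requires_two_groups():
    data = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    with pytest.raises(OutcomeError, match="two groups"):
        compare_groups(data, np.array([1, 1, 1]))


def test_outcomes_csv_round_trip(tmp_path):
    recs = [record(patient_id="a"), record(patient_id="b", death_day=7.0)]
    frame = outcomes_to_frame(recs)
    path = tmp_path / "outcomes.csv"
    frame.to_csv(path, index=False)
    loaded = outcomes_from_frame(pd.read_csv(path))
    assert loaded == recs
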