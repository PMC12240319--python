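"""Frequency tables, chi-square, dose trend and time-to-onset summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from faers_dili.descriptives import (
    annual_counts,
    chi_square,
    compare_onset,
    demographics_table,
    dose_trend,
    onset_days,
    onset_samples,
    onset_summary,
    proportion,
)
from faers_dili.faers_io import parse_partial_date


class TestProportion:
    @pytest.mark.parametrize("num,den,expected", [
        (4160, 7779, 53.48),
        (0, 7779, 0.00),
        (184, 1514, 12.15),
        (1, 8, 12.50),
        (1, 3, 33.33),
    ])
    def test_half_up_two_decimals(self, num, den, expected):
        assert proportion(num, den) == expected

    def test_half_up_not_bankers(self):
        assert proportion(1, 16) == 6.25
        assert proportion(25, 1000) == 2.50
        assert proportion(125, 10000) == 1.25  # 1.25 exactly, stays
        assert proportion(1125, 100000) == 1.13  # 1.125 rounds up

    def test_zero_denominator_is_undefined(self):
        assert proportion(0, 0) != proportion(0, 0)


class TestChiSquare:
    def test_hand_evaluated_two_by_two(self):
        stat, dof, p = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, rel=1e-10)
        assert dof == 1
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_homogeneous_table_is_null(self):
        stat, dof, p = chi_square([[5, 5], [5, 5]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        stat, dof, _ = chi_square([[30, 0], [0, 30]])
        assert stat == pytest.approx(60.0) and dof == 1

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        table = rng.integers(1, 50, size=(3, 4))
        stat, dof, _ = chi_square(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, abs=1e-10)
        assert dof == 6

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[5, 5]])


def _cases(rows):
    """Case frame from (statins, dili, age_group, sex, outcome, region) rows."""
    return pd.DataFrame({
        "statins": [frozenset(r[0]) for r in rows],
        "is_dili": [r[1] for r in rows],
        "age_group": [r[2] for r in rows],
        "sex": [r[3] for r in rows],
        "worst_outcome": [r[4] for r in rows],
        "reporter": ["health_professional"] * len(rows),
        "region": [r[5] for r in rows],
    })


class TestDemographicsTable:
    def test_counts_and_percentages(self):
        dili = _cases([
            (["atorvastatin"], True, ">=65", "female", "HO", "europe"),
            (["atorvastatin"], True, "<65", "male", "DE", "europe"),
            (["simvastatin"], True, "unknown", "female", "unknown", "asia"),
        ])
        non = _cases([
            (["rosuvastatin"], False, "<65", "male", "unknown", "north_america"),
        ])
        tables = demographics_table(dili, non)
        statin = tables["statin"].counts
        assert statin.loc["atorvastatin", "dili"] == 2
        assert statin.loc["rosuvastatin", "non_dili"] == 1
        pct = tables["statin"].percentages()
        assert pct.loc["atorvastatin", "dili"] == 66.67
        out = tables["outcomes"].counts
        assert out.loc["Death", "dili"] == 1
        assert out.loc["Unknown", "non_dili"] == 1
        # every table's counts sum to the group total
        for name in ("age_group", "sex", "outcomes", "reporter", "region"):
            sums = tables[name].counts.sum()
            assert sums["dili"] == 3 and sums["non_dili"] == 1

    def test_unknown_rows_always_present(self):
        dili = _cases([(["atorvastatin"], True, "<65", "female", "HO",
                        "europe")])
        tables = demographics_table(dili, dili.iloc[0:0])
        assert "unknown" in tables["age_group"].counts.index
        assert "Unknown" in tables["outcomes"].counts.index
        # empty group: zero column, no crash
        assert tables["sex"].counts["non_dili"].sum() == 0

    def test_all_unknown_age_concentrates_in_unknown_row(self):
        dili = _cases([(["atorvastatin"], True, "unknown", "female", "HO",
                        "europe")] * 4)
        tables = demographics_table(dili, dili.iloc[0:0])
        assert tables["age_group"].counts.loc["unknown", "dili"] == 4


class TestOnsetDays:
    @pytest.mark.parametrize("start,event,expected", [
        ("20230201", "20230301", 28),
        ("20230401", "20230401", 0),
        ("202302", "20230301", None),  # month precision excluded
        ("", "20230301", None),
        ("20230401", "20230301", None),  # negative difference
    ])
    def test_calendar_arithmetic_and_precision_rule(self, start, event, expected):
        got = onset_days(parse_partial_date(event), parse_partial_date(start))
        assert got == expected


class TestOnsetSummary:
    def test_interpolated_quartiles(self):
        s = pd.DataFrame({"drug": ["x"] * 3, "onset_days": [10, 20, 30]})
        out = onset_summary(s).set_index("drug")
        assert out.loc["x", "median_days"] == 20
        assert out.loc["x", "iqr_low"] == 15 and out.loc["x", "iqr_high"] == 25

    def test_singleton(self):
        s = pd.DataFrame({"drug": ["x"], "onset_days": [40]})
        out = onset_summary(s).set_index("drug")
        assert (out.loc["x", ["median_days", "iqr_low", "iqr_high"]] == 40).all()

    def test_permutation_invariant_and_scale_equivariant(self):
        rng = np.random.default_rng(2)
        days = rng.integers(1, 400, size=50)
        s1 = pd.DataFrame({"drug": ["x"] * 50, "onset_days": days})
        s2 = s1.sample(frac=1, random_state=0)
        assert onset_summary(s1).equals(onset_summary(s2).reset_index(drop=True))
        weeks = s1.assign(onset_days=s1["onset_days"] / 7)
        a, b = onset_summary(s1), onset_summary(weeks)
        assert np.allclose(a["median_days"] / 7, b["median_days"])

    def test_empty_input(self):
        assert onset_summary(pd.DataFrame(columns=["drug", "onset_days"])).empty


class TestCompareOnset:
    def test_identical_groups_not_flagged(self):
        vals = list(range(10, 110, 10))
        s = pd.DataFrame({"drug": ["x"] * 10 + ["y"] * 10,
                          "onset_days": vals + vals})
        cmp_ = compare_onset(s)
        assert cmp_.p_value == pytest.approx(1.0)
        assert not cmp_.pairwise["flagged"].any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(3.0, 1.0, size=200))
        b = np.exp(rng.normal(4.0, 1.0, size=200))
        s = pd.DataFrame({"drug": ["x"] * 200 + ["y"] * 200,
                          "onset_days": np.concatenate([a, b])})
        assert compare_onset(s).p_value < 0.01
        assert compare_onset(s, method="kruskal").p_value < 0.01

    def test_small_group_dropped_with_note(self):
        s = pd.DataFrame({"drug": ["x"] * 5 + ["y"] * 5 + ["z"],
                          "onset_days": list(range(5)) + list(range(5)) + [9]})
        cmp_ = compare_onset(s)
        assert cmp_.dropped_groups == ["z"]
        assert cmp_.groups == ["x", "y"]

    def test_insufficient_groups_undefined(self):
        s = pd.DataFrame({"drug": ["x"] * 5, "onset_days": range(5)})
        assert not compare_onset(s).defined


class TestDoseTrend:
    def _dili(self, doses):
        return pd.DataFrame({
            "statins": [frozenset({"atorvastatin"})] * len(doses),
            "doses_mg_per_day": [{"atorvastatin": d} if d == d else {}
                                 for d in doses],
        })

    def test_flat_counts_give_zero_trend(self):
        doses = [10.0, 20.0, 40.0, 80.0] * 25
        r = dose_trend(self._dili(doses))
        assert r.trend_z == pytest.approx(0.0)
        assert r.heterogeneity_chi2 == pytest.approx(0.0)

    def test_planted_monotone_gradient_detected(self):
        rng = np.random.default_rng(4)
        levels = np.array([10.0, 20.0, 40.0, 80.0])
        doses = levels[rng.choice(4, size=500, p=[0.1, 0.2, 0.3, 0.4])]
        r = dose_trend(self._dili(list(doses)))
        assert r.trend_p < 0.01 and r.trend_z > 0

    def test_unparseable_doses_excluded_and_counted(self):
        doses = [10.0, 20.0, 40.0, 80.0, float("nan"), 15.0]
        r = dose_trend(self._dili(doses))
        assert r.n_excluded == 2
        assert int(r.counts.sum()) == 4

    def test_single_occupied_group_undefined(self):
        r = dose_trend(self._dili([10.0, 10.0]))
        assert not r.defined


class TestAnnualCounts:
    def _frame(self, years, dili_flags):
        return pd.DataFrame({"receipt_year": years, "is_dili": dili_flags})

    def test_full_range_emitted_with_zeros(self):
        out = annual_counts(self._frame([2005, 2005, 2007], [True, False, True]),
                            (2004, 2008))
        assert list(out["year"]) == [2004, 2005, 2006, 2007, 2008]
        assert list(out["dili"]) == [0, 1, 0, 1, 0]
        assert list(out["non_dili"]) == [0, 1, 0, 0, 0]

    def test_empty_input_all_zero(self):
        out = annual_counts(self._frame([], []), (2004, 2006))
        assert out["dili"].sum() == 0 and len(out) == 3
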