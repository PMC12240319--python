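"""ROR/IC estimation, the dual signal rule and background-odds recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_dili.disprop import (
    BackgroundOdds,
    ContingencyTable,
    build_contingency,
    classify_signal,
    compute_signal,
    ic_estimate,
    recover_background,
    ror_estimate,
    stratified_signals,
)

cells = st.integers(min_value=1, max_value=5000)


def brute_force_ror(a, b, c, d):
    """Independent evaluation of the closed forms (test-side oracle)."""
    ror = (a / b) / (c / d)
    half = 1.959963984540054 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, math.exp(math.log(ror) - half), math.exp(math.log(ror) + half)


def brute_force_ic(a, b, c, d):
    n = a + b + c + d
    return math.log2((a * n) / ((a + b) * (a + c)))


class TestRor:
    def test_proportional_table_is_null(self):
        ror, lo, hi = ror_estimate(ContingencyTable(10, 90, 100, 900))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_evaluated_example(self):
        ror, lo, hi = ror_estimate(ContingencyTable(20, 80, 10, 90))
        assert ror == pytest.approx(2.25)
        assert lo == pytest.approx(0.994, abs=5e-4)
        assert hi == pytest.approx(5.092, abs=5e-4)

    def test_zero_cell_yields_undefined_marker(self):
        ror, lo, hi = ror_estimate(ContingencyTable(0, 10, 5, 100))
        assert ror != ror and lo != lo and hi != hi

    def test_woolf_interval_agrees_with_statsmodels(self):
        """Independent library route for the odds-ratio interval."""
        import statsmodels.api as sm
        t = ContingencyTable(52, 1598, 1700, 98300)
        table = sm.stats.Table2x2([[t.a, t.b], [t.c, t.d]])
        ror, lo, hi = ror_estimate(t)
        assert ror == pytest.approx(table.oddsratio, rel=1e-12)
        sm_lo, sm_hi = table.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)

    @given(cells, cells, cells, cells)
    @settings(max_examples=250)
    def test_scaling_comparator_preserves_point_estimate(self, a, b, c, d):
        base, _, _ = ror_estimate(ContingencyTable(a, b, c, d))
        scaled, _, _ = ror_estimate(ContingencyTable(a, b, 10 * c, 10 * d))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_ci_width_converges_to_two_cell_limit(self):
        a, b = 20, 80
        _, lo, hi = ror_estimate(ContingencyTable(a, b, 10 ** 7, 4 * 10 ** 8))
        limit = 1.959963984540054 * math.sqrt(1 / a + 1 / b)
        assert math.log(hi / lo) / 2 == pytest.approx(limit, rel=1e-4)


class TestIc:
    def test_observed_equal_expected_is_zero(self):
        # a = expected exactly: a=10, a+b=100, a+c=100, N=1000 -> E=10
        assert ic_estimate(ContingencyTable(10, 90, 90, 810))[0] == pytest.approx(0.0)

    def test_power_of_two_example(self):
        # a=8, a+b=100, a+c=200, N=10000 -> expected 2, IC = log2(4) = 2
        t = ContingencyTable(8, 92, 192, 9708)
        assert ic_estimate(t)[0] == pytest.approx(2.0)

    def test_a_zero_is_undefined(self):
        ic, lo, hi = ic_estimate(ContingencyTable(0, 10, 5, 100))
        assert ic != ic

    def test_gamma_and_noren_bounds_bracket_the_estimate(self):
        t = ContingencyTable(30, 300, 600, 12000)
        for method in ("noren", "gamma"):
            ic, lo, hi = ic_estimate(t, ci_method=method)
            assert lo < ic < hi

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ic_estimate(ContingencyTable(1, 1, 1, 1), ci_method="bootstrap")


def test_closed_forms_match_brute_force_oracle_on_random_tables():
    """1,000 random small tables, 1e-12 relative agreement both measures."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        a, b, c, d = (int(v) for v in rng.integers(1, 2000, size=4))
        t = ContingencyTable(a, b, c, d)
        ror, lo, hi = ror_estimate(t)
        o_ror, o_lo, o_hi = brute_force_ror(a, b, c, d)
        assert math.isclose(ror, o_ror, rel_tol=1e-12)
        assert math.isclose(lo, o_lo, rel_tol=1e-12)
        assert math.isclose(hi, o_hi, rel_tol=1e-12)
        assert math.isclose(ic_estimate(t)[0], brute_force_ic(a, b, c, d),
                            rel_tol=1e-12)


def test_increasing_a_increases_both_measures():
    base = ContingencyTable(10, 100, 50, 1000)
    bigger = ContingencyTable(20, 100, 50, 1000)
    assert ror_estimate(bigger)[0] > ror_estimate(base)[0]
    assert ic_estimate(bigger)[0] > ic_estimate(base)[0]


def test_independence_gives_null_on_both_scales():
    t = ContingencyTable(10, 90, 100, 900)  # a/b == c/d
    assert ror_estimate(t)[0] == pytest.approx(1.0)
    # IC at exact independence of the margins is 0 only when a equals its
    # expectation; here E = 100*110/1100 = 10 = a
    assert ic_estimate(t)[0] == pytest.approx(0.0)


class TestSignalRule:
    def _result(self, a, ror_l, ic, ic_l):
        t = ContingencyTable(a, 1500, 10 ** 6, 10 ** 8)
        return classify_signal("x", t, (2.0, ror_l, 3.0), (ic, ic_l, ic + 1))

    def test_published_positive_row(self):
        r = self._result(169, 5.89, 2.65, 2.08)
        assert r.ror_signal and r.ic_signal and r.signal

    def test_ic_below_one_fails_despite_ror(self):
        r = self._result(52, 1.43, 0.89, -0.04)
        assert r.ror_signal and not r.ic_signal and not r.signal

    def test_fewer_than_three_cases_never_signals(self):
        r = self._result(2, 50.0, 5.0, 4.0)
        assert not r.ror_signal and not r.signal

    def test_undefined_estimates_fail_closed(self):
        t = ContingencyTable(0, 100, 50, 1000)
        r = classify_signal("x", t, (math.nan,) * 3, (math.nan,) * 3)
        assert not r.ror_signal and not r.ic_signal and not r.signal


class TestContingency:
    def test_four_case_enumeration(self):
        uni = pd.DataFrame({
            "statins": [{"x"}, {"x"}, {"y"}, {"y"}],
            "is_dili": [True, False, True, False],
        })
        t = build_contingency(uni, "x")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_drug_gives_empty_target_side(self):
        uni = pd.DataFrame({"statins": [{"y"}, {"y"}],
                            "is_dili": [True, False]})
        t = build_contingency(uni, "x")
        assert (t.a, t.b) == (0, 0) and (t.c, t.d) == (1, 1)

    def test_multi_ps_case_counts_on_target_side_of_each(self):
        uni = pd.DataFrame({"statins": [{"x", "y"}, {"y"}, set()],
                            "is_dili": [True, False, False]})
        tx = build_contingency(uni, "x")
        ty = build_contingency(uni, "y")
        assert (tx.a, tx.b, tx.c, tx.d) == (1, 0, 0, 2)
        assert (ty.a, ty.b, ty.c, ty.d) == (1, 1, 0, 1)


class TestStratified:
    def _universe(self):
        rng = np.random.default_rng(0)
        n = 6000
        young = rng.random(n) < 0.5
        target = rng.random(n) < 0.3
        p0 = 0.05
        q0 = p0 / (1 - p0)
        ror = np.where(young, 2.0, 4.0)
        odds = np.where(target, ror * q0, q0)
        dili = rng.random(n) < odds / (1 + odds)
        return pd.DataFrame({
            "statins": [{"x"} if t else set() for t in target],
            "is_dili": dili,
            "age_group": np.where(young, "<65", ">=65"),
        })

    def test_planted_stratum_rors_recovered_within_ci(self):
        uni = self._universe()
        results = {r.stratum: r for r in stratified_signals(uni, "x")}
        assert set(results) == {"<65", ">=65"}
        assert results["<65"].ror_l <= 2.0 <= results["<65"].ror_u
        assert results[">=65"].ror_l <= 4.0 <= results[">=65"].ror_u

    def test_empty_stratum_absent(self):
        uni = self._universe()
        uni = uni[uni["age_group"] == ">=65"]
        results = stratified_signals(uni, "x")
        assert [r.stratum for r in results] == [">=65"]

    def test_unknown_age_cases_excluded_from_strata(self):
        uni = pd.DataFrame({
            "statins": [{"x"}] * 6,
            "is_dili": [True, False, True, False, True, False],
            "age_group": ["<65", "<65", ">=65", ">=65", "unknown", "unknown"],
        })
        results = stratified_signals(uni, "x")
        assert sum(r.table.n for r in results) == 4


class TestRecoverBackground:
    PRINTED = {
        "atorvastatin": (4160, 78562, 3.09),
        "rosuvastatin": (1590, 40501, 2.27),
        "simvastatin": (1514, 29670, 2.96),
        "pravastatin": (220, 6142, 2.07),
    }

    def test_single_row_fit_is_exact(self):
        bg = recover_background({"only": (20, 80, 2.0)})
        assert bg.q == pytest.approx((20 / 80) / 2.0, rel=1e-12)

    def test_least_squares_matches_brute_force_grid(self):
        bg = recover_background(self.PRINTED)

        def loss(q):
            return sum(((a / b) / q - ror) ** 2 / ror ** 2
                       for a, b, ror in self.PRINTED.values())

        grid = np.linspace(0.016, 0.019, 30001)
        best = grid[np.argmin([loss(q) for q in grid])]
        assert bg.q == pytest.approx(best, rel=1e-4)
        assert bg.q == pytest.approx(0.01724, abs=2e-5)

    def test_full_fit_residuals_below_two_percent(self):
        from faers_dili.pipeline import load_printed_values
        table = load_printed_values()["signal_table"]
        rows = {d: (v["dili_cases"], v["all_ae_cases"], v["ror"])
                for d, v in table.items()}
        bg = recover_background(rows)
        for d, (a, b, ror) in rows.items():
            assert abs((a / b) / bg.q - ror) / ror < 0.02, d

    def test_degenerate_row_rejected(self):
        with pytest.raises(ValueError):
            recover_background({"x": (5, 0, 2.0)})

    def test_background_odds_invariant(self):
        bg = BackgroundOdds(q=0.02)
        assert bg.p == pytest.approx(0.02 / 1.02)
        with pytest.raises(ValueError):
            BackgroundOdds(q=0.0)
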