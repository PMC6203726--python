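"""Risk statistics against independent brute-force oracles and published
values."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ploidyrisk.stats import (annual_rate, chi_square_association, cohen_kappa,
                              combine_tests, cox_fit, km_estimate, logrank_test,
                              predictive_values, predictive_values_from_counts,
                              proportion_wald_ci)


class TestAnnualRate:
    @pytest.mark.parametrize("events, py, rate, ci", [
        (13, 122.13, 10.64, (6.18, 18.33)),   # severe grade, full cohort
        (23, 1733.07, 1.32, None),            # dysplasia axis overall
        (8, 232.55, 3.44, (1.72, 6.88)),      # aneuploid, early excluded
    ])
    def test_published_rates_reproduced(self, events, py, rate, ci):
        # printed values are truncated to 2 dp in places (1.3271 -> 1.32),
        # so compare at printed precision rather than by rounding
        est = annual_rate(events, py)
        assert abs(est.annual_rate_pct - rate) < 0.01
        if ci is not None:
            assert round(est.ci95[0], 2) == ci[0]
            assert round(est.ci95[1], 2) == ci[1]

    def test_zero_events_zero_rate_null_ci(self):
        est = annual_rate(0, 22.68)
        assert est.annual_rate_pct == 0.0 and est.ci95 is None

    def test_invalid_person_years(self):
        with pytest.raises(ValueError):
            annual_rate(1, 0.0)

    @given(events=st.integers(1, 50), py=st.floats(1.0, 500.0),
           k=st.integers(2, 5))
    def test_homogeneity_scaling(self, events, py, k):
        # same rate, tighter CI when events and person-time scale together
        a = annual_rate(events, py)
        b = annual_rate(events * k, py * k)
        assert b.annual_rate_pct == pytest.approx(a.annual_rate_pct)
        assert (b.ci95[1] - b.ci95[0]) < (a.ci95[1] - a.ci95[0])


class TestWaldCI:
    def test_severe_ppv_interval(self):
        lo, hi = proportion_wald_ci(14, 28)
        assert (round(lo, 1), round(hi, 1)) == (31.5, 68.5)

    def test_degenerate_zero(self):
        assert proportion_wald_ci(0, 10) == (0.0, 0.0)

    def test_upper_bound_may_exceed_100(self):
        lo, hi = proportion_wald_ci(120, 121)
        assert hi > 100.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            proportion_wald_ci(5, 3)


class TestPredictiveValues:
    @given(tp=st.integers(0, 40), fp=st.integers(0, 40),
           fn=st.integers(0, 40), tn=st.integers(0, 40))
    def test_count_conservation(self, tp, fp, fn, tn):
        pv = predictive_values_from_counts(tp, fp, fn, tn)
        total = 0.0
        if pv.ppv is not None:
            total += pv.ppv / 100 * (tp + fp)
        else:
            assert tp + fp == 0
        if pv.npv is not None:
            total += pv.npv / 100 * (tn + fn)
        else:
            assert tn + fn == 0
        assert total == pytest.approx(tp + tn)

    def test_no_positives_gives_null_ppv(self):
        pv = predictive_values_from_counts(0, 0, 3, 7)
        assert pv.ppv is None and pv.ppv_ci is None
        assert pv.npv == pytest.approx(70.0)

    def test_from_rows_matches_counts(self):
        rows = pd.DataFrame({
            "index_grade": ["severe"] * 4 + ["none"] * 6,
            "index_ploidy": ["aneuploid"] * 5 + ["diploid"] * 5,
            "event": [True, True, False, False, True, False, False, False,
                      False, False]})
        pv = predictive_values(rows, lambda t: t["index_grade"] == "severe")
        assert (pv.tp, pv.fp, pv.fn, pv.tn) == (2, 2, 1, 5)


class TestCombineTests:
    _rows = pd.DataFrame({
        "index_grade": ["none"] * 4 + ["severe"] * 4,
        "index_ploidy": ["diploid"] * 2 + ["aneuploid"] * 2
        + ["diploid"] * 2 + ["aneuploid"] * 2,
        "event": [False] * 4 + [False, True, True, True]})

    def test_and_combination(self):
        pv = combine_tests(self._rows, ("aneuploid",), "AND", ("severe",))
        assert (pv.tp, pv.fp) == (2, 0)

    def test_or_with_universal_grade_set_is_ploidy_only(self):
        every = tuple(self._rows["index_grade"].unique())
        pv_or = combine_tests(self._rows, ("aneuploid",), "OR", every)
        assert (pv_or.tp, pv_or.fp, pv_or.fn, pv_or.tn) == (3, 5, 0, 0)
        # absorption: OR with the universal set marks everyone positive
        pv_and = combine_tests(self._rows, ("aneuploid",), "AND", every)
        pv_only = predictive_values(
            self._rows, lambda t: t["index_ploidy"] == "aneuploid")
        assert (pv_and.tp, pv_and.fp) == (pv_only.tp, pv_only.fp)

    def test_negative_indicator_flips_table(self):
        pv = combine_tests(self._rows, ("diploid",), "AND", ("none",),
                           indicator="negative")
        assert pv.tn + pv.fn == 2  # the two diploid/none patients are negative

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            combine_tests(self._rows, (), "AND", ("severe",))


class TestChiSquare:
    def brute_force(self, table):
        table = np.asarray(table, float)
        rows = table.sum(1, keepdims=True)
        cols = table.sum(0, keepdims=True)
        expected = rows @ cols / table.sum()
        return float(((table - expected) ** 2 / expected).sum())

    def test_hand_example(self):
        stat, df, p = chi_square_association([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0) and df == 1

    def test_proportional_rows_give_zero(self):
        stat, _, p = chi_square_association([[10, 20, 30], [1, 2, 3]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    @given(st.lists(st.lists(st.integers(1, 30), min_size=3, max_size=3),
                    min_size=2, max_size=4))
    def test_matches_brute_force_oracle(self, table):
        stat, df, _ = chi_square_association(table)
        assert stat == pytest.approx(self.brute_force(table))
        assert df == (len(table) - 1) * 2


class TestSurvival:
    _fixture = pd.DataFrame({
        "time_years": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
        "event": [True, True, False, True, False, True, False, False],
    })

    def brute_force_km(self, times, events):
        order = np.argsort(times)
        times, events = np.asarray(times)[order], np.asarray(events)[order]
        surv = 1.0
        out = {}
        for t in np.unique(times[events]):
            n_at_risk = np.sum(times >= t)
            d = np.sum((times == t) & events)
            surv *= 1.0 - d / n_at_risk
            out[t] = surv
        return out

    def test_km_matches_product_limit_oracle(self):
        km = km_estimate(self._fixture)["all"]
        oracle = self.brute_force_km(self._fixture["time_years"],
                                     self._fixture["event"].to_numpy())
        for t, s in oracle.items():
            got = km.loc[km["time"] == t, "survival"].iloc[0]
            assert got == pytest.approx(s)

    def test_no_events_survival_is_one(self):
        rows = pd.DataFrame({"time_years": [1.0, 2.0, 3.0],
                             "event": [False] * 3})
        km = km_estimate(rows)["all"]
        assert np.allclose(km["survival"], 1.0)

    def test_logrank_detects_strong_separation(self):
        # two strata with hazard ratio 5: p < 0.001 in >= 95% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 250
            t1 = rng.exponential(1 / 0.05, n)
            t2 = rng.exponential(1 / 0.25, n)
            cens = rng.uniform(5, 9.6, 2 * n)
            times = np.concatenate([t1, t2])
            rows = pd.DataFrame({
                "time_years": np.minimum(times, cens),
                "event": times <= cens,
                "stratum": ["a"] * n + ["b"] * n})
            stat, df, p = logrank_test(rows, "stratum")
            assert df == 1
            hits += p < 0.001
        assert hits >= 95

    def test_logrank_df_counts_zero_event_strata(self):
        rows = pd.DataFrame({
            "time_years": [1, 2, 3, 4, 5, 6],
            "event": [True, True, False, False, False, False],
            "stratum": ["a", "a", "b", "b", "c", "c"]})
        _, df, _ = logrank_test(rows, "stratum")
        assert df == 2


class TestCox:
    def _frame(self, rng, n=800, hr=1.0):
        exposed = rng.random(n) < 0.5
        h = np.where(exposed, 0.04 * hr, 0.04)
        te = rng.exponential(1, n) / h
        tc = rng.uniform(5, 9.6, n)
        return pd.DataFrame({
            "index_grade": "none",
            "index_ploidy": np.where(exposed, "aneuploid", "diploid"),
            "age_at_index": rng.normal(55, 14, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "time_years": np.minimum(te, tc),
            "event": te <= tc})

    def test_recovers_positive_effect(self):
        rng = np.random.default_rng(0)
        est = cox_fit(self._frame(rng, n=2000, hr=3.0), "ploidy")
        (hr,) = [e.hr for e in est if e.term == "ploidy_aneuploid"]
        assert 2.3 < hr < 3.9

    def test_null_is_near_one(self):
        rng = np.random.default_rng(1)
        within = 0
        for _ in range(20):
            est = cox_fit(self._frame(rng, n=2000), "ploidy")
            (hr,) = [e.hr for e in est if e.term == "ploidy_aneuploid"]
            within += 0.8 < hr < 1.25
        assert within >= 18

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        frame = self._frame(rng, n=400, hr=2.0)
        frame["sex"] = "female"
        with pytest.warns(UserWarning, match="constant"):
            est = cox_fit(frame, "ploidy")
        assert all(e.term != "sex_male" for e in est)

    def test_no_events_raises(self):
        rng = np.random.default_rng(3)
        frame = self._frame(rng, n=50)
        frame["event"] = False
        with pytest.raises(ValueError, match="no events"):
            cox_fit(frame, "ploidy")


class TestCohenKappa:
    def test_identical_vectors(self):
        assert cohen_kappa(["dip", "an", "dip"], ["dip", "an", "dip"]) == 1.0

    def test_hand_computed_zero(self):
        # po = pe = 0.5 -> kappa exactly 0
        assert cohen_kappa(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["x", "y"], 5000)
        b = rng.choice(["x", "y"], 5000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["x", "y", "z"], 300)
        b = np.where(rng.random(300) < 0.7, a, rng.choice(["x", "y", "z"], 300))
        po = np.mean(a == b)
        pe = sum(np.mean(a == k) * np.mean(b == k) for k in "xyz")
        assert cohen_kappa(a, b) == pytest.approx((po - pe) / (1 - pe))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a", "b"])
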