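"""Kaplan-Meier, log-rank, and the maximally-selected cutpoint search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromasig.errors import ValidationError
from stromasig.survival import (
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    stratify,
    survival_report,
)


def brute_force_cutpoint(time, event, marker, minprop=0.1):
    """Oracle: exhaustive per-split scan calling logrank_test directly."""
    n = len(time)
    min_side = int(np.ceil(minprop * n))
    best = None
    for c in np.unique(marker):
        low = marker <= c
        if low.sum() < min_side or (~low).sum() < min_side:
            continue
        lr = logrank_test(time[~low], event[~low], time[low], event[low])
        stat = np.sqrt(lr.chi2)
        if best is None or stat > best[1] + 1e-9:
            best = (c, stat)
    return best


class TestKaplanMeier:
    def test_all_events_equals_empirical_survival(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.cumhaz, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1])

    def test_censoring_hand_product_limit(self):
        # times [1, 2+, 3]: S(1) = (1 - 1/3), S(3) = (1 - 1/3)(1 - 1/1) = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.event_times, [1, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert len(curve.event_times) == 0
        assert curve.survival_at(100.0) == 1.0
        assert np.isnan(curve.median)

    def test_censored_at_event_time_still_at_risk(self):
        # censoring tied with the event at t=2 counts in the risk set
        curve = km_estimate([2, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.at_risk, [3, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 40))
    def test_zero_censoring_matches_one_minus_ecdf(self, seed, n):
        rng = np.random.default_rng(seed)
        time = rng.exponential(10, size=n).round(1) + 0.1
        curve = km_estimate(time, np.ones(n, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            np.testing.assert_allclose(s, np.mean(time > t), atol=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        time = rng.exponential(10, size=50)
        event = rng.integers(0, 2, size=50)
        event[0] = 1
        curve = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for t, s in zip(curve.event_times, curve.survival):
            np.testing.assert_allclose(s, kmf.predict(t), atol=1e-10)


class TestLogrank:
    def test_identical_groups_are_null(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 0, 1, 1])
        res = logrank_test(t, e, t, e)
        assert res.chi2 == 0.0 and res.pvalue == 1.0

    def test_hand_oe_v_tabulation(self):
        # A: events at 1, 2; B: events at 3, 4. Step-by-step hypergeometric
        # tabulation gives U = 7/6, V = 17/36, chi2 = 49/17.
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        np.testing.assert_allclose(res.observed_minus_expected, 7 / 6, atol=1e-12)
        np.testing.assert_allclose(res.chi2, 49 / 17, atol=1e-12)

    def test_symmetric_in_group_order(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        np.testing.assert_allclose(r1.chi2, r2.chi2, atol=1e-12)
        np.testing.assert_allclose(r1.observed_minus_expected,
                                   -r2.observed_minus_expected, atol=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(5, 30), rng.exponential(10, 30)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        ea[0] = eb[0] = 1
        ours = logrank_test(ta, ea, tb, eb)
        theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        np.testing.assert_allclose(ours.chi2, theirs.test_statistic, atol=1e-8)
        np.testing.assert_allclose(ours.pvalue, theirs.p_value, atol=1e-8)


class TestMaxstat:
    def test_perfect_separation_scan_maximum_isolates_early_deaths(self):
        time = np.concatenate([np.arange(1, 11), np.arange(101, 111)]).astype(float)
        event = np.ones(20, dtype=int)
        marker = np.argsort(np.argsort(time)).astype(float)  # marker = time rank
        for stat in ("scores", "logrank"):
            cut = maxstat_cutpoint(time, event, marker, stat=stat)
            assert cut.p_selected < 1e-2
            # the reported cutpoint attains the scan maximum
            best = cut.scan.loc[cut.scan["statistic"].abs().idxmax(), "candidate"]
            assert cut.cutpoint == best
            # the induced split separates survival overwhelmingly
            low = marker <= cut.cutpoint
            lr = logrank_test(time[low], event[low], time[~low], event[~low])
            assert lr.pvalue < 1e-3

    def test_equals_brute_force_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 61))
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            marker = rng.normal(size=n)
            cut = maxstat_cutpoint(time, event, marker, stat="logrank")
            c, stat = brute_force_cutpoint(time, event, marker)
            np.testing.assert_allclose(cut.cutpoint, c, atol=1e-12)
            np.testing.assert_allclose(abs(cut.standardized_statistic), stat, atol=1e-9)

    def test_stat_modes_share_o_minus_e_numerator(self, rng):
        n = 40
        time = rng.exponential(10, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        marker = rng.normal(size=n)
        from stromasig.survival import _standardized_scan

        c1, z1, nl1 = _standardized_scan(time, event, marker, 0.1, stat="scores")
        c2, z2, nl2 = _standardized_scan(time, event, marker, 0.1, stat="logrank")
        np.testing.assert_allclose(c1, c2)
        # same sign everywhere: both standardize the same O-E numerator
        assert (np.sign(z1) == np.sign(z2)).all()

    def test_minprop_respected_and_error_when_unsatisfiable(self, rng):
        time = rng.exponential(10, 30)
        event = np.ones(30, dtype=int)
        marker = np.zeros(30)  # single marker value: no admissible split
        with pytest.raises(ValidationError, match="minprop"):
            maxstat_cutpoint(time, event, marker)
        cut = maxstat_cutpoint(time, event, rng.normal(size=30), minprop=0.2)
        assert min(cut.n_high, cut.n_low) >= 6

    def test_permutation_p_agrees_with_approximation_under_effect(self, rng):
        time = np.concatenate([rng.exponential(2, 30), rng.exponential(12, 30)])
        event = np.ones(60, dtype=int)
        marker = np.concatenate([np.zeros(30), np.ones(30)]) + rng.normal(0, 0.01, 60)
        approx = maxstat_cutpoint(time, event, marker, pmethod="lausen_approx")
        perm = maxstat_cutpoint(time, event, marker, pmethod="permutation",
                                n_perm=200, seed=5)
        assert approx.p_selected < 0.05 and perm.p_selected < 0.05
        assert approx.cutpoint == perm.cutpoint


class TestStratifyAndReport:
    def test_split_and_tie_rule(self):
        table = pd.DataFrame({
            "time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
            "marker": [1.0, 2.0, 3.0, 4.0],
        })
        cut = maxstat_cutpoint(table["time"].to_numpy(), table["event"].to_numpy(),
                               table["marker"].to_numpy(), minprop=0.25)
        out = stratify(table, cut)
        assert (out.loc[out["marker"] <= cut.cutpoint, "group"] == "low").all()
        assert (out.loc[out["marker"] > cut.cutpoint, "group"] == "high").all()
        # a marker exactly at the cutpoint goes low (strict > for high)
        assert out.loc[out["marker"] == cut.cutpoint, "group"].eq("low").all()

    def test_stratify_recovers_planted_blocks(self):
        time = np.concatenate([np.arange(1, 11), np.arange(101, 111)]).astype(float)
        event = np.ones(20, dtype=int)
        marker = -np.argsort(np.argsort(time)).astype(float)  # high marker = early death
        table = pd.DataFrame({"time": time, "event": event, "marker": marker})
        cut = maxstat_cutpoint(time, event, marker)
        out = stratify(table, cut)
        # the high-marker group carries the early deaths
        report = survival_report(out)
        assert report.direction == "high_worse"
        assert report.pvalue < 1e-3
        assert {cut.n_high, cut.n_low} == {
            int((out["group"] == "high").sum()), int((out["group"] == "low").sum())
        }

    def test_direction_high_worse_under_double_hazard(self, rng):
        n = 300
        marker = rng.normal(size=n)
        hazard = np.where(marker > 0, 2.0, 1.0)
        time = rng.exponential(1.0 / hazard)
        table = pd.DataFrame({
            "time": time, "event": np.ones(n, dtype=int),
            "marker": marker,
            "group": np.where(marker > 0, "high", "low"),
        })
        report = survival_report(table)
        assert report.direction == "high_worse"
        assert report.pvalue < 0.05
        assert report.median["high"] < report.median["low"]

    def test_identical_groups_no_direction(self):
        half = pd.DataFrame({"time": [1.0, 2, 3], "event": [1, 1, 1]})
        table = pd.concat([half.assign(group="high"), half.assign(group="low")])
        report = survival_report(table)
        assert report.pvalue == 1.0 and report.direction == "none"

    def test_median_missing_when_curve_stays_high(self):
        table = pd.DataFrame({
            "time": [1.0, 2, 3, 4, 5, 6, 7, 8],
            "event": [1, 0, 0, 0, 1, 1, 1, 1],
            "group": ["high"] * 4 + ["low"] * 4,
        })
        report = survival_report(table)
        assert np.isnan(report.median["high"])  # S stays at 3/4 > 1/2
        assert report.to_dict()["median"]["high"] is None
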