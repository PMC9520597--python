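"""Survival primitives against hand computations and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chemosig import (UndefinedTestError, ValidationError, chi2_contingency_cc,
                      horizon_table, km_estimate, logrank_test, table1_report)
from chemosig.survival import logrank_screen, round_half_up, significance_stars

# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([3.0, 7.0, 9.0], [False, False, False])
        assert km.event_times.size == 0
        assert np.all(km.survival_at([0, 5, 100]) == 1.0)

    def test_no_censoring_reduces_to_empirical_survivor(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # times (5, 8, 12, 20), events (1, 0, 1, 1):
        # S = 3/4 after t=5, 3/4 * (1 - 1/2) after t=12, 0 after t=20
        km = km_estimate([5, 8, 12, 20], [1, 0, 1, 1])
        np.testing.assert_allclose(km.event_times, [5, 12, 20])
        np.testing.assert_allclose(km.survival, [0.75, 0.375, 0.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])

    @given(st.lists(st.tuples(st.floats(0.1, 100), st.booleans()),
                    min_size=2, max_size=30))
    def test_curve_is_monotone_and_matches_empirical_when_uncensored(self, data):
        time = np.array([t for t, _ in data])
        event = np.array([e for _, e in data])
        if event.any():
            km = km_estimate(time, event)
            assert np.all(np.diff(km.survival) <= 1e-12)
            assert np.all((km.survival >= 0) & (km.survival <= 1))
        km_all = km_estimate(time, np.ones_like(event))
        # with every sample an event, S(t) is the empirical survivor function
        grid = np.unique(time)
        expected = [(time > t).mean() for t in grid]
        np.testing.assert_allclose(km_all.survival_at(grid), expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_product_limit(self, seed):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(seed)
        time = rng.exponential(100, size=40)
        event = rng.random(40) < 0.7
        if not event.any():
            pytest.skip("no events drawn")
        km = km_estimate(time, event)
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        ours = km.survival_at(km.event_times)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def _permutation_logrank_p(time, event, n_a):
    """Exact permutation p-value over all assignments of n_a samples to A."""
    time, event = np.asarray(time, float), np.asarray(event, bool)
    idx = range(time.size)
    observed = logrank_test(time[:n_a], event[:n_a], time[n_a:], event[n_a:])
    stats = []
    for combo in itertools.combinations(idx, n_a):
        a = np.zeros(time.size, dtype=bool)
        a[list(combo)] = True
        r = logrank_test(time[a], event[a], time[~a], event[~a])
        stats.append(r.statistic)
    stats = np.array(stats)
    return (stats >= observed.statistic - 1e-12).mean(), observed


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t, e = [3, 6, 9, 12], [1, 0, 1, 1]
        r = logrank_test(t, e, t, e)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        ta, ea = [2, 4, 9], [1, 1, 0]
        tb, eb = [10, 12, 14], [1, 0, 1]
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.direction == -r2.direction

    def test_matches_exact_permutation_on_separated_groups(self):
        # fully separated 3-vs-3: the exact permutation law over all 20 label
        # assignments puts mass 2/20 on the extreme statistic (the observed
        # split and its mirror), so p_perm = 0.10 exactly; the asymptotic
        # chi-square p can agree only up to that discreteness atom
        p_perm, observed = _permutation_logrank_p(
            [2, 4, 6, 10, 12, 14], [1, 1, 1, 1, 1, 1], 3)
        assert p_perm == pytest.approx(0.10)
        assert abs(observed.p_value - p_perm) < 0.1
        assert observed.direction > 0  # early deaths in group A

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_permutation_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        time = rng.exponential(50, size=n).round(1)
        event = rng.random(n) < 0.8
        if not event.any():
            event[0] = True
        n_a = int(rng.integers(2, n - 1))
        p_perm, observed = _permutation_logrank_p(time, event, n_a)
        # chi-square approximation vs the exact permutation law at tiny n
        assert abs(observed.p_value - p_perm) < 0.25

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_lifelines_statistic(self, seed):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(seed)
        ta, tb = rng.exponential(80, 30), rng.exponential(160, 35)
        ea, eb = rng.random(30) < 0.7, rng.random(35) < 0.7
        ours = logrank_test(ta, ea, tb, eb)
        theirs = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_zero_events_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_vectorized_screen_agrees_with_scalar_path(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(100, 50)
        event = rng.random(50) < 0.7
        groups = rng.random((8, 50)) < 0.5
        stat, p, oe = logrank_screen(time, event, groups)
        for i in range(8):
            g = groups[i]
            r = logrank_test(time[g], event[g], time[~g], event[~g])
            assert stat[i] == pytest.approx(r.statistic, rel=1e-9)
            assert oe[i] == pytest.approx(r.o_minus_e, rel=1e-9)


# ---------------------------------------------------------------------------
# Horizon tables
# ---------------------------------------------------------------------------


def _clinical(times, events, group):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(times))],
        "time_days": times, "event": events, "treatment": group,
        "cancer_type": "STAD", "subtype": "diffuse"})


class TestHorizonTable:
    def test_reproduces_printed_one_year_rate(self):
        # 82 treated samples, 11 deaths within the horizon -> 86.59% survival
        times = [100.0] * 11 + [400.0] * 71 + [50.0] * 10
        events = [True] * 11 + [False] * 71 + [True] * 10
        groups = ["5-FU"] * 82 + ["none"] * 10
        ht = horizon_table(pd.concat([_clinical(times[:82], events[:82], "5-FU"),
                                      _clinical(times[82:], events[82:], "none")]),
                           ("5-FU", "none"), horizon=365)
        assert ht.deaths["5-FU"] == 11 and ht.alive["5-FU"] == 71
        assert ht.survival_pct["5-FU"] == 86.59

    def test_everyone_dead_before_horizon(self):
        clin = pd.concat([_clinical([10, 20, 30], [1, 1, 1], "5-FU"),
                          _clinical([500], [0], "none")])
        ht = horizon_table(clin, ("5-FU", "none"), horizon=365)
        assert (ht.deaths["5-FU"], ht.alive["5-FU"]) == (3, 0)
        assert ht.survival_pct["5-FU"] == 0.0

    def test_censored_before_horizon_counts_alive(self):
        # 3 deaths <= horizon, 4 censored <= horizon, 3 followed past it
        times = [100, 200, 300, 50, 60, 70, 80, 400, 500, 600]
        events = [1, 1, 1, 0, 0, 0, 0, 0, 1, 0]
        clin = pd.concat([_clinical(times, events, "5-FU"),
                          _clinical([400], [1], "none")])
        ht = horizon_table(clin, ("5-FU", "none"), horizon=365)
        assert (ht.deaths["5-FU"], ht.alive["5-FU"]) == (3, 7)

    def test_group_totals_constant_across_horizons(self, clinical_two_arm):
        totals = set()
        for h in (365, 1095, 1825):
            ht = horizon_table(clinical_two_arm, ("5-FU", "none"), h)
            totals.add(tuple(ht.deaths[g] + ht.alive[g] for g in ht.groups))
        assert len(totals) == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            horizon_table(_clinical([1], [1], "5-FU"), ("5-FU", "none"), 365)


# ---------------------------------------------------------------------------
# Continuity-corrected chi-square
# ---------------------------------------------------------------------------


class TestChi2ContinuityCorrected:
    @pytest.mark.parametrize("table, printed", [
        (((11, 71), (122, 131)), 29.90),
        (((1, 12), (16, 14)), 6.11),
        (((12, 1), (28, 2)), 0.00),  # |O-E| < 0.5 everywhere -> floored to 0
    ])
    def test_published_horizon_cells(self, table, printed):
        stat, _ = chi2_contingency_cc(table)
        assert round_half_up(stat, 2) == printed

    @given(st.tuples(st.integers(0, 60), st.integers(0, 60),
                     st.integers(0, 60), st.integers(0, 60)))
    def test_transpose_and_row_column_swap_invariance(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]])
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            with pytest.raises(UndefinedTestError):
                chi2_contingency_cc(t)
            return
        base = chi2_contingency_cc(t)[0]
        assert chi2_contingency_cc(t.T)[0] == pytest.approx(base, abs=1e-10)
        assert chi2_contingency_cc(t[::-1, ::-1])[0] == pytest.approx(base, abs=1e-10)

    def test_matches_scipy_when_deviation_above_half(self):
        from scipy.stats import chi2_contingency
        t = np.array([[30, 10], [12, 28]])
        ours, p_ours = chi2_contingency_cc(t)
        res = chi2_contingency(t, correction=True)
        assert ours == pytest.approx(res.statistic, rel=1e-12)
        assert p_ours == pytest.approx(res.pvalue, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedTestError):
            chi2_contingency_cc([[0, 0], [5, 6]])


class TestTable1Report:
    def test_report_shape_and_stars(self, clinical_two_arm):
        report = table1_report(clinical_two_arm, groups=("5-FU", "none"))
        # one stratum block per subtype plus "all", two group rows per horizon
        assert set(report["group"]) == {"5-FU", "none"}
        assert set(report["horizon_days"]) == {365, 1095, 1825}
        assert "all" in set(report["stratum"])
        all_rows = report[report["stratum"] == "all"]
        assert (all_rows.groupby("group")["total"].nunique() == 1).all()
        assert set(report["stars"]) <= {"ns", "*", "**", "***", "NA"}

    def test_star_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == "ns"
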