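"""Survival and testing primitives against independent brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rdgenomics.stats import (
    DegreesOfFreedomError,
    bh_fdr,
    fisher_overlap,
    hazard_ratio,
    kaplan_meier,
    logrank_test,
    one_way_anova,
    t_test,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def km_oracle(times, events, t):
    """Product over distinct event times u <= t of (1 - d_u / n_u)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        n_u = np.sum(times >= u)
        d_u = np.sum((times == u) & events)
        s *= 1.0 - d_u / n_u
    return s


def logrank_oracle(times, events, groups):
    """Two-group O-E over shared event times with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    o_minus_e, var = 0.0, 0.0
    for u in sorted(set(times[events])):
        at_risk = times >= u
        n, n1 = at_risk.sum(), (at_risk & (groups == 1)).sum()
        d = ((times == u) & events).sum()
        d1 = ((times == u) & events & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric
    support at fixed margins."""
    from math import comb
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def bh_oracle(pvals):
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def anova_oracle(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_is_flat(self):
        curve = kaplan_meier([5, 8, 12], [False, False, False])
        assert np.all(curve.survival == 1.0)

    def test_hand_computed_steps(self):
        curve = kaplan_meier([1, 2, 3], [True, True, True])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2) == pytest.approx(1 / 3)
        assert curve.at(3) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(1, 11)
            times = np.round(rng.exponential(10, n), 1)
            events = rng.random(n) < 0.7
            curve = kaplan_meier(times, events)
            for t in np.unique(times):
                assert curve.at(t) == pytest.approx(
                    km_oracle(times, events, t), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0], [True])

    @given(
        times=st.lists(st.floats(0, 100), min_size=1, max_size=30),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=100, deadline=None)
    def test_curve_bounds_and_monotonicity(self, times, seed):
        events = np.random.default_rng(seed).random(len(times)) < 0.5
        curve = kaplan_meier(times, events)
        assert curve.survival[0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= -1e-12) & (curve.survival <= 1 + 1e-12))


class TestLogRank:
    def test_identical_groups_null(self):
        times = [2, 4, 6, 8]
        events = [True, True, False, True]
        res = logrank_test(times + times, events + events, [0] * 4 + [1] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(DegreesOfFreedomError):
            logrank_test([1, 2], [True, True], [0, 0])

    def test_matches_hand_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True, True, True, True, False, True])
        groups = np.array([0, 0, 1, 1, 0, 1])
        res = logrank_test(times, events, groups)
        assert res.df == 1
        assert res.statistic == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-8)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(20):
            n = rng.integers(4, 11)
            times = np.round(rng.exponential(10, n), 0) + 1
            events = rng.random(n) < 0.8
            groups = rng.integers(0, 2, n)
            if events[groups == 0].sum() == 0 or events[groups == 1].sum() == 0:
                continue
            res = logrank_test(times, events, groups)
            assert res.statistic == pytest.approx(
                logrank_oracle(times, events, groups), abs=1e-8)


class TestHazardRatio:
    def test_identical_groups_give_unit_hr(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=bool)
        res = hazard_ratio(np.r_[t, t], np.r_[e, e], [0] * 40 + [1] * 40)
        assert res.hr == pytest.approx(1.0, abs=0.05)

    def test_exponential_rate_ratio_recovery(self):
        rng = np.random.default_rng(12)
        t0 = rng.exponential(10.0, 500)
        t1 = rng.exponential(5.0, 500)
        res = hazard_ratio(np.r_[t0, t1], np.ones(1000, dtype=bool),
                           [0] * 500 + [1] * 500)
        assert 1.8 <= res.hr <= 2.2
        assert res.ci_lower <= res.hr <= res.ci_upper

    def test_no_events_non_identifiable(self):
        with pytest.warns(RuntimeWarning):
            res = hazard_ratio([5, 6, 7, 8], [True, True, False, False],
                               [0, 0, 1, 1])
        assert res.non_identifiable
        assert res.ci_upper == np.inf

    def test_covariate_adjustment_returns_effects(self):
        import pandas as pd
        rng = np.random.default_rng(9)
        n = 200
        x = rng.integers(0, 2, n)
        age = rng.normal(50, 10, n)
        t = rng.exponential(10 / np.exp(0.7 * x), n)
        res = hazard_ratio(t, np.ones(n, dtype=bool), x,
                           covariates=pd.DataFrame({"age": age}))
        assert "age" in res.covariate_effects
        assert 1.4 <= res.hr <= 2.9


class TestTTest:
    def test_paired_zero_differences(self):
        assert t_test([1, 2, 3], [1, 2, 3], paired=True) == (0.0, 1.0)

    def test_equal_unpaired_vectors(self):
        stat, p = t_test([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form(self):
        x = np.array([3.1, 2.8, 3.5, 3.0])
        y = np.array([2.2, 2.6, 2.1])
        n1, n2 = len(x), len(y)
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) \
            / (n1 + n2 - 2)
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        stat, p = t_test(x, y)
        assert stat == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(
            2 * sps.t.sf(abs(expected), n1 + n2 - 2), abs=1e-10)

    def test_null_p_values_uniform(self):
        """Two-sided p under the normal null passes a KS uniformity check."""
        rng = np.random.default_rng(77)
        ps = [t_test(rng.normal(size=10), rng.normal(size=10))[1]
              for _ in range(2000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestAnova:
    def test_equal_groups_f_zero(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_identical_values_convention(self):
        assert one_way_anova([[2.0, 2.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_two_groups_equals_squared_t(self):
        x, y = [3.1, 2.8, 3.5, 3.0], [2.2, 2.6, 2.1]
        f, p_f = one_way_anova([x, y])
        t, p_t = t_test(x, y)
        assert f == pytest.approx(t ** 2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_three_groups_vs_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0, 1.5], [2.5, 3.1, 2.9, 3.4], [0.5, 1.1]]
        f, p = one_way_anova(groups)
        f_o, p_o = anova_oracle(groups)
        assert f == pytest.approx(f_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_dominates_input_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)

    def test_idempotent_on_adjusted_input(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_fdr(q), q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFisher:
    def test_balanced_table(self):
        assert fisher_overlap(1, 2, 1, 2) == (1.0, 1.0)

    def test_extreme_table_vs_enumeration(self):
        _, p = fisher_overlap(10, 10, 0, 10)
        assert p == pytest.approx(fisher_oracle(10, 0, 0, 10), abs=1e-12)

    def test_random_tables_vs_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = fisher_overlap(a, a + b, c, c + d)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_transposition_invariance(self):
        _, p1 = fisher_overlap(7, 12, 3, 15)
        _, p2 = fisher_overlap(7, 10, 5, 17)  # transposed table
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(-1, 5, 2, 10)
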