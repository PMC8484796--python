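import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6ascape.stats import (
    bh_adjust,
    correlate,
    cox_fit,
    fisher_exact,
    km_estimate,
    logrank_test,
    rank_sum_test,
    roc_auc,
)
from m6ascape.synthetic import simulate_survival


def newton_cox_oracle(time, event, x, tol=1e-12):
    """One-covariate Cox partial-likelihood Newton solver (no ties assumed)."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    beta = 0.0
    for _ in range(100):
        u = 0.0
        info = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            w = np.exp(beta * x[risk])
            s0, s1, s2 = w.sum(), (w * x[risk]).sum(), (w * x[risk] ** 2).sum()
            u += x[i] - s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
        step = u / info
        beta += step
        if abs(step) < tol:
            break
    return beta


class TestCoxFit:
    def test_identical_groups_zero_beta(self, rng):
        t = rng.exponential(100, 40)
        T, E = np.concatenate([t, t]), np.ones(80, dtype=int)
        g = np.repeat([0.0, 1.0], 40)
        fit = cox_fit(T, E, pd.DataFrame({"g": g}))
        assert abs(fit.summary.loc["g", "beta"]) < 1e-8
        assert fit.summary.loc["g", "hr"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_partial_likelihood_newton_oracle(self, rng):
        t = rng.exponential(50, 120)
        e = (rng.random(120) < 0.8).astype(int)
        x = rng.normal(size=120)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        # no ties: Efron == Breslow == the plain partial likelihood
        assert fit.summary.loc["x", "beta"] == pytest.approx(
            newton_cox_oracle(t, e, x), abs=1e-6)

    def test_breslow_library_agrees_without_ties(self, rng):
        sksurv = pytest.importorskip("sksurv.linear_model")
        t = rng.exponential(50, 150)
        e = (rng.random(150) < 0.7).astype(int)
        x = rng.normal(size=150)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("event", bool), ("time", float)])
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
        ref.fit(x[:, None], y)
        assert fit.summary.loc["x", "beta"] == pytest.approx(ref.coef_[0], abs=1e-6)

    def test_recovers_planted_hr2(self):
        lp = np.concatenate([np.zeros(1000), np.full(1000, np.log(2))])
        t, e = simulate_survival(lp, 0.01, 0.2, seed=42)
        fit = cox_fit(t, e, pd.DataFrame({"g": (lp > 0).astype(float)}))
        assert 0.55 <= fit.summary.loc["g", "beta"] <= 0.85

    def test_wald_ci_consistency(self, rng):
        t = rng.exponential(50, 100)
        e = np.ones(100, dtype=int)
        x = rng.normal(size=100)
        s = cox_fit(t, e, pd.DataFrame({"x": x})).summary.loc["x"]
        assert s["ci_low"] <= s["hr"] <= s["ci_high"]
        assert s["ci_low"] == pytest.approx(
            math.exp(s["beta"] - 1.959963984540054 * s["se"]), rel=1e-9)

    def test_constant_covariate_rejected(self, rng):
        t = rng.exponential(50, 20)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(t, np.ones(20, int), pd.DataFrame({"x": np.ones(20)}))

    def test_no_events_rejected(self, rng):
        t = rng.exponential(50, 20)
        with pytest.raises(ValueError, match="event"):
            cox_fit(t, np.zeros(20, int), pd.DataFrame({"x": rng.normal(size=20)}))

    def test_logrank_and_cox_chisquare_agree_asymptotically(self):
        lp = np.concatenate([np.zeros(1000), np.full(1000, 0.2)])
        t, e = simulate_survival(lp, 0.01, 0.2, seed=5)
        grp = (lp > 0).astype(int)
        lr = logrank_test(t, e, grp)
        s = cox_fit(t, e, pd.DataFrame({"g": grp.astype(float)})).summary.loc["g"]
        wald = (s["beta"] / s["se"]) ** 2
        assert abs(lr.statistic - wald) / lr.statistic < 0.05


class TestKmLogrank:
    def test_product_limit_arithmetic(self):
        km = km_estimate(np.array([1.0, 2.0]), np.array([1, 1]))
        s = dict(zip(km.times, km.survival))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_survival_non_increasing_from_one(self, rng):
        t = rng.exponential(30, 100)
        e = (rng.random(100) < 0.6).astype(int)
        km = km_estimate(t, e)
        assert km.survival[0] <= 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_identical_groups_null(self, rng):
        t = rng.exponential(30, 30)
        T, E = np.concatenate([t, t]), np.ones(60, int)
        res = logrank_test(T, E, np.repeat([0, 1], 30))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_single_group_rejected(self, rng):
        t = rng.exponential(30, 10)
        with pytest.raises(ValueError):
            logrank_test(t, np.ones(10, int), np.zeros(10))


class TestRankSum:
    def test_exact_enumeration_small(self):
        res = rank_sum_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert res.p == pytest.approx(1 / 3, rel=1e-9)
        assert res.effect["exact"]

    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rank_sum_test(x, x).p == pytest.approx(1.0)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(11)
        hits = sum(
            rank_sum_test(rng.normal(0, 1, 50), rng.normal(1, 1, 50)).p < 0.01
            for _ in range(100))
        assert hits >= 95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test(np.array([]), np.array([1.0]))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration at fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        assert fisher_exact(np.array([[2, 0], [0, 2]])).p == pytest.approx(1 / 3)

    def test_balanced_table(self):
        res = fisher_exact(np.array([[5, 5], [5, 5]]))
        assert res.effect["odds_ratio"] == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_extreme_diagonal(self):
        assert fisher_exact(np.array([[10, 0], [0, 10]])).p < 1e-4

    def test_matches_enumeration_for_all_small_margins(self):
        """Exhaustive agreement with the enumeration oracle, totals <= 12."""
        for n in range(1, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                got = fisher_exact(np.array([[a, b], [c, d]])).p
                want = fisher_enumeration_oracle(a, b, c, d)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (a, b, c, d)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[1, -1], [0, 2]]))


def bh_stepup_oracle(p):
    """Textbook step-up arithmetic: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhAdjust:
    def test_stepup_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_sorted_input_gives_monotone_q(self, rng):
        p = np.sort(rng.random(50))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_stepup_oracle(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p),
                                   rtol=1e-9, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30),
           st.integers(min_value=0, max_value=29))
    def test_shrinking_a_p_never_loses_discoveries(self, p, idx):
        p = np.asarray(p)
        idx = idx % len(p)
        before = (bh_adjust(p) <= 0.05).sum()
        p2 = p.copy()
        p2[idx] = p2[idx] / 2.0
        after = (bh_adjust(p2) <= 0.05).sum()
        assert after >= before

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestCorrelate:
    def test_self_correlation(self, rng):
        x = rng.normal(size=20)
        t = correlate(x, pd.DataFrame({"x": x, "neg": -x}))
        assert t.set_index("name").loc["x", "r"] == pytest.approx(1.0)
        assert t.set_index("name").loc["neg", "r"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            r = correlate(x, pd.DataFrame({"y": y}))["r"].iloc[0]
            hits += abs(r) < 0.1
        assert hits >= 198

    def test_constant_column_skipped(self, rng, caplog):
        x = rng.normal(size=10)
        with caplog.at_level("WARNING"):
            t = correlate(x, pd.DataFrame({"c": np.ones(10), "x": x}))
        assert list(t["name"]) == ["x"]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.array([1.0, 2.0]), pd.DataFrame({"y": [1.0, 2.0]}))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(1.0)

    def test_pairwise_enumeration_value(self):
        auc, _ = roc_auc(np.array([3.0, 2.0, 1.0]), np.array([1, 0, 1]))
        assert auc == pytest.approx(0.5)

    def test_complement_symmetry(self, rng):
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(int)
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(-s, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            s = rng.normal(size=1000)
            y = (rng.random(1000) < 0.5).astype(int)
            auc, _ = roc_auc(s, y)
            hits += 0.45 <= auc <= 0.55
        assert hits >= 95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))
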