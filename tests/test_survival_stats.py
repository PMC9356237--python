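import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clical.errors import DomainError
from clical.survival_stats import (kaplan_meier, km_confidence_interval,
                                   log_rank, median_time, nelson_aalen,
                                   restricted_mean)

from conftest import outcomes


def logrank_oracle(groups):
    """Independent k-group O/E/V log-rank, written as an explicit loop over
    event times from the textbook definition (used only as a test oracle)."""
    data = [(t, e, g) for g, grp in enumerate(groups) for t, e in grp]
    k = len(groups)
    event_times = sorted({t for t, e, _ in data if e})
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        n_g = np.array([sum(1 for t, _, g in data if t >= et and g == gi)
                        for gi in range(k)], float)
        d_g = np.array([sum(1 for t, e, g in data
                            if t == et and e and g == gi)
                        for gi in range(k)], float)
        n, d = n_g.sum(), d_g.sum()
        O += d_g
        E += d * n_g / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            p = n_g / n
            V += c * (np.diag(p) - np.outer(p, p))
    u = (O - E)[:-1]
    chi2 = float(u @ np.linalg.pinv(V[:-1, :-1]) @ u)
    return chi2, O, E


class TestKaplanMeier:
    def test_hand_product_limit_three_subjects(self):
        curve = kaplan_meier(outcomes([(1, 1), (2, 1), (3, 0)]))
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(2.9) == pytest.approx(1 / 3)

    def test_hand_product_limit_with_tied_events_and_censoring(self):
        # events at 1,1,2; censored at 2+ and 3+: S(1)=3/5, S(2)=3/5*2/3=2/5
        curve = kaplan_meier(outcomes([(1, 1), (1, 1), (2, 1), (2, 0), (3, 0)]))
        assert curve.survival_at(1) == pytest.approx(3 / 5)
        assert curve.survival_at(2) == pytest.approx(2 / 5)
        # censored tied with the event counted at risk at that time
        assert curve.n_at_risk.tolist() == [5, 3]

    def test_all_censored_is_flat_one_with_no_median(self):
        curve = kaplan_meier(outcomes([(5, 0), (8, 0)]))
        assert curve.survival_at(100) == 1.0
        assert median_time(curve) is None

    def test_no_censoring_equals_empirical_survival(self):
        times = [3, 1, 4, 1, 5, 9, 2, 6]
        curve = kaplan_meier(outcomes([(t, 1) for t in times]))
        n = len(times)
        for t in range(0, 10):
            empirical = sum(1 for x in times if x > t) / n
            assert curve.survival_at(t) == pytest.approx(empirical)

    def test_median_at_exact_half(self):
        curve = kaplan_meier(outcomes([(5, 1), (9, 1)]))
        assert median_time(curve) == 5.0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.7
        t = np.round(np.where(e, t, t * 0.8), 2)
        curve = kaplan_meier(list(zip(t, e)))
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ours = [curve.survival_at(x) for x in curve.event_times]
        theirs = [float(kmf.predict(x)) for x in curve.event_times]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            kaplan_meier([])

    def test_confidence_interval_brackets_estimate(self, rng):
        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.8
        curve = kaplan_meier(list(zip(t, e)))
        lo, hi = km_confidence_interval(curve)
        assert np.all(lo <= curve.survival + 1e-12)
        assert np.all(curve.survival <= hi + 1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.floats(0, 1e3), st.booleans()),
                    min_size=1, max_size=60))
    def test_curve_invariants(self, data):
        curve = kaplan_meier(outcomes(data))
        s = curve.survival
        assert np.all((0 <= s) & (s <= 1.0 + 1e-12))
        assert np.all(np.diff(s) <= 1e-12)          # non-increasing survival
        assert np.all(np.diff(curve.n_at_risk) <= 0)  # shrinking risk set


class TestNelsonAalen:
    def test_hand_computation(self):
        # events at 1 and 3; censored at 3+ and 5+: H(1)=1/4, H(3)=1/4+1/3
        curve = nelson_aalen(outcomes([(1, 1), (3, 1), (3, 0), (5, 0)]))
        assert curve.hazard_at(1) == pytest.approx(1 / 4)
        assert curve.hazard_at(3) == pytest.approx(1 / 4 + 1 / 3)

    def test_single_subject_event(self):
        assert nelson_aalen(outcomes([(2, 1)])).hazard_at(2) == 1.0

    def test_all_censored_is_zero(self):
        curve = nelson_aalen(outcomes([(1, 0), (2, 0)]))
        assert curve.hazard_at(10) == 0.0

    def test_exp_minus_h_tracks_km_at_large_n(self, rng):
        t = rng.exponential(12, 2000)
        c = rng.uniform(5, 40, 2000)
        obs = np.minimum(t, c)
        e = t <= c
        km = kaplan_meier(list(zip(obs, e)))
        na = nelson_aalen(list(zip(obs, e)))
        s_na = np.exp(-na.cumulative_hazard)
        assert np.max(np.abs(s_na - km.survival)) < 0.02


class TestLogRank:
    def test_identical_groups_give_null(self):
        g = outcomes([(1, 1), (2, 1), (5, 0)])
        res = log_rank([g, list(g)])
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.999

    def test_matches_independent_oracle_two_groups(self):
        a = [(1, 1), (2, 1), (3, 1)]
        b = [(4, 1), (5, 1), (6, 1)]
        res = log_rank([outcomes(a), outcomes(b)])
        chi2, O, E = logrank_oracle([a, b])
        assert res.chi_square == pytest.approx(chi2, abs=1e-10)
        assert np.allclose(res.observed, O)
        assert np.allclose(res.expected, E)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_independent_oracle_random(self, k, rng):
        groups = []
        for g in range(k):
            t = np.round(rng.exponential(8 + 3 * g, 40), 1)
            e = rng.random(40) < 0.8
            groups.append(list(zip(t, e)))
        res = log_rank([outcomes(g) for g in groups])
        chi2, O, E = logrank_oracle(groups)
        assert res.chi_square == pytest.approx(chi2, abs=1e-10)
        assert sum(np.asarray(res.observed) - np.asarray(res.expected)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_lifelines_three_groups(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        t = np.concatenate([rng.exponential(m, 50) for m in (5, 8, 14)])
        e = rng.random(150) < 0.85
        lab = np.repeat([0, 1, 2], 50)
        res = log_rank([outcomes(list(zip(t[lab == g], e[lab == g])))
                        for g in range(3)])
        ll = stats_mod.multivariate_logrank_test(t, lab, e)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_invariant_to_patient_order_and_monotone_time_transform(self, rng):
        a = [(t, e) for t, e in zip(rng.exponential(5, 30),
                                    rng.random(30) < 0.8)]
        b = [(t, e) for t, e in zip(rng.exponential(9, 30),
                                    rng.random(30) < 0.8)]
        base = log_rank([outcomes(a), outcomes(b)])
        shuffled = log_rank([outcomes(a[::-1]), outcomes(b[::-1])])
        assert shuffled.chi_square == pytest.approx(base.chi_square, abs=1e-12)
        # rank statistic: invariant under strictly increasing transform
        warp = log_rank([outcomes([(t ** 2 + 1, e) for t, e in a]),
                         outcomes([(t ** 2 + 1, e) for t, e in b])])
        assert warp.chi_square == pytest.approx(base.chi_square, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            log_rank([outcomes([(1, 1)])])
        with pytest.raises(DomainError):
            log_rank([outcomes([(1, 0)]), outcomes([(2, 0)])])


def test_restricted_mean_simple():
    # S = 1 on [0,1), 0.5 on [1,2): area to tau=2 is 1.5
    curve = kaplan_meier(outcomes([(1, 1), (2, 0)]))
    assert restricted_mean(curve, tau=2.0) == pytest.approx(1.5)
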