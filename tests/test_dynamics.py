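import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarekit.dynamics import (BoutEvent, coflaring_filter,
                               cohort_correlation_test,
                               flare_feature_correlation, normalize_elevation,
                               persistence, persistence_cohort, peth,
                               select_bouts, shuffle_control)


class TestCoflaringFilter:
    def test_both_always_flaring(self):
        mask = coflaring_filter(np.ones(10), np.ones(10))
        assert mask.all()

    def test_neither_flares_empty_mask_zero_rule(self):
        a = np.zeros(10)
        mask = coflaring_filter(a, a)
        assert not mask.any()
        res = flare_feature_correlation(a, np.arange(10.0), mask)
        assert res.r == 0.0 and res.zero_assigned

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mask_equals_bitwise_or(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random(60) < 0.3).astype(int)
        b = (rng.random(60) < 0.3).astype(int)
        mask = coflaring_filter(a, b)
        expected = sum(int(x or y) for x, y in zip(a, b))
        assert mask.sum() == expected


def closed_form_point_biserial(y, x):
    """r_pb = (mu1 - mu0) / s_n * sqrt(p * q), population sd."""
    y = np.asarray(y, bool)
    mu1, mu0 = x[y].mean(), x[~y].mean()
    p = y.mean()
    return (mu1 - mu0) / x.std() * np.sqrt(p * (1 - p))


class TestFlareFeatureCorrelation:
    def test_feature_equals_indicator(self):
        rng = np.random.default_rng(0)
        flare = (rng.random(100) < 0.4).astype(int)
        res = flare_feature_correlation(flare, flare.astype(float))
        assert res.r == pytest.approx(1.0)

    def test_never_flares_assigned_zero(self):
        res = flare_feature_correlation(np.zeros(50),
                                        np.random.default_rng(1).random(50))
        assert res.r == 0.0 and res.zero_assigned

    def test_matches_closed_form(self):
        rng = np.random.default_rng(2)
        flare = (rng.random(200) < 0.5).astype(int)
        feat = rng.normal(0, 1, 200) + 0.5 * flare
        res = flare_feature_correlation(flare, feat)
        assert res.r == pytest.approx(closed_form_point_biserial(flare, feat))

    def test_zero_variance_feature_not_applicable(self):
        flare = np.array([0, 1, 0, 1])
        res = flare_feature_correlation(flare, np.full(4, 3.0))
        assert np.isnan(res.r)


class TestShuffleControl:
    def test_n2_gives_plus_minus_observed(self):
        flare = np.array([0, 1])
        feat = np.array([1.0, 2.0])
        obs = flare_feature_correlation(flare, feat).r
        seen = {round(shuffle_control(flare, feat, seed=s).r, 9)
                for s in range(20)}
        assert seen <= {round(obs, 9), round(-obs, 9)}
        assert len(seen) == 2

    def test_mean_near_zero(self):
        rng = np.random.default_rng(3)
        flare = (rng.random(500) < 0.3).astype(int)
        feat = rng.normal(0, 1, 500) + flare
        rs = [shuffle_control(flare, feat, seed=s).r for s in range(1000)]
        assert abs(np.mean(rs)) < 0.02

    def test_multiset_preserved(self):
        rng = np.random.default_rng(4)
        feat = rng.random(30)
        perm = np.random.default_rng(9).permutation(feat)
        assert sorted(perm) == sorted(feat)

    def test_cohort_paired_test(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(0.4, 0.05, 12)
        shuf = rng.normal(0.0, 0.05, 12)
        rep = cohort_correlation_test(obs, shuf)
        assert rep.p_value < 1e-6
        assert rep.t_statistic > 0


class TestSelectBouts:
    def make(self, spans, n=4000):
        flare = np.zeros(n, dtype=int)
        for a, b in spans:
            flare[a:b] = 1
        return flare

    def test_single_long_bout(self):
        flare = self.make([(1000, 1400)])    # 10 s bout at 40 fps
        ev = select_bouts(flare, 40.0)
        q = [e for e in ev if e.qualifies]
        assert len(q) == 2
        assert {e.kind for e in q} == {"onset", "offset"}
        assert q[0].frame == 1000 and q[1].frame == 1400

    def test_close_bouts_disqualify_inner_events(self):
        # two bouts 1 s apart: first offset and second onset non-qualifying
        flare = self.make([(1000, 1200), (1240, 1440)])
        ev = {(e.kind, e.frame): e.qualifies for e in select_bouts(flare, 40.0)}
        assert ev[("onset", 1000)] is True
        assert ev[("offset", 1200)] is False
        assert ev[("onset", 1240)] is False
        assert ev[("offset", 1440)] is True

    def test_boundary_events_never_qualify(self):
        flare = self.make([(0, 400), (3800, 4000)])
        ev = select_bouts(flare, 40.0)
        assert not any(e.qualifies for e in ev
                       if e.frame < 120 or e.frame > 3880)

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(6)
        flare = (rng.random(3000) < 0.35).astype(int)
        w = 120
        ev = select_bouts(flare, 40.0, isolation_s=3.0)
        for e in ev:
            t = e.frame
            if e.kind == "onset":
                expected = (t - w >= 0 and t + w <= 3000
                            and not flare[t - w:t].any()
                            and flare[t:t + w].all())
            else:
                expected = (t - w >= 0 and t + w <= 3000
                            and flare[t - w:t].all()
                            and not flare[t:t + w].any())
            assert e.qualifies == expected


class TestPETH:
    def test_single_event_mean_is_trace_sem_zero(self):
        feat = np.sin(np.arange(500) / 10.0)
        ev = [BoutEvent("onset", 250, True)]
        h = peth(ev, feat, 40.0)
        np.testing.assert_array_equal(h.mean, feat[130:371])
        assert np.all(h.sem == 0.0)

    def test_step_after_onset_appears_at_half_second(self):
        n = 20000
        feat = np.zeros(n)
        onsets = [2000, 6000, 10000, 14000]
        for f in onsets:
            feat[f + 20:f + 120] = 1.0       # step 0.5 s after each onset
        ev = [BoutEvent("onset", f, True) for f in onsets]
        h = peth(ev, feat, 40.0)
        t = h.time_axis
        assert np.all(h.mean[t < 0.5] == 0.0)
        assert h.mean[np.searchsorted(t, 0.5)] == 1.0

    def test_constant_feature_flat(self):
        ev = [BoutEvent("offset", 200, True), BoutEvent("offset", 400, True)]
        h = peth(ev, np.full(1000, 2.5), 40.0, kind="offset")
        assert np.allclose(h.mean, 2.5)
        assert np.allclose(h.sem, 0.0)

    def test_no_events_sentinel(self):
        h = peth([], np.zeros(100), 40.0)
        assert h.n_events == 0 and h.mean is None

    def test_identical_events_mean_equals_single_trace(self):
        feat = np.cos(np.arange(1000) / 7.0)
        # same window content: feature is periodic with the event spacing
        ev = [BoutEvent("onset", 300, True)]
        single = peth(ev, feat, 40.0)
        k = peth(ev * 5, feat, 40.0)
        np.testing.assert_allclose(k.mean, single.mean)


class TestNormalizeElevation:
    def test_simple_window(self):
        out, flag = normalize_elevation(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])
        assert not flag

    def test_constant_window_zeros_flagged(self):
        out, flag = normalize_elevation(np.full(5, 3.3))
        assert np.all(out == 0.0) and flag

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_range_and_extremes(self, seed):
        w = np.random.default_rng(seed).normal(0, 5, 50)
        out, flag = normalize_elevation(w)
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)
        assert out[np.argmin(w)] == 0.0
        assert out[np.argmax(w)] == pytest.approx(1.0)


class TestPersistence:
    def test_exact_exponential_crossings(self):
        # y = A exp(-t/tau): 3/4 crossing at tau ln(4/3), 1/2 at tau ln 2
        tau = 120.0
        t = (np.arange(75) + 0.5) * 8.0
        y = 0.8 * np.exp(-t / tau)
        from flarekit.dynamics import fit_persistence_curve
        curve = fit_persistence_curve(t, y)
        assert curve.tau == pytest.approx(tau, rel=1e-3)
        assert curve.crossings[0.75] == pytest.approx(tau * np.log(4 / 3),
                                                      rel=1e-3)
        assert curve.crossings[0.5] == pytest.approx(tau * np.log(2),
                                                     rel=1e-3)
        assert curve.crossings[0.5] > curve.crossings[0.75]

    def test_tau_recovery_from_bernoulli_cohort(self):
        rng = np.random.default_rng(7)
        t = np.arange(600 * 40) / 40.0
        p = 0.4 * np.exp(-t / 100.0)
        fls = [(rng.random(t.size) < p).astype(np.int8) for _ in range(20)]
        curve = persistence_cohort(fls, 40.0)
        assert curve.fit_success
        assert abs(curve.tau - 100.0) / 100.0 < 0.10

    def test_bin_proportions_framerate_invariant(self):
        # same on/off times at 40 vs 80 fps -> same bin proportions
        spans = [(2.0, 5.0), (10.0, 11.5), (20.0, 28.0)]

        def series(fps, dur=32.0):
            x = np.zeros(int(dur * fps), dtype=int)
            for a, b in spans:
                x[int(a * fps):int(b * fps)] = 1
            return x

        c40 = persistence(series(40.0), 40.0, rolling_s=0.0)
        c80 = persistence(series(80.0), 80.0, rolling_s=0.0)
        np.testing.assert_allclose(c40.bin_proportions, c80.bin_proportions,
                                   atol=1 / (8 * 40))

    def test_too_short_record_errors(self):
        with pytest.raises(ValueError):
            persistence(np.zeros(100), 40.0)

    def test_rolling_on_bins_variant(self):
        flare = (np.random.default_rng(1).random(24000) < 0.3).astype(int)
        c = persistence(flare, 40.0, rolling_on="bins")
        assert c.bin_proportions.size == 24000 // 320
        with pytest.raises(ValueError):
            persistence(flare, 40.0, rolling_on="nope")
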