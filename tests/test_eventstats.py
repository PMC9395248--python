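"""Event rates, coverage, IEI rhythmicity, co-occurrence, band spread."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscevents import (
    BandWindows,
    active_time_ratio,
    band_limited_fraction,
    band_rhythmicity,
    cooccurrence,
    cv2,
    event_rate,
    fano_factor,
    interevent_intervals,
    rhythmicity_test,
)
from tests.conftest import make_events


class TestEventRate:
    def test_simple_rate(self):
        evs = make_events([(i, i + 0.1, i + 0.05, 10.0) for i in range(10)])
        assert event_rate(evs, "alpha", 20.0) == pytest.approx(0.5)

    def test_empty(self):
        assert event_rate([], "alpha", 10.0) == 0.0

    def test_flagged_events_excluded(self):
        evs = make_events([(i, i + 0.1, i + 0.05, 10.0) for i in range(7)])
        for e in evs[:3]:
            e.flag_broadband = True
        assert event_rate(evs, "alpha", 10.0) == pytest.approx(0.4)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            event_rate([], "alpha", 0.0)


class TestActiveTimeRatio:
    def test_half_coverage(self):
        evs = make_events([(0.0, 5.0, 2.0, 10.0)])
        assert active_time_ratio(evs, "alpha", 10.0) == pytest.approx(0.5)

    def test_duplicates_count_once(self):
        evs = make_events([(0.0, 5.0, 2.0, 10.0), (0.0, 5.0, 2.0, 10.0)])
        assert active_time_ratio(evs, "alpha", 10.0) == pytest.approx(0.5)

    def test_interval_union(self):
        evs = make_events([(0.0, 2.0, 1.0, 10.0), (1.0, 3.0, 2.0, 10.0)])
        assert active_time_ratio(evs, "alpha", 10.0) == pytest.approx(0.3)

    def test_any_band_atr_at_least_per_band(self):
        evs = make_events([(0.0, 2.0, 1.0, 10.0), (1.0, 4.0, 2.0, 6.0),
                           (6.0, 7.0, 6.5, 21.0)])
        any_band = active_time_ratio(evs, None, 10.0)
        per_band = [active_time_ratio(evs, b, 10.0)
                    for b in ("theta", "alpha", "beta")]
        assert any_band >= max(per_band)
        assert any_band == pytest.approx(0.5)


class TestIntervals:
    def test_peak_mode(self):
        evs = make_events([(0.9, 1.1, 1.0, 10.0), (1.9, 2.1, 2.0, 10.0),
                           (3.9, 4.1, 4.0, 10.0)])
        np.testing.assert_allclose(
            interevent_intervals(evs, "alpha", "peak"), [1.0, 2.0])

    def test_edge_mode_abutting(self):
        evs = make_events([(0.0, 1.0, 0.5, 10.0), (1.0, 2.0, 1.5, 10.0)])
        np.testing.assert_allclose(
            interevent_intervals(evs, "alpha", "edge"), [0.0])

    def test_edge_mode_overlap_clamped_to_zero(self):
        evs = make_events([(0.0, 2.0, 1.0, 10.0), (1.5, 3.0, 2.0, 10.0),
                           (4.0, 5.0, 4.5, 10.0)])
        np.testing.assert_allclose(
            interevent_intervals(evs, "alpha", "edge"), [0.0, 1.0])

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            interevent_intervals(make_events([(0, 1, 0.5, 10.0)]), "alpha")


class TestCV2:
    def test_constant_intervals(self):
        assert cv2(np.full(10, 2.0)) == 0.0

    def test_hand_population_moments(self):
        assert cv2(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0 / 6.0)

    def test_poisson_calibration(self):
        rng = np.random.default_rng(0)
        assert cv2(rng.exponential(1.0, 50_000)) == pytest.approx(1.0, abs=0.05)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv2(np.zeros(5))

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 50))
    def test_scale_invariance(self, c, seed):
        x = np.random.default_rng(seed).exponential(1.0, 50) + 0.01
        assert cv2(c * x) == pytest.approx(cv2(x), rel=1e-9)

    def test_jitter_recovery_monotone(self):
        # periodic trains with shrinking jitter: CV2 decreases toward 0
        rng = np.random.default_rng(1)
        base = np.arange(200) * 1.0
        vals = []
        for sigma in (0.3, 0.1, 0.03, 0.0):
            times = base + rng.normal(0, sigma, base.size)
            vals.append(cv2(np.diff(np.sort(times))))
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0


class TestFanoFactor:
    def test_periodic_events(self):
        times = np.arange(0, 100, 0.5)  # 20 per 10-s window, exactly
        assert fano_factor(times, 10.0, 100.0) == 0.0

    def test_hand_counts(self):
        # windows of 10 s holding 2 and 4 events: var 1 / mean 3
        times = np.array([1.0, 2.0, 11.0, 12.0, 13.0, 14.0])
        assert fano_factor(times, 10.0, 20.0) == pytest.approx(1.0 / 3.0)

    def test_poisson_calibration(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(rng.exponential(1 / 1.6, 16_000))
        total = times[-1]
        assert fano_factor(times[times < total], 10.0, total) == pytest.approx(
            1.0, abs=0.05)

    def test_guards(self):
        with pytest.raises(ValueError):
            fano_factor(np.array([1.0]), 10.0, 15.0)
        with pytest.raises(ValueError):
            fano_factor(np.array([]), 10.0, 100.0)


class TestRhythmicityTest:
    def test_clearly_rhythmic(self):
        assert rhythmicity_test(np.full(10, 0.2)) < 0.05

    def test_null_symmetric_around_one(self):
        vals = 1.0 + np.array([-0.2, -0.1, -0.05, 0.05, 0.1, 0.2])
        assert rhythmicity_test(vals) == pytest.approx(0.5, abs=0.2)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            rhythmicity_test(np.array([0.5]))

    def test_band_windows_defaults(self):
        bw = BandWindows()
        assert [bw[b] for b in
                ("delta", "theta", "alpha", "beta", "lgamma", "gamma",
                 "hgamma")] == [44.0, 30.0, 24.0, 10.7, 12.0, 3.6, 1.3]

    def test_band_rhythmicity_of_jittered_train(self):
        rng = np.random.default_rng(3)
        times = np.arange(0.75, 600, 1.5) + rng.normal(0, 0.08, 400)
        evs = make_events([(t - 0.05, t + 0.05, t, 10.0) for t in times])
        res = band_rhythmicity(evs, "alpha", 600.0)
        assert res.cv2_mean < 0.5
        assert res.fano < 0.5
        assert res.p_value < 0.05


class TestCooccurrence:
    def test_full_nesting(self):
        evs = make_events([(0.0, 4.0, 2.0, 6.0), (1.0, 2.0, 1.5, 57.0)])
        m = cooccurrence(evs)
        assert m.loc["theta", "gamma"] == 1.0

    def test_no_overlap(self):
        evs = make_events([(0.0, 1.0, 0.5, 6.0), (2.0, 3.0, 2.5, 57.0)])
        assert cooccurrence(evs).loc["theta", "gamma"] == 0.0

    def test_hand_count(self):
        # 2 theta (1 overlapping), 2 gamma (1 overlapping) -> 2/4
        evs = make_events([
            (0.0, 1.0, 0.5, 6.0), (5.0, 6.0, 5.5, 6.0),
            (0.5, 1.5, 1.0, 57.0), (8.0, 9.0, 8.5, 57.0),
        ])
        m = cooccurrence(evs)
        assert m.loc["theta", "gamma"] == pytest.approx(0.5)
        assert m.loc["gamma", "theta"] == pytest.approx(0.5)

    def test_event_counted_once_despite_multiple_partners(self):
        evs = make_events([
            (0.0, 10.0, 5.0, 6.0),
            (1.0, 2.0, 1.5, 57.0), (3.0, 4.0, 3.5, 57.0),
        ])
        # 1 theta overlapping + 2 gamma overlapping out of 3 events
        assert cooccurrence(evs).loc["theta", "gamma"] == pytest.approx(1.0)


class TestBandLimitedFraction:
    def test_hand_table(self):
        evs = make_events([
            dict(t_start=0, t_stop=1, t_peak=0.5, peakF=10.0, minF=9.5,
                 maxF=12.0),                      # limited
            dict(t_start=2, t_stop=3, t_peak=2.5, peakF=10.0, minF=7.0,
                 maxF=12.0),                      # spreads lower (theta)
            dict(t_start=4, t_stop=5, t_peak=4.5, peakF=10.0, minF=9.5,
                 maxF=20.0),                      # spreads higher (beta)
            dict(t_start=6, t_stop=7, t_peak=6.5, peakF=10.0, minF=7.0,
                 maxF=20.0),                      # spreads both ways
        ])
        tab = band_limited_fraction(evs)
        row = tab.loc["alpha"]
        assert row["n"] == 4
        assert row["limited"] == pytest.approx(0.25)
        assert row["spread_lower"] == pytest.approx(0.5)
        assert row["spread_higher"] == pytest.approx(0.5)

    def test_categories_consistent(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(30):
            peak = rng.uniform(9.5, 14.5)
            rows.append(dict(t_start=2.0 * i, t_stop=2.0 * i + 1,
                             t_peak=2.0 * i + 0.5, peakF=peak,
                             minF=peak - rng.uniform(0, 4),
                             maxF=peak + rng.uniform(0, 4)))
        tab = band_limited_fraction(make_events(rows))
        row = tab.loc["alpha"]
        assert row["limited"] <= 1.0 - max(0.0, row["spread_lower"]
                                           + row["spread_higher"] - 1.0)
        assert row["limited"] >= 1.0 - row["spread_lower"] - row["spread_higher"]
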