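"""Band classification, event features, and contaminant exclusion."""

import numpy as np
import pytest

from oscevents import (
    BandScheme,
    ErpTemplate,
    align_zero_phase,
    apply_exclusions,
    bandpass_event,
    classify_band,
    count_extrema,
    erp_score,
    filter_match,
    fspan,
)
from oscevents.detection import OscEvent


class TestClassifyBand:
    @pytest.mark.parametrize("f,expected", [
        (10.0, "alpha"),
        (4.0, "delta"),      # upper bound closed
        (4.0001, "theta"),   # lower bound open
        (9.0, "theta"),
        (30.0, "beta"),      # printed 29->30 gap folded into beta
        (80.0, "gamma"),
        (80.5, "hgamma"),
        (300.0, "unclassified"),
        (0.4, "unclassified"),
    ])
    def test_boundaries(self, f, expected):
        assert classify_band(f) == expected

    def test_combined_gamma_scheme(self):
        scheme = BandScheme.combined_gamma()
        assert classify_band(35.0, scheme) == "gamma"
        assert classify_band(57.0, scheme) == "gamma"
        assert classify_band(100.0, scheme) == "hgamma"

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            classify_band(0.0)

    def test_schemes_must_be_contiguous(self):
        with pytest.raises(ValueError):
            BandScheme((("a", 1.0, 4.0), ("b", 5.0, 10.0)))


class TestFspan:
    def test_equal_bounds(self):
        assert fspan(10.0, 10.0) == 0.0

    def test_direct_evaluation(self):
        assert fspan(9.0, 15.0) == pytest.approx(np.log(5.0 / 3.0))
        assert fspan(9.0, 15.0) == pytest.approx(0.5108, abs=1e-4)

    def test_threshold_in_octaves(self):
        # the broadband cut-off of 1.5 (natural log) is 1.5/ln2 octaves
        assert 1.5 / np.log(2.0) == pytest.approx(2.17, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fspan(0.0, 5.0)
        with pytest.raises(ValueError):
            fspan(6.0, 5.0)


class TestBandpass:
    fs = 500.0
    t = np.arange(0, 4, 1 / fs)

    def test_zero_phase_on_in_band_sinusoid(self):
        x = np.sin(2 * np.pi * 10 * self.t)
        y = bandpass_event(x, 8.0, 12.0, self.fs)
        sl = slice(200, -200)
        r = np.corrcoef(x[sl], y[sl])[0, 1]
        assert r > 0.99
        xc = np.correlate(x[sl] - x[sl].mean(), y[sl] - y[sl].mean(), "full")
        assert abs(np.argmax(xc) - (len(x[sl]) - 1)) == 0  # peak at lag 0

    def test_out_of_band_attenuation(self):
        x10 = np.sin(2 * np.pi * 10 * self.t)
        x60 = np.sin(2 * np.pi * 60 * self.t)
        y = bandpass_event(x10 + x60, 8.0, 12.0, self.fs)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(y.size, 1 / self.fs)
        p60 = spec[np.argmin(np.abs(freqs - 60))]
        p60_in = np.abs(np.fft.rfft(x10 + x60))[np.argmin(np.abs(freqs - 60))]
        assert 20 * np.log10(p60_in / p60) > 20

    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(
            bandpass_event(np.zeros(1000), 8.0, 12.0, self.fs), 0.0)

    def test_degenerate_band_widened(self):
        y = bandpass_event(np.sin(2 * np.pi * 10 * self.t), 10.0, 10.0,
                           self.fs, freq_step=0.25)
        assert np.std(y) > 0.1  # passband survived

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_event(np.zeros(100), 300.0, 400.0, self.fs)


class TestFilterMatch:
    def test_identical_segments(self):
        x = np.sin(np.linspace(0, 10, 100))
        r, label = filter_match(x, x)
        assert r == pytest.approx(1.0)
        assert label == "strong/high"

    def test_sign_flip(self):
        x = np.sin(np.linspace(0, 10, 100))
        r, label = filter_match(x, -x)
        assert r == pytest.approx(-1.0)
        assert label == "weak"

    def test_moderate_range(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        noise = rng.normal(size=2000)
        # mix calibrated to give r ~ 0.3
        y = 0.3 * x + np.sqrt(1 - 0.09) * noise
        r, label = filter_match(x, y)
        assert 0.25 < r <= 0.5
        assert label == "moderate"

    def test_constant_segment_rejected(self):
        with pytest.raises(ValueError):
            filter_match(np.ones(10), np.arange(10.0))


class TestCountExtrema:
    def test_sinusoid_cycles(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        n_peaks, n_troughs = count_extrema(np.sin(2 * np.pi * 5 * t))
        assert n_peaks == 5
        assert n_troughs == 5

    def test_monotone_ramp(self):
        assert count_extrema(np.arange(10.0)) == (0, 0)

    def test_hand_sequence(self):
        assert count_extrema([0.0, 1.0, 0.0, 2.0, 0.0]) == (2, 1)


class TestErpScore:
    def _template(self, fs=500.0):
        t = np.arange(0, 0.1, 1 / fs)
        wf = np.exp(-((t - 0.05) ** 2) / (2 * 0.01**2))
        return ErpTemplate(wf - wf.mean(), fs, "gran")

    def test_identical_event_scores_one(self):
        tpl = self._template()
        assert erp_score(tpl.waveform, tpl) == pytest.approx(1.0)

    def test_scale_invariance(self):
        tpl = self._template()
        assert erp_score(3.0 * tpl.waveform, tpl) == pytest.approx(1.0)

    def test_orthogonal_sinusoid_scores_low(self):
        # equal lengths -> single lag; sine and cosine over integer cycles
        # are exactly orthogonal there
        fs = 500.0
        t = np.arange(0, 0.5, 1 / fs)  # 5 full cycles at 10 Hz
        tpl = ErpTemplate(np.sin(2 * np.pi * 10 * t), fs, "x")
        event = np.cos(2 * np.pi * 10 * t)
        assert abs(erp_score(event, tpl)) < 0.1

    def test_shifted_template_found(self):
        tpl = self._template()
        event = np.zeros(500)
        event[200:250] += tpl.waveform
        assert erp_score(event, tpl) > 0.95

    def test_template_resampling(self):
        tpl = self._template(fs=1000.0)
        down = tpl.resampled(500.0)
        assert down.fs == 500.0
        assert down.waveform.size == tpl.waveform.size // 2


class TestExclusions:
    def _event(self, duration=0.1, erp=np.nan, minF=9.0, maxF=12.0):
        return OscEvent(t_start=1.0, t_stop=1.0 + duration, t_peak=1.05,
                        minF=minF, maxF=maxF, peakF=10.0, peak_power=5.0,
                        erp_score=erp)

    def test_erp_like_event_flagged(self):
        ev = apply_exclusions([self._event(duration=0.1, erp=0.9)])[0]
        assert ev.flag_erp

    def test_long_event_not_erp_flagged(self):
        ev = apply_exclusions([self._event(duration=0.5, erp=0.95)])[0]
        assert not ev.flag_erp

    def test_broadband_event_flagged(self):
        ev = apply_exclusions([self._event(minF=2.0, maxF=20.0)])[0]
        assert ev.flag_broadband  # ln(10) = 2.30 > 1.5
        assert ev.is_excluded

    def test_narrowband_not_flagged(self):
        ev = apply_exclusions([self._event()])[0]
        assert not ev.flag_broadband

    def test_no_templates_skips_erp_rule(self):
        ev = apply_exclusions([self._event(duration=0.1)])[0]
        assert not ev.flag_erp

    def test_flags_commute(self):
        a = self._event(duration=0.1, erp=0.9, minF=2.0, maxF=20.0)
        b = self._event(duration=0.1, erp=0.9, minF=2.0, maxF=20.0)
        apply_exclusions([a])
        apply_exclusions(apply_exclusions([b]))  # order/idempotence
        assert (a.flag_erp, a.flag_broadband) == (b.flag_erp, b.flag_broadband)
        assert a.flag_erp and a.flag_broadband


class TestAlignZeroPhase:
    def test_crest_alignment_on_sinusoid(self):
        fs = 500.0
        t = np.arange(0, 2, 1 / fs)
        x = np.sin(2 * np.pi * 5 * t)
        ev = OscEvent(t_start=0.0, t_stop=2.0, t_peak=1.0, minF=4.0, maxF=6.0,
                      peakF=5.0, it_min=0, it_max=999)
        t0 = align_zero_phase(ev, x, fs=fs)
        # crest of sin(2 pi 5 t) nearest t=1.0 is at t=1.05
        assert t0 == pytest.approx(1.05, abs=2 / fs)

    def test_shift_equivariance(self):
        # shifting signal and peak time together shifts the crest time
        fs = 500.0
        t = np.arange(0, 2, 1 / fs)
        for shift in (0.0, 0.1):
            x = np.sin(2 * np.pi * 5 * (t - shift))
            ev = OscEvent(t_start=0.0, t_stop=2.0, t_peak=1.0 + shift,
                          minF=4.0, maxF=6.0, peakF=5.0, it_min=0, it_max=999)
            t0 = align_zero_phase(ev, x, fs=fs)
            if shift == 0.0:
                base = t0
        assert t0 - base == pytest.approx(0.1, abs=2 / fs)

    def test_nearest_crest_rule(self):
        # crests at 0.95 and 1.05; peak power at 1.02 -> pick 1.05
        ev = OscEvent(t_start=0.9, t_stop=1.1, t_peak=1.02, peakF=10.0)
        fs = 1000.0
        tt = np.arange(0.9, 1.1, 1 / fs)
        ev.filtered = np.cos(2 * np.pi * 10 * (tt - 1.05))
        assert align_zero_phase(ev, fs=fs) == pytest.approx(1.05, abs=2 / fs)

    def test_no_extremum_rejected(self):
        ev = OscEvent(t_start=0.0, t_stop=0.01, t_peak=0.005, peakF=10.0)
        ev.filtered = np.arange(10.0)
        with pytest.raises(ValueError):
            align_zero_phase(ev, fs=1000.0)
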