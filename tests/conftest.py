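import numpy as np
import pytest

from oscevents import DetectionParams, Recording


@pytest.fixture
def fast_params() -> DetectionParams:
    """Reduced frequency grid for quick detection tests."""
    return DetectionParams(freq_min=0.5, freq_max=60.0, freq_step=0.5)


@pytest.fixture
def alpha_recording() -> Recording:
    """30 s of weak 1/f noise with a 10-Hz sinusoid filling the middle window."""
    from oscevents import embed_burst, gen_background

    rec = gen_background(30.0, 500.0, exponent=1.5, scale=0.02, seed=7)
    t = np.arange(rec.n_times) / rec.fs
    x = rec.samples.copy()
    x[0, (t >= 10.0) & (t < 20.0)] += np.sin(
        2 * np.pi * 10.0 * t[(t >= 10.0) & (t < 20.0)])
    return Recording(x, fs=rec.fs, channel_labels=rec.channel_labels)


def make_events(rows):
    """Build a list of OscEvents from (t_start, t_stop, t_peak, peakF) tuples
    or dicts of OscEvent fields."""
    from oscevents import OscEvent, classify_band

    events = []
    for i, r in enumerate(rows):
        if isinstance(r, dict):
            kw = dict(r)
        else:
            t0, t1, tp, f = r
            kw = dict(t_start=t0, t_stop=t1, t_peak=tp, peakF=f,
                      minF=f, maxF=f)
        kw.setdefault("id", i)
        kw.setdefault("band", classify_band(kw["peakF"]))
        kw.setdefault("peak_power", 5.0)
        events.append(OscEvent(**kw))
    return events
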