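"""Event-train statistics: rates, coverage, rhythmicity, co-occurrence.

Rhythmicity of event occurrence within a band is quantified on
interevent-interval (IEI) distributions by the squared coefficient of
variation CV2 = var/mean^2 and on event counts in fixed windows by the
Fano factor FF = var/mean. Both equal 1 for a homogeneous Poisson
process, fall below 1 for rhythmic (regular) event trains, and exceed 1
for bursty trains. Windows are sized per band (longer for slower bands)
so each holds a comparable number of events; a one-sided Wilcoxon
signed-rank test against 1 assesses sub-Poisson regularity.

Population (divide-by-n) variance is used throughout, which keeps the
Poisson calibration CV2 = FF = 1 asymptotically and makes small hand
examples exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .detection import EventTable, OscEvent
from .features import BandScheme

__all__ = [
    "BandWindows",
    "RhythmicityResult",
    "event_rate",
    "active_time_ratio",
    "interevent_intervals",
    "cv2",
    "fano_factor",
    "rhythmicity_test",
    "band_rhythmicity",
    "cooccurrence",
    "band_limited_fraction",
]

# per-band analysis window (s), sized to hold ~12-18 events per window
DEFAULT_BAND_WINDOWS: dict[str, float] = {
    "delta": 44.0, "theta": 30.0, "alpha": 24.0, "beta": 10.7,
    "lgamma": 12.0, "gamma": 3.6, "hgamma": 1.3,
}


@dataclass(frozen=True)
class BandWindows:
    windows: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WINDOWS))

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.windows.values()):
            raise ValueError("window lengths must be positive")

    def __getitem__(self, band: str) -> float:
        return self.windows[band]


@dataclass
class RhythmicityResult:
    band: str
    cv2_values: np.ndarray
    fano: float
    cv2_mean: float
    cv2_sem: float
    p_value: float


def _band_events(events: Iterable[OscEvent] | EventTable, band: str | None) -> list[OscEvent]:
    evs = events.unflagged() if isinstance(events, EventTable) else [
        e for e in events if not e.is_excluded]
    if band is not None:
        evs = [e for e in evs if e.band == band]
    return sorted(evs, key=lambda e: e.t_start)


def event_rate(events: Iterable[OscEvent] | EventTable, band: str | None,
               total_duration: float) -> float:
    """Unflagged events of a band per second of recording."""
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    return len(_band_events(events, band)) / total_duration


def active_time_ratio(events: Iterable[OscEvent] | EventTable,
                      band: str | None, total_duration: float) -> float:
    """Fraction of the recording covered by the union of event spans.

    ``band=None`` gives the any-band ATR. Overlapping and nested events
    count once, so per-band ATRs may sum above 1 while each stays in [0,1].
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    evs = _band_events(events, band)
    covered = 0.0
    cur_start, cur_stop = None, None
    for e in evs:
        if cur_stop is None or e.t_start > cur_stop:
            if cur_stop is not None:
                covered += cur_stop - cur_start
            cur_start, cur_stop = e.t_start, e.t_stop
        else:
            cur_stop = max(cur_stop, e.t_stop)
    if cur_stop is not None:
        covered += cur_stop - cur_start
    return covered / total_duration


def interevent_intervals(events: Iterable[OscEvent] | EventTable,
                         band: str, mode: str = "peak") -> np.ndarray:
    """Successive intervals between a band's events.

    ``mode="peak"``: peak-power time to peak-power time. ``mode="edge"``:
    end of one event to start of the next; overlapping events give
    negative raw gaps, reported as 0.
    """
    if mode not in ("peak", "edge"):
        raise ValueError("mode must be 'peak' or 'edge'")
    evs = _band_events(events, band)
    if len(evs) < 2:
        raise ValueError("need at least 2 events to form intervals")
    if mode == "peak":
        times = np.array([e.t_peak for e in evs])
        return np.diff(np.sort(times))
    gaps = np.array([b.t_start - a.t_stop for a, b in zip(evs[:-1], evs[1:])])
    return np.maximum(gaps, 0.0)


def cv2(intervals: np.ndarray) -> float:
    """Squared coefficient of variation: population variance / squared mean."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    m = x.mean()
    if m <= 0:
        raise ValueError("mean interval must be positive")
    return float(x.var() / m**2)


def fano_factor(event_times: np.ndarray, window_len: float,
                total_duration: float) -> float:
    """Variance-to-mean ratio of counts in consecutive nonoverlapping windows.

    Windows start at t = 0; a trailing partial window is dropped.
    """
    if total_duration < 2 * window_len:
        raise ValueError("need at least two full windows")
    t = np.asarray(event_times, dtype=float)
    n_win = int(total_duration // window_len)
    counts = np.histogram(t, bins=n_win, range=(0.0, n_win * window_len))[0]
    m = counts.mean()
    if m == 0:
        raise ValueError("no events in any window")
    return float(counts.var() / m)


def rhythmicity_test(values: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value for median(values) < 1.

    Small p indicates the CV2 (or FF) values are systematically below the
    Poisson reference of 1, i.e. rhythmic recurrence.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    d = v - 1.0
    if np.all(d == 0):
        raise ValueError("all values equal 1; test undefined")
    return float(stats.wilcoxon(d, alternative="less",
                                zero_method="wilcox").pvalue)


def band_rhythmicity(events: Iterable[OscEvent] | EventTable, band: str,
                     total_duration: float,
                     band_windows: BandWindows | None = None,
                     mode: str = "peak") -> RhythmicityResult:
    """Per-window CV2 values, overall FF and the sub-Poisson test for a band.

    The recording is tiled with the band's analysis window; CV2 is computed
    within each window holding >= 3 events, FF from the counts across all
    windows.
    """
    band_windows = band_windows or BandWindows()
    wlen = band_windows[band]
    evs = _band_events(events, band)
    times = np.array([e.t_peak for e in evs])
    n_win = int(total_duration // wlen)
    cv2_vals = []
    for w in range(n_win):
        sel = times[(times >= w * wlen) & (times < (w + 1) * wlen)]
        if sel.size >= 3:
            cv2_vals.append(cv2(np.diff(np.sort(sel))))
    cv2_vals = np.asarray(cv2_vals)
    ff = fano_factor(times, wlen, total_duration)
    p = rhythmicity_test(cv2_vals) if cv2_vals.size >= 5 else np.nan
    sem = cv2_vals.std(ddof=1) / np.sqrt(cv2_vals.size) if cv2_vals.size > 1 else np.nan
    return RhythmicityResult(band=band, cv2_values=cv2_vals, fano=ff,
                             cv2_mean=float(cv2_vals.mean()) if cv2_vals.size else np.nan,
                             cv2_sem=float(sem), p_value=p)


def cooccurrence(events: Iterable[OscEvent] | EventTable,
                 scheme: BandScheme | None = None) -> pd.DataFrame:
    """Band x band probability that events of two bands occur together.

    For bands a != b: the number of a-events overlapping in time any
    b-event, plus the number of b-events overlapping any a-event, divided
    by the total number of events in the two bands. Each event counts once
    however many partners it overlaps. The diagonal is left at 1.
    """
    scheme = scheme or BandScheme.default()
    labels = scheme.labels
    by_band = {b: _band_events(events, b) for b in labels}
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ea, eb = by_band[a], by_band[b]
            total = len(ea) + len(eb)
            if total == 0:
                mat.loc[a, b] = mat.loc[b, a] = 0.0
                continue
            n = sum(any(e.t_start < f.t_stop and f.t_start < e.t_stop
                        for f in eb) for e in ea)
            n += sum(any(e.t_start < f.t_stop and f.t_start < e.t_stop
                         for f in ea) for e in eb)
            mat.loc[a, b] = mat.loc[b, a] = n / total
    return mat


def band_limited_fraction(events: Iterable[OscEvent] | EventTable,
                          scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-band fractions of band-limited vs frequency-spreading events.

    An event is band-limited when both minF and maxF fall inside the band
    of its peak; it spreads lower when minF falls below that band and
    higher when maxF rises above it (an event can do both).
    """
    scheme = scheme or BandScheme.default()
    rows = []
    for band in scheme.labels:
        evs = _band_events(events, band)
        lo, hi = scheme.bounds(band)
        n = len(evs)
        if n == 0:
            rows.append({"band": band, "n": 0, "limited": np.nan,
                         "spread_lower": np.nan, "spread_higher": np.nan})
            continue
        lower = sum(e.minF <= lo for e in evs)
        higher = sum(e.maxF > hi for e in evs)
        limited = sum(e.minF > lo and e.maxF <= hi for e in evs)
        rows.append({"band": band, "n": n, "limited": limited / n,
                     "spread_lower": lower / n, "spread_higher": higher / n})
    return pd.DataFrame(rows).set_index("band")
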