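"""Per-event features, band classification, and exclusion rules.

Events are classified into physiological frequency bands by the frequency
of maximum power (peakF); band intervals are open on the lower bound and
closed on the upper. Each event's underlying signal is band-pass filtered
to its own [minF, maxF] box with a zero-phase Butterworth filter, from
which the filter-match (Pearson r between raw and filtered waveforms) and
time-domain extrema counts are computed.

Two classes of contaminant are flagged rather than deleted: ERP-like
transients (stereotyped stimulus-evoked deflections whose wavelet
signature mimics an oscillation) via normalized cross-correlation with an
average ERP template, and broadband events (frequency span
Fspan = ln(maxF/minF) > 1.5, i.e. more than ~2.17 octaves), typical of
rapid-onset transients or noise. Flagged events are kept in the table but
excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy import signal as sps
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .detection import OscEvent
    from .spectrogram import DetectionParams

__all__ = [
    "BandScheme",
    "ErpTemplate",
    "classify_band",
    "fspan",
    "bandpass_event",
    "filter_match",
    "count_extrema",
    "erp_score",
    "apply_exclusions",
    "align_zero_phase",
    "extract_features",
]

# (low, high] Hz per band, superseding the printed 1-Hz gaps so every
# frequency in (0.5, 200] is classifiable
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 9.0),
    ("alpha", 9.0, 15.0),
    ("beta", 15.0, 30.0),
    ("lgamma", 30.0, 40.0),
    ("gamma", 40.0, 80.0),
    ("hgamma", 80.0, 200.0),
)

FSPAN_LIMIT = 1.5          # natural log; ~2.17 octaves
ERP_SCORE_LIMIT = 0.8
ERP_DUR_RANGE = (0.075, 0.300)  # s


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous (low, high] frequency bands."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = None
        for _, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError("band bounds must satisfy low < high")
            if prev_high is not None and lo != prev_high:
                raise ValueError("bands must be contiguous and non-overlapping")
            prev_high = hi

    @classmethod
    def default(cls) -> "BandScheme":
        return cls(DEFAULT_BANDS)

    @classmethod
    def combined_gamma(cls) -> "BandScheme":
        """Variant merging low-gamma and gamma into one 30-80 Hz band."""
        bands = [b for b in DEFAULT_BANDS if b[0] not in ("lgamma", "gamma")]
        bands.insert(4, ("gamma", 30.0, 80.0))
        return cls(tuple(bands))

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bands]

    def bounds(self, label: str) -> tuple[float, float]:
        for name, lo, hi in self.bands:
            if name == label:
                return lo, hi
        raise KeyError(label)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def classify_band(peakF: float, scheme: BandScheme | None = None) -> str:
    """Band label whose (low, high] interval contains ``peakF``.

    Frequencies outside every band return ``"unclassified"``.
    """
    if peakF <= 0:
        raise ValueError("peakF must be positive")
    scheme = scheme or BandScheme.default()
    for name, lo, hi in scheme.bands:
        if lo < peakF <= hi:
            return name
    return "unclassified"


def fspan(minF: float, maxF: float) -> float:
    """Logarithmic frequency span ln(maxF / minF) of an event."""
    if minF <= 0 or maxF <= 0:
        raise ValueError("frequencies must be positive")
    if minF > maxF:
        raise ValueError("minF must not exceed maxF")
    return float(np.log(maxF / minF))


from functools import lru_cache


@lru_cache(maxsize=4096)
def _butter_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    # event boxes live on the detection frequency grid, so designs repeat
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_event(window_signal: np.ndarray, minF: float, maxF: float,
                   fs: float, freq_step: float = 0.25) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a window to an event's box.

    Fourth-order Butterworth realized as second-order sections, applied
    forward and backward (``sosfiltfilt``) for zero net phase shift. The
    low edge is floored at 0.1 Hz; a degenerate ``minF == maxF`` band is
    widened by one frequency-grid step on each side.
    """
    nyq = fs / 2.0
    if minF >= nyq:
        raise ValueError("band entirely above Nyquist")
    if minF == maxF:
        minF, maxF = minF - freq_step, maxF + freq_step
    lo = max(minF, 0.1)
    hi = min(maxF, nyq * 0.99)
    sos = _butter_sos(lo, hi, fs)
    x = np.asarray(window_signal, dtype=float)
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    return sps.sosfiltfilt(sos, x, padlen=min(padlen, x.size - 1))


def filter_match(raw_segment: np.ndarray, filtered_segment: np.ndarray) -> tuple[float, str]:
    """Pearson correlation between raw and filtered event waveforms.

    Returns ``(r, label)`` where the qualitative label is "weak" for
    r <= 0.25 (including negative r), "moderate" for 0.25 < r <= 0.5 and
    "strong/high" above. High r means the oscillation is plainly visible
    in the raw trace.
    """
    raw = np.asarray(raw_segment, dtype=float)
    filt = np.asarray(filtered_segment, dtype=float)
    if raw.size != filt.size:
        raise ValueError("segments must have equal length")
    if raw.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(raw) == 0 or np.ptp(filt) == 0:
        raise ValueError("Pearson r undefined for a constant segment")
    r = float(stats.pearsonr(raw, filt).statistic)
    if r > 0.5:
        label = "strong/high"
    elif r > 0.25:
        label = "moderate"
    else:
        label = "weak"
    return r, label


def count_extrema(filtered_segment: np.ndarray) -> tuple[int, int]:
    """Counts of strict interior local maxima and minima (peaks, troughs)."""
    x = np.asarray(filtered_segment, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    n_peaks = int(np.count_nonzero((d_prev > 0) & (d_next > 0)))
    n_troughs = int(np.count_nonzero((d_prev < 0) & (d_next < 0)))
    return n_peaks, n_troughs


@dataclass(frozen=True)
class ErpTemplate:
    """Average event-related-potential waveform used to score contaminants."""

    waveform: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(wf)):
            raise ValueError("template contains non-finite values")
        if np.ptp(wf) == 0:
            raise ValueError("template must be non-constant")
        object.__setattr__(self, "waveform", wf)

    def resampled(self, fs: float) -> "ErpTemplate":
        if np.isclose(fs, self.fs):
            return self
        n = int(round(self.waveform.size * fs / self.fs))
        return ErpTemplate(sps.resample(self.waveform, n), fs, self.label)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "ErpTemplate":
        import pandas as pd

        df = pd.read_csv(path)
        t, v = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return cls(v, fs, label or Path(path).stem)

    @classmethod
    def from_hdf5(cls, path: str | Path, label: str = "") -> "ErpTemplate":
        import h5py

        with h5py.File(path, "r") as f:
            wf = f["waveform"][()]
            fs = float(f["fs"][()])
        return cls(wf, fs, label or Path(path).stem)


def erp_score(event_raw: np.ndarray, template: ErpTemplate,
              fs: float | None = None) -> float:
    """Maximum normalized sliding cross-correlation of event and template.

    The shorter waveform slides across the longer; at each lag both
    segments are mean-removed and unit-normalized, and the signed maximum
    over all lags is returned (in [-1, 1]). Scale-invariant: an event that
    is a scaled copy of the template scores 1.
    """
    x = np.asarray(event_raw, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant event waveform")
    if fs is not None:
        template = template.resampled(fs)
    t = template.waveform
    short, long_ = (t, x) if t.size <= x.size else (x, t)
    short = short - short.mean()
    sn = np.linalg.norm(short)
    best = -1.0
    for lag in range(long_.size - short.size + 1):
        seg = long_[lag : lag + short.size]
        seg = seg - seg.mean()
        denom = sn * np.linalg.norm(seg)
        if denom == 0:
            continue
        best = max(best, float(np.dot(short, seg) / denom))
    return best


def apply_exclusions(events: "Iterable[OscEvent] | object",
                     templates: list[ErpTemplate] | None = None,
                     fs: float | None = None) -> list["OscEvent"]:
    """Set the ERP and broadband exclusion flags on each event.

    flag_broadband: Fspan > 1.5. flag_erp: ERP score > 0.8 and duration in
    [75, 300] ms (requires templates and an event raw waveform; skipped
    otherwise, as for recordings without ERP data). The two rules are
    independent, so flagging commutes. Events stay in the table; statistics
    consume ``EventTable.unflagged()``.
    """
    evs = list(events.events) if hasattr(events, "events") else list(events)
    lo, hi = ERP_DUR_RANGE
    for ev in evs:
        ev.flag_broadband = ev.fspan > FSPAN_LIMIT
        if not np.isnan(ev.erp_score):
            ev.flag_erp = (ev.erp_score > ERP_SCORE_LIMIT
                           and lo <= ev.duration <= hi)
    return evs


def align_zero_phase(event: "OscEvent", window_signal: np.ndarray | None = None,
                     fs: float | None = None, t_offset: float = 0.0) -> float:
    """Time of the filtered-waveform crest nearest the event's power peak.

    Used to align event waveforms for display: time zero corresponds to
    oscillation phase 0 (a local maximum) closest to peak power. Raises if
    the filtered span has no local maximum.
    """
    filt = event.filtered
    if filt is None:
        if window_signal is None or fs is None:
            raise ValueError("event has no filtered waveform; pass the window signal")
        full = bandpass_event(window_signal, event.minF, event.maxF, fs)
        filt = full[event.it_min : event.it_max + 1]
    if fs is None:
        fs = filt.size / event.duration
    t_offset = event.t_start
    idx = sps.argrelmax(filt)[0]
    if idx.size == 0:
        raise ValueError("no local maximum in the event span")
    crest_times = t_offset + idx / fs
    return float(crest_times[np.argmin(np.abs(crest_times - event.t_peak))])


def extract_features(ev: "OscEvent", raw_window: np.ndarray, fs: float,
                     params: "DetectionParams", scheme: BandScheme,
                     templates: list[ErpTemplate] | None = None) -> None:
    """Fill an event's derived features in place.

    Filters the full analysis window to the event's [minF, maxF] (avoiding
    filter transients at the event edges), then extracts the event span for
    filter-match and extrema counts. ERP scoring matches templates by
    channel label, falling back to the single template when only one is
    given.
    """
    ev.band = classify_band(ev.peakF, scheme)
    # filter a neighborhood a few low-edge cycles beyond the event so the
    # event span is free of filter edge transients
    pad = int(round(3.0 / max(ev.minF, 0.1) * fs))
    j0 = max(0, ev.it_min - pad)
    j1 = min(raw_window.size, ev.it_max + 1 + pad)
    filt = bandpass_event(raw_window[j0:j1], ev.minF, ev.maxF, fs,
                          freq_step=params.freq_step)
    seg_raw = raw_window[ev.it_min : ev.it_max + 1]
    seg_filt = filt[ev.it_min - j0 : ev.it_max + 1 - j0]
    ev.filtered = seg_filt
    if seg_raw.size >= 3 and np.ptp(seg_raw) > 0 and np.ptp(seg_filt) > 0:
        ev.filter_match, _ = filter_match(seg_raw, seg_filt)
    ev.n_peaks, ev.n_troughs = count_extrema(seg_filt) if seg_filt.size >= 3 else (0, 0)
    if templates:
        tpl = next((t for t in templates if t.label == ev.channel), templates[0])
        if np.ptp(seg_raw) > 0:
            ev.erp_score = erp_score(seg_raw, tpl, fs=fs)
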