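"""Oscillation-event detection in the normalized wavelet spectrogram.

An oscillation event is a contiguous time-frequency region of moderate to
high median-normalized power surrounding a local spectral maximum. The
pipeline: find every bin that exceeds its 3x3 neighborhood and the power
threshold (a multiple of the per-frequency median); grow a bounding box
around each peak until power falls below the smaller of half the peak
amplitude and the threshold; merge boxes whose overlap exceeds a fraction
of the smaller box; extract per-event features. Detection runs per
analysis window (events never span the nonoverlapping windows), while the
normalization medians are global to the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import features as feat
from .signal_io import Recording
from .spectrogram import DetectionParams, Spectrogram, morlet_power, normalize_by_median

__all__ = [
    "SpectralPeak",
    "OscEvent",
    "EventTable",
    "find_peaks",
    "grow_box",
    "merge_events",
    "detect",
]

EVENT_COLUMNS = [
    "id", "channel", "window", "t_start", "t_stop", "t_peak",
    "minF", "maxF", "peakF", "peak_power", "duration", "n_cycles",
    "Fspan", "band", "filter_match", "n_peaks", "n_troughs",
    "erp_score", "flag_erp", "flag_broadband",
]


@dataclass(frozen=True)
class SpectralPeak:
    """A suprathreshold local maximum bin (frequency index, time index)."""

    f_index: int
    t_index: int
    peak_power: float  # in multiples of the per-frequency median


@dataclass
class OscEvent:
    """One detected oscillation event and its features.

    Index fields (``if_min`` ... ``it_max``) are inclusive bin bounds in the
    window-local spectrogram; the physical fields are derived from them.
    ``n_cycles = duration * peakF`` and ``Fspan = ln(maxF / minF)``.
    """

    id: int = -1
    channel: str = ""
    window_index: int = 0
    t_start: float = 0.0
    t_stop: float = 0.0
    t_peak: float = 0.0
    minF: float = 0.0
    maxF: float = 0.0
    peakF: float = 0.0
    peak_power: float = 0.0
    band: str = "unclassified"
    filter_match: float = np.nan
    n_peaks: int = 0
    n_troughs: int = 0
    erp_score: float = np.nan
    flag_erp: bool = False
    flag_broadband: bool = False
    # window-local inclusive bin bounds
    if_min: int = 0
    if_max: int = 0
    it_min: int = 0
    it_max: int = 0
    if_peak: int = 0
    it_peak: int = 0
    filtered: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_cycles(self) -> float:
        return self.duration * self.peakF

    @property
    def fspan(self) -> float:
        return feat.fspan(self.minF, self.maxF)

    @property
    def is_excluded(self) -> bool:
        return self.flag_erp or self.flag_broadband

    def box_area(self) -> int:
        """Bounding-box area in spectrogram bins."""
        return (self.if_max - self.if_min + 1) * (self.it_max - self.it_min + 1)


@dataclass
class EventTable:
    """Ordered collection of detected events with provenance."""

    events: list[OscEvent] = field(default_factory=list)
    channel: str = ""
    params: DetectionParams = field(default_factory=DetectionParams)
    total_duration: float = 0.0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def unflagged(self) -> list[OscEvent]:
        return [e for e in self.events if not e.is_excluded]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": e.id, "channel": e.channel, "window": e.window_index,
                "t_start": e.t_start, "t_stop": e.t_stop, "t_peak": e.t_peak,
                "minF": e.minF, "maxF": e.maxF, "peakF": e.peakF,
                "peak_power": e.peak_power, "duration": e.duration,
                "n_cycles": e.n_cycles, "Fspan": e.fspan, "band": e.band,
                "filter_match": e.filter_match, "n_peaks": e.n_peaks,
                "n_troughs": e.n_troughs, "erp_score": e.erp_score,
                "flag_erp": e.flag_erp, "flag_broadband": e.flag_broadband,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def frame_from_csv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path)


def find_peaks(spec: Spectrogram | np.ndarray, threshold: float) -> list[SpectralPeak]:
    """Suprathreshold 3x3 local maxima of a normalized spectrogram.

    A bin qualifies when it strictly exceeds its (up to) eight neighbors
    and exceeds ``threshold``; border bins compare against available
    neighbors only. Plateaus of exactly equal values yield a single peak,
    the earliest-time then lowest-frequency bin of the plateau.
    """
    if isinstance(spec, Spectrogram):
        if not spec.is_normalized:
            raise ValueError("find_peaks requires a normalized spectrogram")
        P = spec.power
    else:
        P = np.asarray(spec, dtype=float)

    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    nbmax = ndimage.maximum_filter(P, footprint=footprint, mode="constant",
                                   cval=-np.inf)
    above = P > threshold
    strict = above & (P > nbmax)
    peaks = [SpectralPeak(int(f), int(t), float(P[f, t]))
             for f, t in zip(*np.nonzero(strict))]

    # plateau candidates: equal to the neighborhood max but not below it
    tied = above & (P == nbmax)
    if tied.any():
        eight = np.ones((3, 3), dtype=bool)
        lab, nlab = ndimage.label(tied, structure=eight)
        for k in range(1, nlab + 1):
            comp = lab == k
            val = P[comp][0]
            # grow the plateau across all connected equal-value bins (a bin
            # adjacent to a larger one is not in `tied` but still belongs)
            eq_lab, _ = ndimage.label(P == val, structure=eight)
            comp = eq_lab == eq_lab[tuple(np.argwhere(comp)[0])]
            # a plateau bordering any strictly larger bin is not a maximum
            border = ndimage.binary_dilation(comp, structure=eight) & ~comp
            if border.any() and P[border].max() > val:
                continue
            fs, ts = np.nonzero(comp)
            order = np.lexsort((fs, ts))  # earliest time, then lowest freq
            f, t = int(fs[order[0]]), int(ts[order[0]])
            peaks.append(SpectralPeak(f, t, float(P[f, t])))
    peaks.sort(key=lambda p: (p.t_index, p.f_index))
    return peaks


def grow_box(spec: Spectrogram | np.ndarray, peak: SpectralPeak,
             threshold: float, mode: str = "axis") -> tuple[int, int, int, int]:
    """Grow the event bounding box around a spectral peak.

    Walks outward from the peak until power falls below
    ``min(peak_power / 2, threshold)``; the boundary bin is the last bin
    still at or above that bound. Time bounds walk the peak-frequency row,
    frequency bounds the peak-time column (``mode="axis"``); with
    ``mode="flood"`` the box bounds the full connected above-bound region
    containing the peak. Returns inclusive ``(it_min, it_max, if_min,
    if_max)`` clipped to the matrix (the caller passes one window).
    """
    P = spec.power if isinstance(spec, Spectrogram) else np.asarray(spec)
    bound = min(peak.peak_power / 2.0, threshold)
    fi, ti = peak.f_index, peak.t_index

    if mode == "flood":
        mask = P >= bound
        lab, _ = ndimage.label(mask)
        comp = lab == lab[fi, ti]
        fs, ts = np.nonzero(comp)
        return int(ts.min()), int(ts.max()), int(fs.min()), int(fs.max())

    row = P[fi]
    it_min = ti
    while it_min > 0 and row[it_min - 1] >= bound:
        it_min -= 1
    it_max = ti
    while it_max < row.size - 1 and row[it_max + 1] >= bound:
        it_max += 1
    col = P[:, ti]
    if_min = fi
    while if_min > 0 and col[if_min - 1] >= bound:
        if_min -= 1
    if_max = fi
    while if_max < col.size - 1 and col[if_max + 1] >= bound:
        if_max += 1
    return it_min, it_max, if_min, if_max


def merge_events(events: list[OscEvent], merge_overlap: float,
                 power: np.ndarray | None = None) -> list[OscEvent]:
    """Merge bounding boxes that overlap by more than the given fraction.

    Two events merge when their box-intersection area strictly exceeds
    ``merge_overlap`` times the smaller of the two box areas; the merged
    event takes the union box, and its peak is the maximum-power bin
    inside the union (requires ``power``; without it, the higher-power
    constituent's peak). Repeats until no pair merges; the result is
    ordered by start time. Merging bridges events separated by brief
    subthreshold dips.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    events = list(events)
    while len(events) > 1:
        events.sort(key=lambda e: (e.it_min, e.if_min))
        t0 = np.array([e.it_min for e in events])
        t1 = np.array([e.it_max for e in events])
        f0 = np.array([e.if_min for e in events])
        f1 = np.array([e.if_max for e in events])
        area = (t1 - t0 + 1) * (f1 - f0 + 1)
        # candidate pairs must overlap in time: with events sorted by
        # it_min, partner j > i qualifies only while t0[j] <= t1[i]
        hi_j = np.searchsorted(t0, t1, side="right")
        ii = np.concatenate([np.repeat(i, hi_j[i] - i - 1)
                             for i in range(len(events))]) \
            if np.any(hi_j > np.arange(len(events)) + 1) else np.array([], int)
        jj = np.concatenate([np.arange(i + 1, hi_j[i])
                             for i in range(len(events))]) \
            if ii.size else np.array([], int)
        if ii.size == 0:
            break
        ot = np.minimum(t1[ii], t1[jj]) - np.maximum(t0[ii], t0[jj]) + 1
        of = np.maximum(
            0, np.minimum(f1[ii], f1[jj]) - np.maximum(f0[ii], f0[jj]) + 1)
        ok = ot * of > merge_overlap * np.minimum(area[ii], area[jj])
        if not ok.any():
            break
        n = len(events)
        graph = coo_matrix((np.ones(int(ok.sum())), (ii[ok], jj[ok])),
                           shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        out: list[OscEvent] = []
        for k in np.unique(labels):
            members = [events[i] for i in np.flatnonzero(labels == k)]
            if len(members) == 1:
                out.append(members[0])
                continue
            hi = max(members, key=lambda e: e.peak_power)
            ev = OscEvent(
                channel=hi.channel, window_index=hi.window_index,
                it_min=min(e.it_min for e in members),
                it_max=max(e.it_max for e in members),
                if_min=min(e.if_min for e in members),
                if_max=max(e.if_max for e in members),
                it_peak=hi.it_peak, if_peak=hi.if_peak,
                peak_power=hi.peak_power,
            )
            if power is not None:
                _locate_peak(ev, power)
            out.append(ev)
        events = out
        if len(events) == n:  # no reduction; avoid infinite loop
            break
    events.sort(key=lambda e: (e.it_min, e.if_min))
    return events


def _locate_peak(ev: OscEvent, power: np.ndarray) -> None:
    """Reassign the event's peak to the maximum-power bin inside its box."""
    sub = power[ev.if_min : ev.if_max + 1, ev.it_min : ev.it_max + 1]
    df, dt = np.unravel_index(int(np.argmax(sub)), sub.shape)
    ev.if_peak = ev.if_min + int(df)
    ev.it_peak = ev.it_min + int(dt)
    ev.peak_power = float(sub[df, dt])


def detect(
    rec: Recording,
    channel: int | str = 0,
    params: DetectionParams | None = None,
    band_scheme: "feat.BandScheme | None" = None,
    erp_templates: "list[feat.ErpTemplate] | None" = None,
    spec: Spectrogram | None = None,
) -> EventTable:
    """Run the full detection pipeline on one channel.

    Wavelet power -> median normalization -> per-window peak finding, box
    growth and merging -> feature extraction -> ERP/broadband exclusion
    flags. Deterministic given its inputs. A precomputed (unnormalized)
    ``spec`` may be passed to reuse the transform across threshold or
    merge settings.
    """
    params = params or DetectionParams()
    band_scheme = band_scheme or feat.BandScheme.default()
    ch_label = rec.channel_labels[rec.channel_index(channel)]
    x = rec.get_channel(channel)
    if not np.any(x):  # silent channel: nothing to normalize against
        return EventTable(events=[], channel=ch_label, params=params,
                          total_duration=rec.duration)

    if spec is None:
        spec = morlet_power(rec, channel, params)
    nspec = spec if spec.is_normalized else normalize_by_median(spec)

    n_win_samples = int(round(params.window_len * rec.fs))
    events: list[OscEvent] = []
    for w in range(nspec.n_windows):
        sl = nspec.window_slice(w)
        P = nspec.power[:, sl]
        cands: list[OscEvent] = []
        for pk in find_peaks(P, params.threshold):
            it0, it1, if0, if1 = grow_box(P, pk, params.threshold,
                                          mode=params.box_growth)
            ev = OscEvent(
                channel=ch_label, window_index=w,
                it_min=it0, it_max=it1, if_min=if0, if_max=if1,
                it_peak=pk.t_index, if_peak=pk.f_index,
                peak_power=pk.peak_power,
            )
            # the box can bound a larger off-axis bin than the seeding
            # 3x3 maximum; the event's peak is the box-wide maximum
            _locate_peak(ev, P)
            cands.append(ev)
        cands = merge_events(cands, params.merge_overlap, power=P)

        t_off = rec.t0 + w * params.window_len
        dt = 1.0 / rec.fs
        raw_win = x[w * n_win_samples : (w + 1) * n_win_samples]
        for ev in cands:
            ev.t_start = t_off + ev.it_min * dt
            ev.t_stop = t_off + (ev.it_max + 1) * dt  # half-open span
            ev.t_peak = t_off + ev.it_peak * dt
            ev.minF = float(nspec.freqs[ev.if_min])
            ev.maxF = float(nspec.freqs[ev.if_max])
            ev.peakF = float(nspec.freqs[ev.if_peak])
            feat.extract_features(ev, raw_win, rec.fs, params, band_scheme,
                                  templates=erp_templates)
        events.extend(cands)

    events = feat.apply_exclusions(events, erp_templates, fs=rec.fs)
    for i, ev in enumerate(events):
        ev.id = i
    return EventTable(events=events, channel=ch_label, params=params,
                      total_duration=nspec.n_windows * params.window_len)
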