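"""Morlet wavelet spectrograms with per-frequency median normalization.

The time-frequency decomposition behind event detection: complex Morlet
wavelets of a fixed number of cycles (default 7, a compromise between time
and frequency resolution) evaluated on a linear frequency grid (default
0.25-250 Hz in 0.25-Hz steps), applied to nonoverlapping fixed-length
windows (default 10 s). Power is the squared magnitude of the wavelet
coefficient. Each frequency row is then divided by its median over the
full recording so that a single power threshold (a multiple of the median)
is comparable across frequencies despite the 1/f shape of neural spectra.

The wavelet convention: width ``w`` is the number of cycles, i.e. the
Gaussian envelope has sigma_t = w / (2 pi f). Amplitude is normalized so a
unit-amplitude sinusoid at the tuned frequency yields power 1 regardless of
f. The transform is computed per window as a zero-padded convolution,
realized in the frequency domain (the analytic Morlet is a Gaussian on the
positive-frequency axis), which is exact and fast for long windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft

from .signal_io import Recording

__all__ = ["DetectionParams", "Spectrogram", "morlet_power", "normalize_by_median"]


@dataclass(frozen=True)
class DetectionParams:
    """All tunables of the detection pipeline.

    freq_min, freq_max, freq_step : Hz
        Linear wavelet frequency grid (default 0.25-250 in 0.25 steps).
    wavelet_width : float
        Morlet width in cycles (default 7; sensitivity range 5-9).
    window_len : float
        Nonoverlapping analysis window length in seconds (default 10).
    threshold : float
        Event detection threshold as a multiple of the per-frequency
        median power (default 4).
    merge_overlap : float
        Fraction of the smaller bounding-box area above which two events
        are merged (default 0.5).
    box_growth : str
        "axis" walks the peak row/column (default); "flood" grows the full
        2-D suprathreshold component for sensitivity analysis.
    mirror_pad : bool
        Mirror-pad windows before convolution to suppress edge artifacts
        (default off: plain zero padding).
    """

    freq_min: float = 0.25
    freq_max: float = 250.0
    freq_step: float = 0.25
    wavelet_width: float = 7.0
    window_len: float = 10.0
    threshold: float = 4.0
    merge_overlap: float = 0.5
    box_growth: str = "axis"
    mirror_pad: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.freq_min <= self.freq_max):
            raise ValueError("need 0 < freq_min <= freq_max")
        if self.freq_step <= 0:
            raise ValueError("freq_step must be positive")
        if self.wavelet_width < 3:
            raise ValueError("wavelet_width must be >= 3 cycles")
        if self.threshold <= 1:
            raise ValueError("threshold must exceed 1 (x median)")
        if not (0 < self.merge_overlap < 1):
            raise ValueError("merge_overlap must be in (0, 1)")
        if self.box_growth not in ("axis", "flood"):
            raise ValueError("box_growth must be 'axis' or 'flood'")

    @property
    def freqs(self) -> np.ndarray:
        n = int(round((self.freq_max - self.freq_min) / self.freq_step)) + 1
        return self.freq_min + self.freq_step * np.arange(n)


@dataclass
class Spectrogram:
    """Frequency x time wavelet power with normalization bookkeeping.

    ``power`` has shape (n_freqs, n_times); ``window_index`` maps each time
    column to the analysis window it came from; ``norm_medians`` holds the
    per-frequency medians once :func:`normalize_by_median` has run (power is
    then in multiples of the median).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_index: np.ndarray
    fs: float
    norm_medians: np.ndarray | None = None
    params: DetectionParams = field(default_factory=DetectionParams)

    @property
    def is_normalized(self) -> bool:
        return self.norm_medians is not None

    @property
    def n_windows(self) -> int:
        return int(self.window_index.max()) + 1 if self.window_index.size else 0

    def window_slice(self, w: int) -> slice:
        cols = np.flatnonzero(self.window_index == w)
        return slice(int(cols[0]), int(cols[-1]) + 1)

    def save(self, path) -> None:
        """Persist to the HDF5 layout /power, /freqs, /times, /medians."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power)
            f["freqs"] = self.freqs
            f["times"] = self.times
            f["window_index"] = self.window_index
            f["fs"] = self.fs
            if self.norm_medians is not None:
                f["medians"] = self.norm_medians


from functools import lru_cache


@lru_cache(maxsize=4)
def _cached_bank(fs: float, nfft: int, freq_min: float, freq_step: float,
                 n_freqs: int, width: float) -> np.ndarray:
    freqs = freq_min + freq_step * np.arange(n_freqs)
    return _kernel_bank(fs, nfft, freqs, width)


def _kernel_bank(fs: float, nfft: int, freqs: np.ndarray, width: float) -> np.ndarray:
    """Frequency response of the analytic Morlet at each center frequency.

    H(nu) = 2 exp(-2 pi^2 sigma_t^2 (nu - f0)^2) on the non-negative DFT
    frequencies (the negative half is zero: analytic wavelet). The factor
    2 makes a unit real sinusoid at f0 come out with |coefficient| = 1 at
    every f0, so power is comparable across the grid. Stored as float32:
    only power ratios to the median matter downstream.
    """
    npos = nfft // 2 + 1
    nu = np.arange(npos) * (fs / nfft)
    sigma_t = width / (2.0 * np.pi * freqs)  # envelope width in s
    H = 2.0 * np.exp(
        -2.0 * np.pi**2 * sigma_t[:, None] ** 2 * (nu[None, :] - freqs[:, None]) ** 2
    )
    return H.astype(np.float32)


def _apply_bank(x: np.ndarray, nfft: int, bank: np.ndarray,
                n_keep: int, offset: int = 0) -> np.ndarray:
    """Convolve one padded segment with every wavelet in the bank."""
    npos = nfft // 2 + 1
    Xp = sfft.rfft(x, nfft).astype(np.complex64)
    out = np.empty((bank.shape[0], n_keep), dtype=np.complex64)
    chunk = 128
    for i in range(0, bank.shape[0], chunk):
        Z = np.zeros((min(chunk, bank.shape[0] - i), nfft), dtype=np.complex64)
        Z[:, :npos] = Xp * bank[i : i + chunk]
        out[i : i + chunk] = sfft.ifft(Z, axis=1)[:, offset : offset + n_keep]
    return out


def _morlet_coeffs(x: np.ndarray, fs: float, freqs: np.ndarray, width: float,
                   mirror_pad: bool = False) -> np.ndarray:
    """Complex Morlet coefficients of a 1-D signal at each frequency.

    The signal is zero-padded (or mirror-padded) to at least twice its
    length before the frequency-domain convolution, so the result matches
    a linear convolution with the (effectively compact) wavelet.
    """
    n = x.size
    if mirror_pad:
        x = np.concatenate([x[::-1], x, x[::-1]])
        off = n
    else:
        off = 0
    nfft = sfft.next_fast_len(x.size + n)
    bank = _kernel_bank(fs, nfft, np.asarray(freqs, dtype=float), width)
    return _apply_bank(x, nfft, bank, n, off)


def morlet_power(rec: Recording, channel: int | str = 0,
                 params: DetectionParams | None = None) -> Spectrogram:
    """Wavelet power spectrogram of one channel on nonoverlapping windows.

    Each window of ``params.window_len`` seconds is transformed
    independently; a trailing partial window is dropped. Raises if
    ``freq_max`` is not below the Nyquist frequency or the recording is
    shorter than one window.
    """
    params = params or DetectionParams()
    if params.freq_max >= rec.fs / 2:
        raise ValueError(
            f"freq_max {params.freq_max} Hz >= Nyquist {rec.fs / 2} Hz"
        )
    x = rec.get_channel(channel)
    n_win_samples = int(round(params.window_len * rec.fs))
    n_windows = x.size // n_win_samples
    if n_windows == 0:
        raise ValueError("recording shorter than one analysis window")
    freqs = params.freqs

    pad = 2 * n_win_samples if params.mirror_pad else 0
    nfft = sfft.next_fast_len(2 * n_win_samples + pad)
    bank = _cached_bank(rec.fs, nfft, params.freq_min, params.freq_step,
                        freqs.size, params.wavelet_width)
    blocks = []
    for w in range(n_windows):
        seg = x[w * n_win_samples : (w + 1) * n_win_samples]
        off = 0
        if params.mirror_pad:
            seg = np.concatenate([seg[::-1], seg, seg[::-1]])
            off = n_win_samples
        coeff = _apply_bank(seg, nfft, bank, n_win_samples, off)
        blocks.append(np.abs(coeff) ** 2)  # float32: only ratios matter
    power = np.concatenate(blocks, axis=1)
    n_used = n_windows * n_win_samples
    times = rec.t0 + np.arange(n_used) / rec.fs
    window_index = np.repeat(np.arange(n_windows), n_win_samples)
    return Spectrogram(power=power, freqs=freqs, times=times,
                       window_index=window_index, fs=rec.fs, params=params)


def normalize_by_median(spec: Spectrogram) -> Spectrogram:
    """Divide each frequency row by its median over the whole recording.

    The median pools all time columns across windows, so the same divisor
    applies everywhere; it is stored in ``norm_medians``. Raises on an
    already-normalized input or an all-zero row (undefined normalization).
    """
    if spec.is_normalized:
        raise ValueError("spectrogram already normalized")
    med = np.median(spec.power, axis=1)
    if np.any(med <= 0):
        bad = spec.freqs[np.flatnonzero(med <= 0)[0]]
        raise ValueError(f"zero median power at {bad} Hz; cannot normalize")
    return replace(spec, power=spec.power / med[:, None], norm_medians=med)
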