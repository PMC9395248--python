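"""Recording I/O, channel metadata, and current-source density.

A :class:`Recording` is the in-memory container used throughout the package:
a channels x time array of samples with a sampling rate, channel labels and
units. Supported on-disk formats are CSV (one column per channel, header row
of labels), raw binary float32/float64 with a JSON sidecar, a simple HDF5
layout (``/data`` channels x time, ``/fs``, ``/labels``, ``/units``), and EDF.

Current-source density (CSD) is estimated from laminar LFP as the negative
second spatial difference across equally spaced contacts, so that
depolarizing current sinks come out positive. Edge contacts are dropped
(no padding): analyses target selected interior sink channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "LaminarGeometry",
    "read_recording",
    "write_recording",
    "compute_csd",
    "decimate_recording",
]


@dataclass
class Recording:
    """Sampled multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal values, e.g. LFP in mV or CSD in mV/mm^2.
    fs : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        One label per channel.
    units : str
        Physical units of the samples.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_times / fs)."""
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.fs

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_labels.index(channel)
        return int(channel)

    def get_channel(self, channel: int | str) -> np.ndarray:
        return self.samples[self.channel_index(channel)]


@dataclass(frozen=True)
class LaminarGeometry:
    """Laminar probe geometry: inter-contact spacing, superficial-to-deep order.

    ``spacing_um`` is the physical distance between adjacent contacts in
    micrometres (typical laminar probes: 100-150 um).
    """

    spacing_um: float

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("contact spacing must be positive")

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    units: str = "a.u.",
    n_channels: int | None = None,
    dtype: str = "float32",
) -> Recording:
    """Read a recording from disk.

    ``format`` is one of ``{"csv", "raw", "hdf5", "edf"}``; when omitted it is
    guessed from the file suffix. Headerless formats (csv, raw) require ``fs``;
    raw binary additionally requires ``n_channels`` unless a JSON sidecar
    ``<path>.json`` provides ``fs``/``n_channels``/``dtype``/``units``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _guess_format(path)
    format = format.lower()
    if format == "csv":
        return _read_csv(path, fs, units)
    if format in ("raw", "raw-binary", "bin"):
        return _read_raw(path, fs, units, n_channels, dtype)
    if format in ("hdf5", "h5"):
        return _read_hdf5(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {
        ".csv": "csv",
        ".h5": "hdf5",
        ".hdf5": "hdf5",
        ".edf": "edf",
        ".bin": "raw",
        ".dat": "raw",
        ".raw": "raw",
    }.get(suffix, "raw")


def _read_csv(path: Path, fs: float | None, units: str) -> Recording:
    import pandas as pd

    if fs is None:
        raise ValueError("CSV input requires an explicit sampling rate")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no samples in {path}")
    return Recording(
        samples=df.to_numpy().T,
        fs=fs,
        channel_labels=[str(c) for c in df.columns],
        units=units,
    )


def _read_raw(
    path: Path,
    fs: float | None,
    units: str,
    n_channels: int | None,
    dtype: str,
) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        n_channels = meta.get("n_channels", n_channels)
        dtype = meta.get("dtype", dtype)
        units = meta.get("units", units)
    if fs is None or n_channels is None:
        raise ValueError("raw binary input requires fs and n_channels")
    data = np.fromfile(path, dtype=np.dtype(dtype))
    if data.size == 0:
        raise ValueError(f"no samples in {path}")
    if data.size % n_channels:
        raise ValueError(
            f"{data.size} values do not divide into {n_channels} channels"
        )
    # channel-major layout: all of channel 0, then channel 1, ...
    return Recording(data.reshape(n_channels, -1), fs=fs, units=units)


def _read_hdf5(path: Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        samples = f["data"][()]
        fs = float(f["fs"][()])
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]
        ]
        units = f["units"][()]
        units = units.decode() if isinstance(units, bytes) else str(units)
        t0 = float(f["t0"][()]) if "t0" in f else 0.0
    return Recording(samples, fs=fs, channel_labels=labels, units=units, t0=t0)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        units="V",
    )


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to HDF5 (default) or CSV."""
    import h5py

    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "csv":
        import pandas as pd

        pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
            path, index=False
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.samples)
        f["fs"] = rec.fs
        f["labels"] = [s.encode() for s in rec.channel_labels]
        f["units"] = rec.units.encode()
        f["t0"] = rec.t0


def compute_csd(rec: Recording, geom: LaminarGeometry) -> Recording:
    """Current-source density from a laminar LFP recording.

    CSD_i = -(V_{i-1} - 2 V_i + V_{i+1}) / dz^2 at each interior contact,
    with dz the inter-contact spacing in mm; sinks are positive. The two
    edge contacts are dropped, so the output has n_channels - 2 channels
    labelled after the interior contacts.
    """
    if rec.n_channels < 3:
        raise ValueError("CSD requires at least 3 laminar channels")
    v = rec.samples
    dz2 = geom.spacing_mm**2
    csd = -(v[:-2] - 2.0 * v[1:-1] + v[2:]) / dz2
    return replace(
        rec,
        samples=csd,
        channel_labels=rec.channel_labels[1:-1],
        units=f"{rec.units}/mm^2",
    )


def decimate_recording(rec: Recording, target_fs: float = 1000.0) -> Recording:
    """Resample to the analysis rate with an anti-alias FIR (polyphase).

    Recordings are acquired at rates far above the <=250 Hz analysis range
    (e.g. 44 kHz); wavelet analysis runs at a working rate of 1000 Hz by
    default, at least 4x the maximum analysis frequency. No-op if the
    recording is already at ``target_fs``.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if np.isclose(rec.fs, target_fs):
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return replace(rec, samples=out, fs=target_fs)
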