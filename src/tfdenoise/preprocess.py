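"""Raw-recording handling: CSV I/O, band-pass filtering, decimation, CAR, epoching.

The target recordings are event-related EEG sessions: multi-channel scalp
potentials in microvolts sampled at a fixed rate, with stimulus onsets given as
sample indices.  The standard single-trial preparation applied here is
down-sampling to 250 Hz, zero-phase band-pass filtering to the 2-30 Hz ERP
band, common average re-referencing, and extraction of fixed-length epochs
starting at each stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


class ParseError(ValueError):
    """Raised when a recording file cannot be parsed into a numeric matrix."""


@dataclass
class Recording:
    """A multi-channel time series with sampling rate and event onsets.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Scalp potentials in microvolts; columns are channels.
    fs : float
        Sampling rate in Hz.
    events : list of int
        0-based sample indices of stimulus onsets.
    channel_names : list of str
        One name per column of ``data``.
    """

    data: np.ndarray
    fs: float
    events: list[int] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (samples x channels) matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        n = self.data.shape[0]
        bad = [e for e in self.events if not 0 <= e < n]
        if bad:
            raise ValueError(f"event indices outside [0, {n}): {bad}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length single-channel trials cut after stimulus onsets."""

    trials: np.ndarray  # (n_trials, n_samples)
    fs: float
    channel: str
    duration_s: float

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[0] < 1:
            raise ValueError("EpochSet needs at least one trial")
        expected = int(round(self.fs * self.duration_s))
        if self.trials.shape[1] != expected:
            raise ValueError(
                f"trial length {self.trials.shape[1]} != round(fs*duration)={expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def load_csv(path: str | Path, fs: float, has_header: bool = False) -> Recording:
    """Read a samples x channels CSV matrix into a :class:`Recording`.

    Raises :class:`ParseError` naming the offending 0-based data row when a
    cell is non-numeric or a row has a different column count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=0 if has_header else None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    names = [str(c) for c in df.columns] if has_header else []
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() & df.notna().to_numpy()
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ParseError(f"{path}: non-numeric cell in data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy().any(axis=1))[0, 0])
        raise ParseError(f"{path}: missing cell in data row {row} (ragged rows?)")
    # convert through float() — correctly rounded, unlike pandas' fast parser
    data = np.array([[float(v) for v in row] for row in df.to_numpy()])
    return Recording(data, fs=fs, channel_names=names)


def save_csv(recording: Recording, path: str | Path, header: bool = False) -> None:
    """Write the data matrix with enough digits for a bit-exact round trip."""
    path = Path(path)
    head = ",".join(recording.channel_names) if header else ""
    np.savetxt(path, recording.data, fmt="%.17g", delimiter=",",
               header=head, comments="")


def bandpass(x: np.ndarray, fs: float, low: float, high: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D series.

    A 4th-order Butterworth applied forward-backward (``filtfilt``), so the
    effective magnitude response is the square of the design response and the
    phase (hence ERP component latency) is untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass expects a 1-D series")
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # filtfilt's default edge padding needs a few filter lengths of signal
    padlen = 3 * (2 * order + 1)
    if x.size <= 3 * padlen:
        raise ValueError(f"signal too short ({x.size}) for order-{order} band-pass")
    return sps.sosfiltfilt(sos, x)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased integer decimation from ``fs_in`` to ``fs_out``."""
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    if q == 1:
        return x.copy()
    y = sps.decimate(x, q, ftype="fir", zero_phase=True)
    return y[: x.size * int(fs_out) // int(fs_in)] if y.size else y


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if recording.n_channels < 2:
        raise ValueError("CAR undefined for a single channel")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    return replace(recording, data=data)


def extract_epochs(recording: Recording, channel: str | int,
                   duration_s: float) -> EpochSet:
    """Cut one fixed-length trial per event from a single channel.

    Trial ``i`` holds the half-open window ``[onset_i, onset_i + N)`` with
    ``N = round(fs * duration_s)``.
    """
    if isinstance(channel, str):
        if channel not in recording.channel_names:
            raise KeyError(f"unknown channel {channel!r}")
        idx = recording.channel_names.index(channel)
        name = channel
    else:
        idx = int(channel)
        name = recording.channel_names[idx]
    n = int(round(recording.fs * duration_s))
    bad = [e for e in recording.events if e + n > recording.n_samples]
    if bad:
        raise ValueError(f"epoch window exceeds recording for events {bad}")
    if not recording.events:
        raise ValueError("recording has no events")
    col = recording.data[:, idx]
    trials = np.stack([col[e:e + n] for e in recording.events])
    return EpochSet(trials=trials, fs=recording.fs, channel=name,
                    duration_s=duration_s)


def preprocess_recording(recording: Recording, channel: str | int,
                         fs_out: float = 250.0,
                         band: tuple[float, float] = (2.0, 30.0),
                         duration_s: float = 1.0) -> EpochSet:
    """Standard single-trial preparation in one call.

    Fixed order: downsample -> band-pass -> common average reference ->
    epoch extraction.  Event indices are rescaled to the output rate.
    """
    q = recording.fs / fs_out
    data = np.column_stack([downsample(recording.data[:, c], recording.fs,
                                       fs_out)
                            for c in range(recording.n_channels)])
    data = np.column_stack([bandpass(data[:, c], fs_out, *band)
                            for c in range(data.shape[1])])
    events = [int(e / q) for e in recording.events]
    rec = Recording(data, fs=fs_out, events=events,
                    channel_names=recording.channel_names)
    if rec.n_channels >= 2:
        rec = common_average_reference(rec)
    return extract_epochs(rec, channel, duration_s)


def load_edf(path: str | Path, events: list[int] | None = None) -> Recording:
    """Optional EDF reader behind the same :class:`Recording` contract.

    Requires ``mne``; not needed for the core pipeline.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return Recording(data, fs=float(raw.info["sfreq"]),
                     events=list(events or []),
                     channel_names=list(raw.ch_names))
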