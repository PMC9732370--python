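"""Short-time Fourier transform round trip for single trials.

A 1-D trial x(t) is mapped to a complex time-frequency matrix X(t, f) that the
rest of the pipeline treats as an image, and back.  Analysis/synthesis is
delegated to :class:`scipy.signal.ShortTimeFFT`, whose canonical dual-window
inversion is exact (to rounding) whenever the window/hop pair is invertible;
non-invertible configs are rejected when the config is built, never silently.
Frame k is centred at sample ``k * hop``; the signal is implicitly
zero-extended at both edges so every sample, including the first, carries
synthesis weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

_WINDOWS = ("hann", "hamming")


@dataclass(frozen=True)
class StftConfig:
    """STFT analysis parameters.

    Defaults — Hann window of 64 samples (256 ms at 250 Hz), hop 16 (75 %
    overlap), one-sided 64-point FFT — give ~3.9 Hz resolution: the 2-30 Hz
    ERP band occupies ~8 informative rows and the whole image stays small
    enough for full-image non-local means.
    """

    window_length: int = 64
    hop: int = 16
    window_shape: str = "hann"
    fft_length: int = 64
    one_sided: bool = True

    def __post_init__(self) -> None:
        if self.window_shape not in _WINDOWS:
            raise ValueError(f"window_shape must be one of {_WINDOWS}")
        if not 1 <= self.hop <= self.window_length:
            raise ValueError("need 1 <= hop <= window_length")
        if self.fft_length < self.window_length:
            raise ValueError("fft_length must be >= window_length")
        if not self._sfft().invertible:
            raise ValueError(
                f"window/hop pair ({self.window_shape}, {self.window_length}, "
                f"{self.hop}) does not satisfy the overlap-add condition for "
                "exact inversion"
            )

    def window(self) -> np.ndarray:
        return get_window(self.window_shape, self.window_length, fftbins=True)

    def _sfft(self, fs: float = 1.0) -> ShortTimeFFT:
        return ShortTimeFFT(
            self.window(), hop=self.hop, fs=fs,
            mfft=self.fft_length,
            fft_mode="onesided" if self.one_sided else "twosided",
        )


@dataclass
class TFR:
    """Complex time-frequency matrix with axis metadata.

    ``values[r, k]`` is the complex amplitude at frequency ``freqs[r]`` in the
    frame centred at ``frame_times[k]`` seconds.  ``original_length`` is kept
    so the inverse transform can truncate exactly.
    """

    values: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray
    config: StftConfig
    fs: float
    original_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (len(self.freqs), len(self.frame_times)):
            raise ValueError("values shape inconsistent with axis metadata")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


def stft(x: np.ndarray, config: StftConfig = StftConfig(),
         fs: float = 250.0) -> TFR:
    """Forward STFT of a 1-D trial."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stft expects a 1-D series")
    if x.size < config.window_length:
        raise ValueError(
            f"signal length {x.size} shorter than one window "
            f"({config.window_length})"
        )
    sfft = config._sfft(fs)
    values = sfft.stft(x)
    freqs = np.asarray(sfft.f, dtype=float)
    times = np.asarray(sfft.t(x.size), dtype=float)
    return TFR(values=values, freqs=freqs, frame_times=times,
               config=config, fs=fs, original_length=x.size)


def istft(tfr: TFR) -> np.ndarray:
    """Inverse STFT, truncated to the original signal length."""
    sfft = tfr.config._sfft(tfr.fs)
    x = sfft.istft(tfr.values, k1=tfr.original_length)
    return np.asarray(x[: tfr.original_length], dtype=float)


def split_mag_phase(tfr: TFR) -> tuple[np.ndarray, np.ndarray]:
    """Polar decomposition of the complex matrix: (|X|, arg X)."""
    return tfr.magnitude, tfr.phase


def combine_mag_phase(mag: np.ndarray, phase: np.ndarray,
                      template: TFR) -> TFR:
    """Rebuild a TFR from magnitude and phase using ``template``'s metadata."""
    mag = np.asarray(mag, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if mag.shape != phase.shape or mag.shape != template.values.shape:
        raise ValueError("magnitude/phase shapes do not match the template")
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    return TFR(values=mag * np.exp(1j * phase), freqs=template.freqs,
               frame_times=template.frame_times, config=template.config,
               fs=template.fs, original_length=template.original_length)


def export_csv(tfr: TFR, stem: str | Path) -> None:
    """Debug dump: `<stem>_real.csv`, `<stem>_imag.csv` + a JSON sidecar."""
    stem = Path(stem)
    np.savetxt(stem.with_name(stem.name + "_real.csv"), tfr.values.real,
               fmt="%.17g", delimiter=",")
    np.savetxt(stem.with_name(stem.name + "_imag.csv"), tfr.values.imag,
               fmt="%.17g", delimiter=",")
    meta = {
        "freqs_hz": tfr.freqs.tolist(),
        "frame_times_s": tfr.frame_times.tolist(),
        "fs": tfr.fs,
        "original_length": tfr.original_length,
        "config": {
            "window_length": tfr.config.window_length,
            "hop": tfr.config.hop,
            "window_shape": tfr.config.window_shape,
            "fft_length": tfr.config.fft_length,
            "one_sided": tfr.config.one_sided,
        },
    }
    stem.with_name(stem.name + "_meta.json").write_text(
        json.dumps(meta, indent=2))
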