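"""Seeded generator of multi-trial single-channel ERP data.

Emulates an event-related visual target-detection session: each 1-s trial at
250 Hz contains stimulus-locked Gaussian-shaped components — an N1-like
negativity near 150 ms and a P3-like positivity near 350 ms — whose latency
and amplitude jitter independently from trial to trial, buried in structured
background noise (pink 1/f EEG background, a 10 Hz alpha oscillation with
random phase, and band-passed 30-120 Hz white noise standing in for muscle
activity).  The noise of every trial is rescaled so the realised SNR,
10*log10(||clean||^2 / ||noise||^2) over the epoch, matches the configured
target exactly.  The default block size of 56 trials matches a typical
target-image block.

The across-trial mean of the *jittered* clean components differs from the
jitter-free template: latency jitter smears the average, exactly the
single-trial information the denoising methods are meant to preserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class Component:
    """One Gaussian-windowed ERP deflection."""

    polarity: int  # +1 or -1
    peak_time_s: float
    width_s: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if not self.width_s > 0:
            raise ValueError("width_s must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Relative amplitudes of the three structured noise sources."""

    pink_exponent: float = 1.0
    alpha_freq_hz: float = 10.0
    alpha_amp: float = 1.0
    emg_band_hz: tuple[float, float] = (30.0, 120.0)
    emg_amp: float = 1.0
    pink_amp: float = 1.0


_DEFAULT_COMPONENTS = (
    Component(polarity=-1, peak_time_s=0.15, width_s=0.03, amplitude_uv=5.0),
    Component(polarity=+1, peak_time_s=0.35, width_s=0.06, amplitude_uv=10.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated block."""

    fs: float = 250.0
    duration_s: float = 1.0
    n_trials: int = 56
    components: tuple[Component, ...] = _DEFAULT_COMPONENTS
    latency_jitter_sd_s: float = 0.02
    amplitude_jitter_cv: float = 0.15
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    target_snr_db: float = -5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class SimOutput:
    """Generated trials plus the ground truth they were built from."""

    trials: np.ndarray           # (n_trials, N) clean + noise
    clean_per_trial: np.ndarray  # (n_trials, N) jittered component sums
    template: np.ndarray         # (N,) jitter-free component sum
    realized_snr_db: np.ndarray  # (n_trials,)
    config: SimConfig


def _component_waveform(comp: Component, t: np.ndarray, peak_shift: float,
                        amp_scale: float) -> np.ndarray:
    amp = comp.amplitude_uv * amp_scale * comp.polarity
    peak = comp.peak_time_s + peak_shift
    return amp * np.exp(-0.5 * ((t - peak) / comp.width_s) ** 2)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _emg_noise(rng: np.random.Generator, n: int, fs: float,
               band: tuple[float, float]) -> np.ndarray:
    """Band-passed white noise emulating broadband muscle activity."""
    low, high = band
    high = min(high, 0.999 * fs / 2)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.normal(size=n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _noise_epoch(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """One unscaled structured-noise epoch (mix of the three sources)."""
    nz = cfg.noise
    n, fs = cfg.n_samples, cfg.fs
    t = np.arange(n) / fs
    out = np.zeros(n)
    if nz.pink_amp > 0:
        out = out + nz.pink_amp * _pink_noise(rng, n, nz.pink_exponent)
    if nz.alpha_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out + nz.alpha_amp * np.sin(2 * np.pi * nz.alpha_freq_hz * t
                                          + phase)
    if nz.emg_amp > 0:
        out = out + nz.emg_amp * _emg_noise(rng, n, fs, nz.emg_band_hz)
    return out


def template(config: SimConfig) -> np.ndarray:
    """Jitter-free sum of the configured components."""
    t = np.arange(config.n_samples) / config.fs
    out = np.zeros(config.n_samples)
    for comp in config.components:
        out += _component_waveform(comp, t, 0.0, 1.0)
    return out


def generate(config: SimConfig = SimConfig()) -> SimOutput:
    """Generate one block of trials; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    n, fs = config.n_samples, config.fs
    t = np.arange(n) / fs
    clean = np.zeros((config.n_trials, n))
    noise = np.zeros((config.n_trials, n))
    snr = np.zeros(config.n_trials)
    for i in range(config.n_trials):
        shift = rng.normal(0.0, config.latency_jitter_sd_s)
        for comp in config.components:
            scale = max(0.0, rng.normal(1.0, config.amplitude_jitter_cv))
            clean[i] += _component_waveform(comp, t, shift, scale)
        eps = _noise_epoch(rng, config)
        p_noise = float(np.sum(eps * eps))
        p_clean = float(np.sum(clean[i] * clean[i]))
        if p_noise > 0 and p_clean > 0:
            target = 10.0 ** (config.target_snr_db / 10.0)
            eps = eps * np.sqrt(p_clean / (target * p_noise))
            snr[i] = 10.0 * np.log10(p_clean / np.sum(eps * eps))
        elif p_noise == 0:
            snr[i] = np.inf
        else:
            snr[i] = -np.inf
        noise[i] = eps
    return SimOutput(trials=clean + noise, clean_per_trial=clean,
                     template=template(config), realized_snr_db=snr,
                     config=config)


def generate_multichannel(config: SimConfig = SimConfig(),
                          gains: tuple[float, ...] = (1.0, 0.8, 0.6)
                          ) -> np.ndarray:
    """(n_samples, n_channels) matrix: scaled template + independent noise.

    A minimal multi-channel surrogate for exercising re-referencing: every
    channel carries the same jitter-free template at a different gain plus
    its own structured noise at the configured SNR.
    """
    rng = np.random.default_rng(config.seed)
    tpl = template(config)
    p_clean = float(np.sum(tpl * tpl))
    target = 10.0 ** (config.target_snr_db / 10.0)
    cols = []
    for gain in gains:
        eps = _noise_epoch(rng, config)
        p_noise = float(np.sum(eps * eps))
        if p_noise > 0 and p_clean > 0:
            eps = eps * gain * np.sqrt(p_clean / (target * p_noise))
        cols.append(gain * tpl + eps)
    return np.column_stack(cols)


def reference_from_trials(trials: np.ndarray) -> np.ndarray:
    """Across-trial average — the benchmark's reference signal."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 1 or trials.size == 0:
        raise ValueError("need at least one trial")
    return trials.mean(axis=0)
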