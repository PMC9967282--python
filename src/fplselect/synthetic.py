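"""Synthetic data with known ground truth.

Two generators cover the two entry points of the pipeline:

- :func:`make_tabular` produces a planted-feature classification table: a
  known subset of columns carries a class-conditional Gaussian mean shift,
  optional "redundant" columns are noisy copies of informative ones (mimicking
  the near-duplicate signals of adjacent electrodes), and the rest is pure
  noise.  Selection quality can then be measured as overlap with the planted
  set.
- :func:`make_segments` produces EEG-like multichannel segments in the
  3-second, 128-Hz, 30-channel geometry: per-band sinusoids with jittered
  frequency and phase, scaled by class-dependent amplitude multipliers
  (drowsy segments get stronger theta, alert segments stronger beta), on top
  of 1/f (pink) background noise shared across channels to a configurable
  degree.

Both generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DEFAULT_CHANNELS, EEGSegmentSet, FeatureMatrix

__all__ = ["TabularSpec", "SignalSpec", "make_tabular", "make_segments"]


@dataclass
class TabularSpec:
    n_samples: int = 2000
    d0: int = 100
    k_informative: int = 10
    effect_size: float = 2.0      # standardized class-mean shift
    n_redundant: int = 0
    noise_sd: float = 0.3         # noise added to redundant copies
    class_balance: float = 0.5    # fraction of class-1 samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative + self.n_redundant > self.d0:
            raise ValueError("k_informative + n_redundant must be <= d0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")


def make_tabular(spec: TabularSpec) -> tuple[FeatureMatrix, list[int]]:
    """Planted-feature table; returns the matrix and planted column indices.

    Informative columns are N(0,1) for class 0 and N(effect_size,1) for
    class 1; redundant columns are noisy copies of informative ones; the
    remainder is N(0,1) noise.  Column positions are randomised so selectors
    cannot benefit from ordering.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_samples * spec.class_balance))
    y = np.zeros(spec.n_samples, dtype=int)
    y[rng.choice(spec.n_samples, size=n1, replace=False)] = 1

    X = rng.normal(size=(spec.n_samples, spec.d0))
    positions = rng.permutation(spec.d0)
    informative = positions[:spec.k_informative]
    redundant = positions[spec.k_informative:
                          spec.k_informative + spec.n_redundant]
    X[:, informative] += spec.effect_size * y[:, None]
    for j, col in enumerate(redundant):
        src = informative[j % spec.k_informative]
        X[:, col] = X[:, src] + spec.noise_sd * rng.normal(size=spec.n_samples)

    names = [f"f{i:03d}" for i in range(spec.d0)]
    return FeatureMatrix(X, names, y), sorted(int(i) for i in informative)


@dataclass
class SignalSpec:
    n_segments: int = 240
    n_channels: int = 30
    fs: float = 128.0
    duration: float = 3.0
    band_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "theta": 1.0, "alpha": 1.0, "beta": 0.7})
    drowsy_multipliers: dict[str, float] = field(default_factory=lambda: {
        "theta": 1.8})
    alert_multipliers: dict[str, float] = field(default_factory=lambda: {
        "beta": 1.4})
    pink_noise_level: float = 1.0
    channel_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.band_amplitudes, self.drowsy_multipliers,
                  self.alert_multipliers):
            if any(v <= 0 for v in d.values()):
                raise ValueError("amplitudes and multipliers must be > 0")
        if not 0.0 <= self.channel_corr <= 1.0:
            raise ValueError("channel_corr must be in [0, 1]")


_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_segments(spec: SignalSpec) -> EEGSegmentSet:
    """EEG-like segment stack with class-dependent band amplitudes."""
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.fs * spec.duration))
    t = np.arange(n_t) / spec.fs
    labels = np.zeros(spec.n_segments, dtype=int)
    labels[1::2] = 1  # alternating, balanced
    data = np.zeros((spec.n_segments, spec.n_channels, n_t))

    rho = spec.channel_corr
    for s in range(spec.n_segments):
        mult = (spec.drowsy_multipliers if labels[s] == 1
                else spec.alert_multipliers)
        for band, (lo, hi) in _BAND_EDGES.items():
            base = spec.band_amplitudes.get(band, 0.0)
            if base <= 0:
                continue
            amp = base * mult.get(band, 1.0)
            freq = rng.uniform(lo, hi - 0.5)
            phase = rng.uniform(0, 2 * np.pi)
            for c in range(spec.n_channels):
                ph_jit = phase + 0.2 * rng.normal()
                amp_jit = amp * (1.0 + 0.1 * rng.normal())
                data[s, c] += amp_jit * np.sin(2 * np.pi * freq * t + ph_jit)
        common = _pink_noise(rng, n_t)
        for c in range(spec.n_channels):
            own = _pink_noise(rng, n_t)
            noise = np.sqrt(rho) * common + np.sqrt(1 - rho) * own
            data[s, c] += spec.pink_noise_level * noise

    if spec.n_channels == len(DEFAULT_CHANNELS):
        channels = list(DEFAULT_CHANNELS)
    else:
        channels = [f"CH{i + 1:02d}" for i in range(spec.n_channels)]
    return EEGSegmentSet(data=data, fs=spec.fs, channel_labels=channels,
                         labels=labels, segment_duration=spec.duration)
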