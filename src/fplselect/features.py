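"""Frequency-domain EEG features: Welch band powers and band-power ratios.

Each fixed-length EEG segment is reduced, per channel, to ten numbers: the
theta (4-8 Hz), alpha (8-12 Hz) and beta (12-30 Hz) band powers estimated
from a Welch power spectral density, plus seven ratios between those powers
that are standard drowsiness indicators.  Channel-group columns (frontal,
temporal, all) are the arithmetic means of the member channels' feature
values.  With the default 30-channel montage and the three default groups
this yields a 330-column feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "BandSet",
    "ChannelGroups",
    "EEGSegmentSet",
    "FeatureMatrix",
    "DEFAULT_CHANNELS",
    "PER_CHANNEL_FEATURES",
    "welch_psd",
    "band_power",
    "ratio_features",
    "extract_features",
]

#: The 32 cap electrodes of the sustained-attention driving montage, with the
#: two reference electrodes (A1, A2) removed: 30 signal channels.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Order of the ten per-channel (and per-group) features.
PER_CHANNEL_FEATURES: tuple[str, ...] = (
    "alpha_psd",
    "beta_psd",
    "theta_psd",
    "theta_alpha_over_beta",
    "alpha_over_beta",
    "theta_alpha_over_alpha_beta",
    "theta_over_beta",
    "theta_over_theta_alpha",
    "alpha_over_theta_alpha",
    "theta_alpha_over_theta_beta",
)

_EPS = 1e-12  # guard added to ratio denominators; silent channels stay finite


@dataclass
class BandSet:
    """Named frequency intervals in Hz, half-open ``[lo, hi)``."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    beta: tuple[float, float] = (12.0, 30.0)

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        items = [("theta", self.theta), ("alpha", self.alpha), ("beta", self.beta)]
        for name, (lo, hi) in items:
            if not 0 <= lo < hi:
                raise ValueError(f"band {name!r}: need 0 <= lo < hi, got [{lo}, {hi})")
            if hi > nyq + 1e-9:
                raise ValueError(f"band {name!r} upper edge {hi} exceeds Nyquist {nyq}")
        for (n1, b1), (n2, b2) in zip(items, items[1:]):
            if b1[1] > b2[0]:
                raise ValueError(f"bands {n1!r} and {n2!r} overlap or are unordered")


@dataclass
class ChannelGroups:
    """Mapping from group name to member channel labels.

    The default frontal/temporal memberships follow montage convention; "all"
    expands to every channel of the segment set.
    """

    groups: dict[str, list[str]] = field(default_factory=lambda: {
        "frontal": ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"],
        "temporal": ["FT7", "FT8", "T3", "T4", "TP7", "TP8", "T5", "T6"],
        "all": [],  # empty = every channel
    })

    def resolve(self, channel_labels: list[str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, members in self.groups.items():
            if not members:
                out[name] = list(channel_labels)
                continue
            for ch in members:
                if ch not in channel_labels:
                    raise ValueError(
                        f"group {name!r} references unknown channel {ch!r}"
                    )
            out[name] = list(members)
        return out


@dataclass
class EEGSegmentSet:
    """A stack of fixed-length multichannel EEG segments.

    data has shape ``(n_segments, n_channels, n_timepoints)`` in microvolts;
    labels are binary (0 = alert, 1 = drowsy).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    labels: np.ndarray
    segment_duration: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_segments, n_channels, n_timepoints)")
        n_seg, n_ch, n_t = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length must match n_channels")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel_labels must be unique")
        if len(self.labels) != n_seg:
            raise ValueError("labels length must match n_segments")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        expected = int(round(self.fs * self.segment_duration))
        if n_t != expected:
            raise ValueError(
                f"n_timepoints {n_t} != fs*duration = {expected}"
            )


class FeatureMatrix:
    """Samples x named-features table with binary labels."""

    def __init__(self, values: np.ndarray, feature_names: list[str],
                 labels: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.feature_names = list(feature_names)
        self.labels = np.asarray(labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match n_features")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must match n_samples")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite (no NaN/Inf)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset (by name), preserving the requested order."""
        idx = self.indices_of(names)
        return FeatureMatrix(self.values[:, idx], list(names), self.labels)

    def indices_of(self, names: list[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown feature name(s): {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def take_rows(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[rows], self.feature_names,
                             self.labels[rows])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       label_column: str = "label") -> "FeatureMatrix":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        feats = df.drop(columns=[label_column])
        return cls(feats.to_numpy(dtype=float), list(feats.columns), labels)

    @classmethod
    def from_csv(cls, path, label_column: str = "label") -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path), label_column)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"FeatureMatrix(n_samples={self.n_samples}, "
                f"n_features={self.n_features})")


def welch_psd(x: np.ndarray, fs: float,
              window_seconds: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann-tapered, non-overlapping windows.

    With ``window_seconds`` equal to the segment duration this reduces to a
    single tapered periodogram, which is the configuration used for 3-s
    segments analysed with a 3-s window.
    """
    x = np.asarray(x, dtype=float)
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    nperseg = int(round(fs * window_seconds))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of length {x.shape[-1]} is shorter than one window; "
            f"need at least {nperseg} samples (fs*window_seconds)"
        )
    freqs, psd = _signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=0, detrend="constant",
                               scaling="density")
    return freqs, psd


def band_power(frequencies: np.ndarray, psd: np.ndarray,
               band: tuple[float, float]) -> float:
    """Integrated PSD over a half-open band ``[lo, hi)`` of bin centers."""
    frequencies = np.asarray(frequencies, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = band
    sel = (frequencies >= lo) & (frequencies < hi)
    if not sel.any():
        raise ValueError(f"band [{lo}, {hi}) contains no frequency bins")
    df = frequencies[1] - frequencies[0]
    return float(np.sum(psd[..., sel], axis=-1) * df)


def ratio_features(theta: float, alpha: float, beta: float) -> dict[str, float]:
    """The seven standard band-power ratios, epsilon-guarded."""
    if min(theta, alpha, beta) < 0:
        raise ValueError("band powers must be non-negative")
    ta = theta + alpha
    return {
        "theta_alpha_over_beta": ta / (beta + _EPS),
        "alpha_over_beta": alpha / (beta + _EPS),
        "theta_alpha_over_alpha_beta": ta / (alpha + beta + _EPS),
        "theta_over_beta": theta / (beta + _EPS),
        "theta_over_theta_alpha": theta / (ta + _EPS),
        "alpha_over_theta_alpha": alpha / (ta + _EPS),
        "theta_alpha_over_theta_beta": ta / (theta + beta + _EPS),
    }


def _channel_features(x: np.ndarray, fs: float, window_seconds: float,
                      bands: BandSet, relative: bool) -> np.ndarray:
    freqs, psd = welch_psd(x, fs, window_seconds)
    theta = band_power(freqs, psd, bands.theta)
    alpha = band_power(freqs, psd, bands.alpha)
    beta = band_power(freqs, psd, bands.beta)
    if relative:
        df = freqs[1] - freqs[0]
        total = float(np.sum(psd) * df) + _EPS
        a_feat, b_feat, t_feat = alpha / total, beta / total, theta / total
    else:
        a_feat, b_feat, t_feat = alpha, beta, theta
    ratios = ratio_features(theta, alpha, beta)
    return np.array([a_feat, b_feat, t_feat] + list(ratios.values()))


def extract_features(segments: EEGSegmentSet,
                     bands: BandSet | None = None,
                     groups: ChannelGroups | None = None,
                     window_seconds: float | None = None,
                     relative: bool = False) -> FeatureMatrix:
    """Build the per-channel + per-group feature table from raw segments.

    Parameters
    ----------
    segments
        The raw segment stack.
    bands
        Frequency bands; defaults to theta/alpha/beta.
    groups
        Channel groups whose feature values are averaged over members;
        defaults to frontal/temporal/all.  Pass ``ChannelGroups({})`` for no
        group columns.
    window_seconds
        Welch window length; defaults to the full segment duration.
    relative
        If True, band-power columns are normalised by total power (the seven
        ratios are unaffected, being scale-invariant).
    """
    bands = bands if bands is not None else BandSet()
    groups = groups if groups is not None else ChannelGroups()
    if window_seconds is None:
        window_seconds = segments.segment_duration
    bands.validate(segments.fs)
    resolved = groups.resolve(segments.channel_labels)

    n_seg, n_ch, _ = segments.data.shape
    per_channel = np.empty((n_seg, n_ch, len(PER_CHANNEL_FEATURES)))
    for s in range(n_seg):
        for c in range(n_ch):
            per_channel[s, c] = _channel_features(
                segments.data[s, c], segments.fs, window_seconds, bands,
                relative)

    blocks = [per_channel[:, c, :] for c in range(n_ch)]
    names = [f"{ch}__{f}" for ch in segments.channel_labels
             for f in PER_CHANNEL_FEATURES]
    ch_index = {ch: i for i, ch in enumerate(segments.channel_labels)}
    for gname, members in resolved.items():
        idx = [ch_index[ch] for ch in members]
        blocks.append(per_channel[:, idx, :].mean(axis=1))
        names.extend(f"{gname}__{f}" for f in PER_CHANNEL_FEATURES)

    values = np.concatenate([b.reshape(n_seg, -1) for b in blocks], axis=1)
    if not np.isfinite(values).all():  # pragma: no cover - guarded upstream
        warnings.warn("non-finite feature values produced; check input data")
    return FeatureMatrix(values, names, segments.labels)
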