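"""Synthetic EEG fixtures with the statistical structure the scheme assumes.

Two generators:

* :func:`generate_raw` — multichannel "recordings" built as sums of
  band-limited sinusoids (random frequency and phase inside each band) plus
  white Gaussian noise.  Classes differ by amplitude multipliers on chosen
  bands and channel subsets, so class information lives exactly where the
  feature pipeline looks: in per-band power.  This is deliberately
  non-physiological EEG — no 1/f background, artifacts or nonstationarity —
  but it exercises every stage of the pipeline.
* :func:`generate_feature_dataset` — ready-made 5-band feature matrices in
  the 62-channel convention (contiguous 100-row blocks for delta, theta,
  alpha, beta, gamma), with class-dependent mean shifts in designated band
  blocks.

Both are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DEFAULT_BANDS, FeatureMatrix, SignalRecord
from .train import LabeledDataset

__all__ = ["SyntheticConfig", "FeatureSyntheticConfig", "generate_raw",
           "generate_feature_dataset", "separable_2class_config",
           "noisy_2class_config", "FIVE_BANDS"]

#: 5-band layout of SEED-IV-style feature matrices.
FIVE_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass
class SyntheticConfig:
    """Raw-signal generator settings.

    ``class_profiles[c]`` maps a band name to ``(amplitude_multiplier,
    channel_indices)``; unlisted bands keep the base amplitude on every
    channel.  Defaults emulate 60-second 14-channel trials at 128 Hz.
    """
    n_subjects: int = 1
    trials_per_class: int = 20
    n_channels: int = 14
    fs: float = 128.0
    duration: float = 60.0
    n_classes: int = 2
    base_amplitude: float = 1.0
    class_profiles: dict = field(default_factory=dict)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.duration < 1.0:
            raise ValueError("duration must be at least 1 s")
        if self.n_channels < 1 or self.n_classes < 2:
            raise ValueError("need >= 1 channel and >= 2 classes")
        band_names = {b[0] for b in DEFAULT_BANDS}
        for cls, profile in self.class_profiles.items():
            for band, (amp, chans) in profile.items():
                if band not in band_names:
                    raise ValueError(f"unknown band {band!r}")
                if amp <= 0:
                    raise ValueError("amplitude multipliers must be positive")
                if any(ch >= self.n_channels or ch < 0 for ch in chans):
                    raise ValueError("channel subset out of range")


def separable_2class_config(seed: int = 7, duration: float = 6.0) -> SyntheticConfig:
    """The end-to-end benchmark dataset: 2 classes, 14 channels, 20
    trials/class, 3x beta-band amplitude on channels 0-3 for class 1, noise
    sd 0.3.  Short 6-s trials keep the benchmark desk-sized."""
    return SyntheticConfig(
        trials_per_class=20, n_channels=14, fs=128.0, duration=duration,
        n_classes=2, noise_sd=0.3, seed=seed,
        class_profiles={1: {"beta": (3.0, (0, 1, 2, 3))}})


def noisy_2class_config(seed: int = 7) -> SyntheticConfig:
    """A harder variant for regularization studies: weaker contrast (1.5x
    beta), heavier noise (sd 1.5) and fewer trials (10/class)."""
    return SyntheticConfig(
        trials_per_class=10, n_channels=14, fs=128.0, duration=6.0,
        n_classes=2, noise_sd=1.5, seed=seed,
        class_profiles={1: {"beta": (1.5, (0, 1, 2, 3))}})


def generate_raw(cfg: SyntheticConfig) -> list[tuple[SignalRecord, int, int]]:
    """Deterministic list of (record, label, subject_id) trials.

    Each channel carries one sinusoid per band (frequency uniform inside the
    band, random phase) at the class-dependent amplitude, plus white noise.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(int(round(cfg.fs * cfg.duration))) / cfg.fs
    channel_names = [f"CH{i}" for i in range(cfg.n_channels)]
    trials = []
    for subject in range(cfg.n_subjects):
        for label in range(cfg.n_classes):
            profile = cfg.class_profiles.get(label, {})
            for _ in range(cfg.trials_per_class):
                data = np.zeros((cfg.n_channels, t.size))
                for band_name, lo, hi in DEFAULT_BANDS:
                    freqs = rng.uniform(lo, hi, cfg.n_channels)
                    phases = rng.uniform(0, 2 * np.pi, cfg.n_channels)
                    amps = np.full(cfg.n_channels, cfg.base_amplitude)
                    if band_name in profile:
                        mult, chans = profile[band_name]
                        amps[list(chans)] *= mult
                    data += amps[:, None] * np.sin(
                        2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
                data += rng.normal(0.0, cfg.noise_sd, data.shape)
                trials.append((SignalRecord(data, cfg.fs, channel_names),
                               label, subject))
    return trials


@dataclass
class FeatureSyntheticConfig:
    """Settings for ready-made 5-band feature matrices (SEED-IV shape:
    5 bands x 100 features x 62 channels by default)."""
    n_subjects: int = 1
    trials_per_class: int = 20
    n_channels: int = 62
    n_per_band: int = 100
    n_classes: int = 2
    effect_size: float = 1.0
    effect_band: str = "beta"
    effect_channels: tuple | None = None   # default: first min(8, m) channels
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_channels is None:
            self.effect_channels = tuple(range(min(8, self.n_channels)))
        if self.effect_band not in FIVE_BANDS:
            raise ValueError(f"effect_band must be one of {FIVE_BANDS}")
        if any(ch >= self.n_channels for ch in self.effect_channels):
            raise ValueError("effect channel out of range")


def generate_feature_dataset(cfg: FeatureSyntheticConfig) -> LabeledDataset:
    """Gaussian feature matrices with a class-1 mean shift confined to the
    ``effect_band`` block on ``effect_channels``; contiguous band blocks in
    delta..gamma order."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_band * len(FIVE_BANDS)
    channel_names = [f"CH{i}" for i in range(cfg.n_channels)]
    layout = [(band, "de", w)
              for band in FIVE_BANDS for w in range(cfg.n_per_band)]
    band_start = {b: i * cfg.n_per_band for i, b in enumerate(FIVE_BANDS)}

    samples, labels, subjects = [], [], []
    for subject in range(cfg.n_subjects):
        for label in range(cfg.n_classes):
            for _ in range(cfg.trials_per_class):
                values = rng.normal(0.0, cfg.noise_sd, (n, cfg.n_channels))
                if label == 1 and cfg.effect_size != 0.0:
                    s = band_start[cfg.effect_band]
                    rows = slice(s, s + cfg.n_per_band)
                    values[rows, list(cfg.effect_channels)] += cfg.effect_size
                samples.append(FeatureMatrix(values, list(layout),
                                             list(channel_names)))
                labels.append(label)
                subjects.append(subject)
    return LabeledDataset(samples, np.array(labels), np.array(subjects),
                          dimension="discrete")
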