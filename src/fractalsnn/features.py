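"""EEG preprocessing and temporal-spectral-spatial (TSS) feature extraction.

Raw multichannel EEG is bandpass-filtered (zero-phase 4th-order Butterworth),
z-scored per channel, cut into overlapping windows, and summarised per window
and frequency band by two classical features:

* **PSD** — mean periodogram power (Hann taper) inside the band, and
* **DE** — differential entropy under a Gaussian assumption,
  ``0.5 * ln(2*pi*e*var)`` with ``var`` the variance of the band-filtered
  window (the convention of the SEED feature lineage).

Per channel, windows are concatenated band by band (default order theta,
alpha, beta, gamma; PSD rows before DE rows inside each band), yielding a
feature matrix ``X in R^{n x m}`` whose columns are EEG channels.  That matrix
is the working representation for the rest of the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SignalRecord", "BandSpec", "FeatureMatrix", "DEFAULT_BANDS",
    "preprocess", "segment", "band_features", "assemble_feature_matrix",
    "extract_features", "read_signal", "write_signal",
]

#: Frequency bands used for the 4-band layout (Hz).
DEFAULT_BANDS = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 30.0),
    ("gamma", 30.0, 45.0),
)

#: Differential entropy floor for zero-variance windows (nats).
DE_FLOOR = -20.0


class DegenerateInputError(ValueError):
    """Raised for inputs the pipeline cannot meaningfully process."""


@dataclass
class BandSpec:
    """A frequency band ``[lo, hi]`` in Hz."""
    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo < hi, "
                             f"got ({self.lo}, {self.hi})")
        if self.hi >= fs / 2:
            raise ValueError(f"band {self.name}: hi={self.hi} Hz >= Nyquist "
                             f"({fs / 2} Hz)")


@dataclass
class SignalRecord:
    """Multichannel EEG: ``data`` is (channels x samples) at rate ``fs``."""
    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count does not match channel_names")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def last_seconds(self, seconds: float) -> "SignalRecord":
        """Keep only the trailing ``seconds`` of the record."""
        n = int(round(seconds * self.fs))
        if n >= self.n_samples:
            return self
        return SignalRecord(self.data[:, -n:], self.fs, list(self.channel_names))


@dataclass
class FeatureMatrix:
    """TSS feature matrix: ``values`` is (n features x m channels).

    ``layout`` describes each row as ``(band, feature_kind, window_index)``;
    band blocks are contiguous in the configured band order.
    """
    values: np.ndarray
    layout: list[tuple[str, str, int]]
    channel_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.layout) != self.values.shape[0]:
            raise ValueError("layout length must equal row count")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must equal column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def band_rows(self, band: str) -> np.ndarray:
        """Row indices belonging to ``band``."""
        return np.array([i for i, (b, _, _) in enumerate(self.layout) if b == band])

    # -- disk round-trip (bit-exact) ------------------------------------

    def save(self, path: str | Path) -> None:
        """Write to an HDF5 container; float64 values round-trip bit-exactly."""
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            lay = np.array([f"{b}\t{k}\t{w}" for b, k, w in self.layout],
                           dtype=h5py.string_dtype())
            f.create_dataset("layout", data=lay)
            f.create_dataset("channel_names",
                             data=np.array(self.channel_names,
                                           dtype=h5py.string_dtype()))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        with h5py.File(path, "r") as f:
            values = f["values"][...]
            layout = []
            for s in f["layout"][...]:
                b, k, w = s.decode().split("\t")
                layout.append((b, k, int(w)))
            channels = [s.decode() for s in f["channel_names"][...]]
        return cls(values, layout, channels)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _butter_sos(lo: float, hi: float, fs: float, order: int = 4):
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def preprocess(raw: SignalRecord, lo: float = 4.0, hi: float = 60.0) -> SignalRecord:
    """Bandpass filter (zero-phase Butterworth) then z-score each channel.

    Raises :class:`DegenerateInputError` for constant channels and
    ``ValueError`` when the band is invalid for the sampling rate.
    """
    BandSpec("passband", lo, hi).validate(raw.fs)
    if raw.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples per channel")
    sd = raw.data.std(axis=1)
    if np.any(sd == 0):
        bad = [raw.channel_names[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(f"constant (zero-variance) channel(s): {bad}")
    sos = _butter_sos(lo, hi, raw.fs)
    filt = sps.sosfiltfilt(sos, raw.data, axis=1)
    filt = filt - filt.mean(axis=1, keepdims=True)
    fsd = filt.std(axis=1)
    if np.any(fsd == 0):
        raise DegenerateInputError("channel became constant after filtering")
    out = filt / fsd[:, None]
    if not np.all(np.isfinite(out)):
        raise DegenerateInputError("non-finite values after preprocessing")
    return SignalRecord(out, raw.fs, list(raw.channel_names))


def segment(record: SignalRecord, win_s: float, step_s: float) -> list[np.ndarray]:
    """Sliding windows of ``win_s`` seconds advanced by ``step_s`` seconds.

    Returns ``floor((duration - win)/step) + 1`` fully contained windows
    (channels x win_samples each); windows that would overrun are dropped.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    win = int(round(win_s * record.fs))
    step = int(round(step_s * record.fs))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if win > record.n_samples:
        raise DegenerateInputError(
            f"window ({win_s} s) exceeds record duration ({record.duration} s)")
    n_win = (record.n_samples - win) // step + 1
    return [record.data[:, i * step:i * step + win] for i in range(n_win)]


def band_features(window: np.ndarray, fs: float, band: BandSpec,
                  prefiltered: bool = False) -> tuple[float, float]:
    """PSD and DE of one single-channel window in one band.

    PSD is the mean Hann-taper periodogram power inside ``band`` (linear
    scale).  DE is ``0.5*ln(2*pi*e*var)`` of the band-filtered window; pass
    ``prefiltered=True`` when the window already is the band signal.  A
    zero-variance band signal clips DE at ``DE_FLOOR``.
    """
    window = np.asarray(window, dtype=np.float64).ravel()
    if window.size < 2:
        raise ValueError("window must hold at least 2 samples")
    band.validate(fs)
    freqs, pxx = sps.periodogram(window, fs=fs, window="hann")
    in_band = (freqs >= band.lo) & (freqs <= band.hi)
    psd = float(pxx[in_band].mean()) if np.any(in_band) else 0.0

    if prefiltered:
        band_sig = window
    else:
        sos = _butter_sos(band.lo, band.hi, fs)
        band_sig = sps.sosfiltfilt(sos, window)
    var = float(band_sig.var())
    if var <= 0.0:
        logger.warning("zero-variance band signal in %s; DE clipped to %.1f",
                       band.name, DE_FLOOR)
        de = DE_FLOOR
    else:
        de = max(0.5 * np.log(2.0 * np.pi * np.e * var), DE_FLOOR)
    return psd, de


def assemble_feature_matrix(per_channel: list[dict[tuple[str, str], np.ndarray]],
                            band_order: list[str],
                            feature_kinds: list[str],
                            channel_names: list[str]) -> FeatureMatrix:
    """Stack per-channel band/window feature series into a FeatureMatrix.

    ``per_channel[i]`` maps ``(band, kind)`` to the window-ordered series of
    channel ``i``.  Rows are grouped by band in ``band_order``; inside a band,
    one contiguous sub-block per feature kind (in ``feature_kinds`` order),
    windows in their original order.  Column ``i`` is channel ``i``.
    """
    if len(per_channel) != len(channel_names):
        raise ValueError("one series dict per channel required")
    counts = {len(v) for ch in per_channel for v in ch.values()}
    if len(counts) != 1:
        raise ValueError(f"ragged window counts across channels/bands: {sorted(counts)}")
    n_win = counts.pop()

    layout: list[tuple[str, str, int]] = []
    for band in band_order:
        for kind in feature_kinds:
            layout.extend((band, kind, w) for w in range(n_win))
    cols = []
    for ch in per_channel:
        col = np.concatenate([np.asarray(ch[(band, kind)], dtype=np.float64)
                              for band in band_order for kind in feature_kinds])
        cols.append(col)
    return FeatureMatrix(np.column_stack(cols), layout, list(channel_names))


def extract_features(raw: SignalRecord,
                     bands: tuple = DEFAULT_BANDS,
                     win_s: float = 1.0,
                     step_s: float = 0.5,
                     feature_kinds: tuple[str, ...] = ("psd", "de"),
                     passband: tuple[float, float] = (4.0, 60.0),
                     last_seconds: float | None = 60.0) -> FeatureMatrix:
    """Full pipeline: (optional) tail selection, preprocess, segment, features.

    ``feature_kinds`` is a subset of ``("psd", "de")``; each kind adds one
    contiguous sub-block per band.
    """
    for k in feature_kinds:
        if k not in ("psd", "de"):
            raise ValueError(f"unknown feature kind {k!r}")
    if last_seconds is not None:
        raw = raw.last_seconds(last_seconds)
    pe = preprocess(raw, *passband)
    windows = segment(pe, win_s, step_s)
    band_specs = [BandSpec(*b) for b in bands]

    per_channel: list[dict[tuple[str, str], np.ndarray]] = []
    for c in range(pe.n_channels):
        series: dict[tuple[str, str], list[float]] = {
            (b.name, k): [] for b in band_specs for k in feature_kinds}
        for w in windows:
            for b in band_specs:
                psd, de = band_features(w[c], pe.fs, b)
                if "psd" in feature_kinds:
                    series[(b.name, "psd")].append(psd)
                if "de" in feature_kinds:
                    series[(b.name, "de")].append(de)
        per_channel.append({k: np.array(v) for k, v in series.items()})

    return assemble_feature_matrix(per_channel, [b.name for b in band_specs],
                                   list(feature_kinds), pe.channel_names)


# ---------------------------------------------------------------------------
# raw-signal disk formats
# ---------------------------------------------------------------------------

def write_signal(record: SignalRecord, path: str | Path) -> None:
    """Write channels x samples TSV plus a ``.json`` sidecar (fs, channels)."""
    path = Path(path)
    np.savetxt(path, record.data, delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"fs": record.fs, "channel_names": record.channel_names}))


def read_signal(path: str | Path) -> SignalRecord:
    """Read a record from EDF (via mne) or delimited text + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return SignalRecord(raw.get_data(), raw.info["sfreq"],
                            list(raw.ch_names))
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return SignalRecord(data, float(meta["fs"]), list(meta["channel_names"]))
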