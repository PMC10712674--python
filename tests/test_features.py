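"""Feature-extraction pipeline: filtering, windowing, PSD/DE, assembly, IO."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from fractalsnn.features import (BandSpec, DegenerateInputError, FeatureMatrix,
                                 assemble_feature_matrix, band_features,
                                 extract_features, preprocess, read_signal,
                                 segment, write_signal, DE_FLOOR, SignalRecord)


def make_record(data, fs=128.0):
    data = np.atleast_2d(data)
    return SignalRecord(data, fs, [f"CH{i}" for i in range(data.shape[0])])


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

def test_preprocess_zscores_each_channel(rng):
    rec = make_record(rng.normal(2.0, 5.0, size=(3, 1024)))
    out = preprocess(rec, 4.0, 60.0)
    assert np.abs(out.data.mean(axis=1)).max() < 1e-8
    assert np.abs(out.data.std(axis=1) - 1.0).max() < 1e-8


def test_preprocess_attenuates_out_of_band_content(rng):
    """A 2 Hz tone mixed with a 10 Hz tone: after the 4-60 Hz bandpass the
    2 Hz line carries under 5% of the 10 Hz line's power (periodogram)."""
    fs = 128.0
    t = np.arange(int(fs * 8)) / fs
    x = np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 10.0 * t)
    out = preprocess(make_record(x, fs), 4.0, 60.0)
    freqs, pxx = sps.periodogram(out.data[0], fs=fs)
    p2 = pxx[np.abs(freqs - 2.0) < 1.0].sum()
    p10 = pxx[np.abs(freqs - 10.0) < 1.0].sum()
    assert p2 < 0.05 * p10


def test_preprocess_rejects_constant_channel():
    data = np.vstack([np.ones(256), np.random.default_rng(0).normal(size=256)])
    with pytest.raises(DegenerateInputError):
        preprocess(make_record(data), 4.0, 60.0)


def test_preprocess_rejects_band_beyond_nyquist(rng):
    rec = make_record(rng.normal(size=(1, 256)), fs=100.0)
    with pytest.raises(ValueError):
        preprocess(rec, 4.0, 60.0)   # 60 >= 100/2


# ---------------------------------------------------------------------------
# segment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("duration, win, step, expected", [
    (60.0, 1.0, 0.5, 119),
    (1.0, 1.0, 0.5, 1),
    (60.0, 1.0, 1.0, 60),
])
def test_segment_window_counts(rng, duration, win, step, expected):
    fs = 128.0
    rec = make_record(rng.normal(size=(2, int(duration * fs))), fs)
    windows = segment(rec, win, step)
    assert len(windows) == expected
    assert all(w.shape == (2, int(win * fs)) for w in windows)


@given(n_win=st.integers(1, 40), win=st.integers(1, 4), step=st.integers(1, 4))
def test_segment_count_formula(n_win, win, step):
    """floor((duration - win)/step) + 1 for any duration >= win."""
    fs = 16.0
    duration = win + step * (n_win - 1)
    data = np.zeros((1, int(duration * fs)))
    data[0, 0] = 1.0   # avoid constant-channel edge cases downstream
    windows = segment(make_record(data, fs), float(win), float(step))
    assert len(windows) == (int(duration * fs) - win * int(fs)) // (step * int(fs)) + 1
    assert len(windows) == n_win


def test_segment_rejects_window_longer_than_record(rng):
    rec = make_record(rng.normal(size=(1, 64)), fs=128.0)
    with pytest.raises(DegenerateInputError):
        segment(rec, 1.0, 0.5)


# ---------------------------------------------------------------------------
# band features
# ---------------------------------------------------------------------------

BETA = BandSpec("beta", 14.0, 30.0)


def test_de_of_unit_variance_gaussian(rng):
    """DE of a unit-variance Gaussian band signal is 0.5*ln(2*pi*e)."""
    x = rng.normal(size=8192)
    x = (x - x.mean()) / x.std()
    _, de = band_features(x, 128.0, BETA, prefiltered=True)
    assert de == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=1e-6)


def test_zero_window_psd_zero_and_de_floored():
    psd, de = band_features(np.zeros(128), 128.0, BETA, prefiltered=True)
    assert psd == 0.0
    assert de == DE_FLOOR


def test_amplitude_scaling_laws(rng):
    """Doubling amplitudes multiplies PSD by 4 and adds ln 2 to DE."""
    x = rng.normal(size=256)
    psd1, de1 = band_features(x, 128.0, BETA)
    psd2, de2 = band_features(2 * x, 128.0, BETA)
    assert psd2 == pytest.approx(4 * psd1, rel=1e-9)
    assert de2 - de1 == pytest.approx(np.log(2.0), abs=1e-9)


@given(c=st.floats(0.1, 50.0), seed=st.integers(0, 100))
def test_de_scaling_property(c, seed):
    """de(c*x) - de(x) = ln|c| on white-noise windows."""
    x = np.random.default_rng(seed).normal(size=256)
    _, de1 = band_features(x, 128.0, BETA, prefiltered=True)
    _, de2 = band_features(c * x, 128.0, BETA, prefiltered=True)
    assert de2 - de1 == pytest.approx(np.log(abs(c)), abs=1e-6)


# ---------------------------------------------------------------------------
# assembly and layout
# ---------------------------------------------------------------------------

def test_assemble_single_band_de_only():
    per_channel = [
        {("theta", "de"): np.array([1.0, 2.0])},
        {("theta", "de"): np.array([3.0, 4.0])},
    ]
    fm = assemble_feature_matrix(per_channel, ["theta"], ["de"], ["A", "B"])
    assert fm.values.shape == (2, 2)
    assert np.array_equal(fm.values, [[1.0, 3.0], [2.0, 4.0]])
    assert fm.layout == [("theta", "de", 0), ("theta", "de", 1)]


def test_assemble_rejects_ragged_window_counts():
    per_channel = [
        {("theta", "de"): np.array([1.0, 2.0])},
        {("theta", "de"): np.array([3.0])},
    ]
    with pytest.raises(ValueError):
        assemble_feature_matrix(per_channel, ["theta"], ["de"], ["A", "B"])


def test_full_pipeline_row_count_and_band_order(rng):
    """60 s at 1 s / 0.5 s windows, 4 bands, DE only -> 476 rows per channel,
    with contiguous band blocks in the configured order."""
    fs = 128.0
    rec = make_record(rng.normal(size=(2, int(60 * fs))), fs)
    fm = extract_features(rec, feature_kinds=("de",), last_seconds=None)
    assert fm.values.shape == (4 * 119, 2)
    bands_seen = [b for b, _, _ in fm.layout]
    # contiguous blocks in theta, alpha, beta, gamma order
    block = len(fm.layout) // 4
    assert bands_seen == (["theta"] * block + ["alpha"] * block
                          + ["beta"] * block + ["gamma"] * block)


def test_channel_permutation_permutes_columns(rng):
    fs = 128.0
    data = rng.normal(size=(3, int(4 * fs)))
    fm = extract_features(make_record(data, fs), feature_kinds=("de",),
                          last_seconds=None)
    perm = [2, 0, 1]
    rec_p = SignalRecord(data[perm], fs, [f"CH{i}" for i in perm])
    fm_p = extract_features(rec_p, feature_kinds=("de",), last_seconds=None)
    assert np.allclose(fm_p.values, fm.values[:, perm])
    assert fm_p.channel_names == [f"CH{i}" for i in perm]


def test_psd_and_de_form_two_subblocks_per_band(rng):
    fs = 128.0
    rec = make_record(rng.normal(size=(1, int(3 * fs))), fs)
    fm = extract_features(rec, feature_kinds=("psd", "de"), last_seconds=None)
    kinds_theta = [k for b, k, _ in fm.layout if b == "theta"]
    n_win = len(kinds_theta) // 2
    assert kinds_theta == ["psd"] * n_win + ["de"] * n_win


# ---------------------------------------------------------------------------
# disk round-trips
# ---------------------------------------------------------------------------

def test_feature_matrix_roundtrip_bit_exact(tmp_path, rng):
    fm = FeatureMatrix(rng.normal(size=(6, 3)),
                       [("theta", "de", w) for w in range(6)],
                       ["A", "B", "C"])
    path = tmp_path / "fm.h5"
    fm.save(path)
    back = FeatureMatrix.load(path)
    assert np.array_equal(back.values, fm.values)
    assert back.layout == fm.layout
    assert back.channel_names == fm.channel_names


def test_signal_roundtrip(tmp_path, rng):
    rec = make_record(rng.normal(size=(2, 64)), fs=128.0)
    path = tmp_path / "rec.tsv"
    write_signal(rec, path)
    back = read_signal(path)
    assert np.allclose(back.data, rec.data)
    assert back.fs == rec.fs
    assert back.channel_names == rec.channel_names
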