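"""Labels, folds, training loop and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fractalsnn.model import FractalSNN, ModelConfig
from fractalsnn.synthetic import FeatureSyntheticConfig, generate_feature_dataset
from fractalsnn.train import (CVProtocol, LabeledDataset, Standardizer,
                              TrainConfig, binarize_rating, evaluate,
                              make_folds, mask_channels, train_folds,
                              train_model)


@pytest.mark.parametrize("rating, middle, expected", [
    (3, 3, 1),    # at the midpoint counts as high
    (2, 3, 0),
    (5, 5, 1),
    (4.9, 5, 0),
])
def test_rating_binarization(rating, middle, expected):
    assert binarize_rating(rating, middle) == expected


def tiny_dataset(n_samples=18, n_subjects=1, n=6, m=4, seed=0):
    cfg = FeatureSyntheticConfig(
        n_subjects=n_subjects, trials_per_class=n_samples // (2 * n_subjects),
        n_channels=m, n_per_band=n // 5 + 1, effect_size=3.0,
        effect_channels=(0, 1), seed=seed)
    return generate_feature_dataset(cfg)


@pytest.mark.parametrize("n_samples, k, test_size", [(18, 9, 2), (40, 10, 4)])
def test_kfold_sizes_match_protocols(n_samples, k, test_size):
    ds = tiny_dataset(n_samples=n_samples)
    folds = make_folds(ds, CVProtocol("kfold", k, seed=0))
    assert len(folds) == k
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(n_samples))   # disjoint + exhaustive
    for tr, te in folds:
        assert len(te) == test_size
        assert len(tr) == n_samples - test_size
        assert set(tr).isdisjoint(te)


@given(k=st.integers(2, 8), mult=st.integers(1, 4))
def test_kfold_partitions_for_divisible_sizes(k, mult):
    n_samples = 2 * k * mult
    ds = tiny_dataset(n_samples=n_samples)
    folds = make_folds(ds, CVProtocol("kfold", k, seed=1))
    sizes = {len(te) for _, te in folds}
    assert sizes == {n_samples // k}
    assert sorted(np.concatenate([te for _, te in folds])) == list(range(n_samples))


def test_loso_covers_each_subject_exactly_once():
    ds = tiny_dataset(n_samples=20, n_subjects=5)
    folds = make_folds(ds, CVProtocol("loso"))
    assert len(folds) == 5
    held_out = []
    for tr, te in folds:
        subjects = set(ds.subject_ids[te])
        assert len(subjects) == 1
        assert subjects.isdisjoint(ds.subject_ids[tr])
        held_out.extend(subjects)
    assert sorted(held_out) == [0, 1, 2, 3, 4]


def test_k_larger_than_dataset_rejected():
    ds = tiny_dataset(n_samples=4)
    with pytest.raises(ValueError):
        make_folds(ds, CVProtocol("kfold", 9, seed=0))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_evaluate_perfect_and_confusion_row_sums(rng):
    ds = tiny_dataset(n_samples=12)
    n, m = ds.samples[0].n, ds.samples[0].m
    model = FractalSNN(ModelConfig(n=n, m=m, z=2, fractal_order=2, seed=0))
    x = ds.stack()
    pred = model.predict(x).probs.argmax(axis=1)
    res = evaluate(model, x, pred)       # score against its own predictions
    assert res.accuracy == 1.0
    res2 = evaluate(model, x, ds.labels)
    assert res2.confusion.sum() == len(ds)
    assert np.array_equal(res2.confusion.sum(axis=1),
                          np.bincount(ds.labels, minlength=2))


def test_accuracy_against_random_labels_near_chance(rng):
    """A fixed predictor scored on uniform random 4-class labels lands near
    0.25 (binomial, 3 SE)."""
    cfg = FeatureSyntheticConfig(trials_per_class=200, n_classes=4,
                                 n_channels=4, n_per_band=2, effect_size=0.0,
                                 seed=3)
    ds = generate_feature_dataset(cfg)
    n, m = ds.samples[0].n, ds.samples[0].m
    model = FractalSNN(ModelConfig(n=n, m=m, z=4, fractal_order=1, seed=1))
    labels = rng.integers(0, 4, len(ds))
    res = evaluate(model, ds.stack(), labels)
    se = np.sqrt(0.25 * 0.75 / len(ds))
    assert abs(res.accuracy - 0.25) < 3 * se


def test_evaluate_rejects_empty():
    ds = tiny_dataset(n_samples=4)
    n, m = ds.samples[0].n, ds.samples[0].m
    model = FractalSNN(ModelConfig(n=n, m=m, z=2, fractal_order=1))
    with pytest.raises(ValueError):
        evaluate(model, np.zeros((0, n, m)), np.zeros(0, dtype=int))


# ---------------------------------------------------------------------------
# channel masking
# ---------------------------------------------------------------------------

def test_mask_channels_identity_and_removal():
    ds = tiny_dataset(n_samples=8, m=14)
    assert mask_channels(ds, set()).samples[0].m == 14
    masked = mask_channels(ds, {"CH0", "CH3", "CH7", "CH13"})
    assert masked.samples[0].m == 10
    assert "CH0" not in masked.samples[0].channel_names
    # metadata round-trips: the kept names are the original minus the mask
    expected = [c for c in ds.samples[0].channel_names
                if c not in {"CH0", "CH3", "CH7", "CH13"}]
    assert masked.samples[0].channel_names == expected


def test_mask_channels_errors():
    ds = tiny_dataset(n_samples=8, m=4)
    with pytest.raises(ValueError):
        mask_channels(ds, {"CH0", "CH1", "CH2", "CH3"})
    with pytest.raises(ValueError):
        mask_channels(ds, {"NOPE"})


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def run_short_training(seed):
    ds = tiny_dataset(n_samples=12, seed=4)
    n, m = ds.samples[0].n, ds.samples[0].m
    model = FractalSNN(ModelConfig(n=n, m=m, z=2, fractal_order=2, seed=seed))
    x = Standardizer().fit(ds.stack()).transform(ds.stack())
    curve = train_model(model, x, ds.labels, TrainConfig(epochs=15, seed=seed))
    return model, curve


def test_same_seed_gives_identical_loss_curves():
    _, c1 = run_short_training(7)
    _, c2 = run_short_training(7)
    assert c1 == c2


def test_loss_decreases_on_separable_data():
    _, curve = run_short_training(3)
    assert curve[-1] < curve[0]


def test_train_folds_reports_per_fold_accuracy():
    ds = tiny_dataset(n_samples=12, seed=5)
    n, m = ds.samples[0].n, ds.samples[0].m
    cfg = ModelConfig(n=n, m=m, z=2, fractal_order=2)
    folds = make_folds(ds, CVProtocol("kfold", 3, seed=0))
    results = train_folds(ds, folds, cfg, TrainConfig(epochs=10, seed=0))
    assert len(results) == 3
    for r in results:
        assert 0.0 <= r.accuracy <= 1.0
        assert len(r.loss_curve) == 10
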