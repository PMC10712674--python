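"""Label construction, cross-validation protocols, training loop, metrics.

Subject-dependent evaluation uses k-fold cross-validation within each subject
(9-fold for 18-trial subjects, 10-fold for 40-trial subjects); fold means are
averaged within a subject first, then across subjects.  Subject-independent
evaluation uses leave-one-subject-out (LOSO).  Continuous affect ratings are
binarized at the scale midpoint (high iff rating >= midpoint).

Training minimises cross-entropy with Adam and surrogate spike gradients;
features are standardised per matrix cell using training-fold statistics.
Every source of randomness (fold shuffling, weight init, drop-path masks) is
driven from one seed stream, so a fixed seed reproduces fold assignment,
weights and metrics exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, LeaveOneGroupOut

from .autodiff import Adam, Tensor, cross_entropy
from .features import FeatureMatrix
from .model import FractalSNN, ModelConfig

logger = logging.getLogger(__name__)

__all__ = ["LabeledDataset", "CVProtocol", "TrainConfig", "binarize_rating",
           "make_folds", "train_model", "train_folds", "run_cv", "evaluate",
           "mask_channels", "Standardizer"]


@dataclass
class LabeledDataset:
    """Feature matrices with integer class labels and subject ids."""
    samples: list[FeatureMatrix]
    labels: np.ndarray
    subject_ids: np.ndarray
    dimension: str = "valence"     # valence | arousal | dominance | discrete

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if not (len(self.samples) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("samples, labels and subject_ids must align")
        if len(self.samples) and self.labels.min() < 0:
            raise ValueError("labels must be non-negative class indices")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.samples) else 0

    def stack(self) -> np.ndarray:
        """All samples as one (B, n, m) array."""
        return np.stack([s.values for s in self.samples])

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset([self.samples[i] for i in idx],
                              self.labels[idx], self.subject_ids[idx],
                              self.dimension)


def binarize_rating(rating: float, middle: float) -> int:
    """1 ("high") iff the rating is not less than the scale midpoint."""
    return int(rating >= middle)


@dataclass
class CVProtocol:
    """kfold (within-subject) or loso (across subjects)."""
    kind: str = "kfold"
    k: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("kfold", "loso"):
            raise ValueError(f"unknown protocol {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("kfold needs k >= 2")


def make_folds(dataset: LabeledDataset,
               protocol: CVProtocol) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs partitioning the dataset.

    kfold: disjoint, exhaustive test sets (shuffled, seeded); loso: one fold
    per subject, whose samples form the test set.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if protocol.kind == "kfold":
        if protocol.k > len(dataset):
            raise ValueError(f"k={protocol.k} exceeds sample count {len(dataset)}")
        kf = KFold(n_splits=protocol.k, shuffle=True, random_state=protocol.seed)
        return [(tr, te) for tr, te in kf.split(np.arange(len(dataset)))]
    logo = LeaveOneGroupOut()
    return [(tr, te) for tr, te in
            logo.split(np.arange(len(dataset)), groups=dataset.subject_ids)]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 100
    batch_size: int | None = None      # None = full batch
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only adam is implemented")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy is implemented")


class Standardizer:
    """Per-cell z-scoring of (B, n, m) feature stacks using train statistics."""

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean_ = x.mean(axis=0)
        self.std_ = np.maximum(x.std(axis=0), 1e-8)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.std_


def train_model(model: FractalSNN, x: np.ndarray, y: np.ndarray,
                cfg: TrainConfig,
                rng: np.random.Generator | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean training loss curve."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n_samples = x.shape[0]
    batch = cfg.batch_size or n_samples
    curve: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_samples)
        losses = []
        for start in range(0, n_samples, batch):
            idx = order[start:start + batch]
            logits = model.forward(x[idx], training=True, rng=rng)
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    return curve


@dataclass
class EvalResult:
    accuracy: float
    confusion: np.ndarray      # rows = true class, columns = predicted


def evaluate(model: FractalSNN, x: np.ndarray, y: np.ndarray) -> EvalResult:
    """Accuracy and per-class confusion counts on a held-out set."""
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict(x).probs
    pred = probs.argmax(axis=1)
    acc = float((pred == y).mean())
    cm = confusion_matrix(y, pred, labels=np.arange(model.cfg.z))
    return EvalResult(accuracy=acc, confusion=cm)


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    loss_curve: list[float]
    confusion: np.ndarray
    model: FractalSNN


def train_folds(dataset: LabeledDataset,
                folds: list[tuple[np.ndarray, np.ndarray]],
                model_cfg: ModelConfig, train_cfg: TrainConfig,
                seed_seq: np.random.SeedSequence | None = None) -> list[FoldResult]:
    """Train one freshly initialised model per fold (no leakage across folds:
    model seeds come from one spawned stream, scalers fit on train data only)."""
    seed_seq = seed_seq if seed_seq is not None else np.random.SeedSequence(
        train_cfg.seed)
    x_all = dataset.stack()
    y_all = dataset.labels
    results = []
    for fold_idx, (tr, te) in enumerate(folds):
        child = seed_seq.spawn(1)[0]
        model_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "seed": model_seed})
        model = FractalSNN(cfg)
        scaler = Standardizer().fit(x_all[tr])
        rng = np.random.default_rng(child)
        curve = train_model(model, scaler.transform(x_all[tr]), y_all[tr],
                            train_cfg, rng=rng)
        model.input_mean, model.input_std = scaler.mean_, scaler.std_
        res = evaluate(model, scaler.transform(x_all[te]), y_all[te])
        logger.info("fold %d: accuracy %.3f (final loss %.4f)",
                    fold_idx, res.accuracy, curve[-1])
        results.append(FoldResult(fold_idx, res.accuracy, curve,
                                  res.confusion, model))
    return results


@dataclass
class CVResult:
    per_subject: dict            # subject -> list of fold accuracies
    mean_accuracy: float
    sd_accuracy: float
    fold_results: list[FoldResult]


def run_cv(dataset: LabeledDataset, protocol: CVProtocol,
           model_cfg: ModelConfig, train_cfg: TrainConfig) -> CVResult:
    """Full protocol run.

    kfold: folds are drawn within each subject and fold accuracies averaged
    per subject, then across subjects.  loso: one fold per held-out subject,
    averaged across subjects.
    """
    seed_seq = np.random.SeedSequence(train_cfg.seed)
    per_subject: dict = {}
    all_results: list[FoldResult] = []
    if protocol.kind == "kfold":
        for subject in np.unique(dataset.subject_ids):
            sub = dataset.subset(np.flatnonzero(dataset.subject_ids == subject))
            folds = make_folds(sub, protocol)
            results = train_folds(sub, folds, model_cfg, train_cfg, seed_seq)
            per_subject[subject] = [r.accuracy for r in results]
            all_results.extend(results)
    else:
        folds = make_folds(dataset, protocol)
        results = train_folds(dataset, folds, model_cfg, train_cfg, seed_seq)
        for (tr, te), r in zip(folds, results):
            subject = dataset.subject_ids[te[0]]
            per_subject[subject] = [r.accuracy]
        all_results = results
    subject_means = np.array([np.mean(v) for v in per_subject.values()])
    return CVResult(per_subject=per_subject,
                    mean_accuracy=float(subject_means.mean()),
                    sd_accuracy=float(subject_means.std()),
                    fold_results=all_results)


def mask_channels(dataset: LabeledDataset, disabled) -> LabeledDataset:
    """Remove the named channels from every sample (symmetric-disabling
    utility); the model width m shrinks accordingly."""
    disabled = set(disabled)
    if not len(dataset):
        raise ValueError("empty dataset")
    names = dataset.samples[0].channel_names
    unknown = disabled - set(names)
    if unknown:
        raise ValueError(f"unknown channel(s): {sorted(unknown)}")
    keep = [i for i, c in enumerate(names) if c not in disabled]
    if not keep:
        raise ValueError("cannot disable every channel")
    masked = [FeatureMatrix(s.values[:, keep], list(s.layout),
                            [s.channel_names[i] for i in keep])
              for s in dataset.samples]
    return LabeledDataset(masked, dataset.labels.copy(),
                          dataset.subject_ids.copy(), dataset.dimension)
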