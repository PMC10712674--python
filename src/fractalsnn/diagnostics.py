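"""Model diagnostics: gradient saliency maps and reliability (calibration).

Saliency backpropagates the pre-softmax logit of one class to the input
feature matrix (surrogate gradients carry through the spike thresholds), then
min-max normalises the absolute gradient to [0, 1].  Reliability bins each
class's predicted probabilities into [0,.25), [.25,.5), [.5,.75), [.75,1]
and compares the mean predicted probability with the empirical accuracy
per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["SaliencyMap", "saliency", "reliability", "RELIABILITY_BINS"]

#: Bin edges of the reliability diagram; the last bin is closed at 1.
RELIABILITY_BINS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0))


@dataclass
class SaliencyMap:
    """Normalised |gradient| of a class score w.r.t. the input (n x m)."""
    values: np.ndarray
    class_index: int


def saliency(model, x: FeatureMatrix | np.ndarray, class_idx: int,
             standardize: bool = False) -> SaliencyMap:
    """Saliency of ``class_idx``'s logit for one input feature matrix.

    ``model`` needs a ``forward_tensor(x, training=False)`` method returning
    the logits tensor; any fitted :class:`~fractalsnn.model.FractalSNN`
    qualifies.  ``standardize`` z-scores the matrix first (when the model was
    trained on standardised features).  A zero gradient everywhere yields an
    all-zero map with a warning; otherwise min 0, max 1.
    """
    values = x.values if isinstance(x, FeatureMatrix) else np.asarray(x)
    values = values.astype(np.float64)
    if standardize:
        sd = values.std()
        values = (values - values.mean()) / (sd if sd > 0 else 1.0)
    inp = Tensor(values, requires_grad=True)
    logits = model.forward_tensor(inp, training=False)
    score = logits[int(class_idx)]
    score.backward(np.ones_like(score.data))
    grad = np.abs(inp.grad) if inp.grad is not None else np.zeros_like(values)
    lo, hi = grad.min(), grad.max()
    if hi <= lo:
        logger.warning("zero gradient everywhere: all-zero saliency map")
        return SaliencyMap(np.zeros_like(grad), int(class_idx))
    return SaliencyMap((grad - lo) / (hi - lo), int(class_idx))


def reliability(probs: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-class reliability table.

    For each class ``c`` every sample is binned by its predicted probability
    of ``c``; each row reports the bin's sample count, mean predicted
    probability and empirical accuracy (fraction of samples whose true label
    is ``c``).  Empty bins keep count 0 with NaN statistics and are flagged,
    never fabricated.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise ValueError("probs must be (n_samples, n_classes)")
    if len(labels) != probs.shape[0]:
        raise ValueError("labels do not match probs")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rows = []
    for cls in range(probs.shape[1]):
        p = probs[:, cls]
        correct = labels == cls
        for lo, hi in RELIABILITY_BINS:
            if hi >= 1.0:
                in_bin = (p >= lo) & (p <= hi)
            else:
                in_bin = (p >= lo) & (p < hi)
            count = int(in_bin.sum())
            rows.append({
                "class": cls,
                "bin_lo": lo,
                "bin_hi": hi,
                "count": count,
                "mean_predicted": float(p[in_bin].mean()) if count else np.nan,
                "accuracy": float(correct[in_bin].mean()) if count else np.nan,
                "empty": count == 0,
            })
    table = pd.DataFrame(rows)
    if table["empty"].any():
        logger.info("reliability: %d empty bin(s) flagged",
                    int(table["empty"].sum()))
    return table
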