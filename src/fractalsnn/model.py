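"""Full scheme assembly: attention -> fractal block -> readout -> classifier.

The classifier head takes the fractal representation ``F_c(X) in R^{n x m}``,
passes it through a readout Soma (``n1`` neurons, binary spike output), then
per channel through a dimensionality bottleneck — a linear layer up to
``2*n1``, a leaky ReLU, a linear layer down to the ``z`` class logits — and
finally pools the per-channel logits with learnable channel weights before a
softmax.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attention import AttentionParams, attention_tensor
from .autodiff import Tensor
from .features import FeatureMatrix
from .fractal import (DropPathConfig, FractalSpec, build_fractal,
                      fractal_forward)
from .neuron import NeuronConfig, soma

__all__ = ["ModelConfig", "HeadParams", "Prediction", "head_forward",
           "FractalSNN", "scheme_forward"]


@dataclass
class Prediction:
    """Class probabilities (sum to 1) and the raw logits they came from."""
    probs: np.ndarray
    logits: np.ndarray


@dataclass
class ModelConfig:
    """Everything needed to build the scheme for (n features, m channels,
    z classes).  Defaults: order-3 fractal, one attention head, inverted
    drop-path at rate 0.15."""
    n: int
    m: int
    z: int
    attention_enabled: bool = True
    heads: int = 1
    fractal_order: int = 3
    drop: DropPathConfig = field(default_factory=DropPathConfig)
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    n1: int | None = None          # readout Soma size; defaults to n
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.z < 2:
            raise ValueError("need at least 2 classes")
        if self.n1 is None:
            self.n1 = self.n

    def to_dict(self) -> dict:
        return {"n": self.n, "m": self.m, "z": self.z,
                "attention_enabled": self.attention_enabled,
                "heads": self.heads, "fractal_order": self.fractal_order,
                "drop": {"p": self.drop.p, "mode": self.drop.mode},
                "neuron": self.neuron.to_dict(), "n1": self.n1,
                "leaky_slope": self.leaky_slope, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["drop"] = DropPathConfig(**d["drop"])
        d["neuron"] = NeuronConfig(**d["neuron"])
        return cls(**d)


@dataclass
class HeadParams:
    """Readout Soma weights plus the bottleneck and pooling parameters."""
    w_readout: Tensor              # (n1, n)
    l1_w: Tensor                   # (2*n1, n1)
    l1_b: Tensor                   # (2*n1,)
    l2_w: Tensor                   # (z, 2*n1)
    l2_b: Tensor                   # (z,)
    w_pool: Tensor                 # (m,)
    leaky_slope: float = 0.01

    def tensors(self) -> list[Tensor]:
        return [self.w_readout, self.l1_w, self.l1_b, self.l2_w, self.l2_b,
                self.w_pool]

    @classmethod
    def init(cls, n: int, n1: int, m: int, z: int,
             rng: np.random.Generator, leaky_slope: float = 0.01) -> "HeadParams":
        return cls(
            w_readout=Tensor(rng.normal(0, 1 / np.sqrt(n), (n1, n)),
                             requires_grad=True),
            l1_w=Tensor(rng.normal(0, 1 / np.sqrt(n1), (2 * n1, n1)),
                        requires_grad=True),
            l1_b=Tensor(np.zeros(2 * n1), requires_grad=True),
            l2_w=Tensor(rng.normal(0, 1 / np.sqrt(2 * n1), (z, 2 * n1)),
                        requires_grad=True),
            l2_b=Tensor(np.zeros(z), requires_grad=True),
            w_pool=Tensor(np.full(m, 1.0 / m), requires_grad=True),
            leaky_slope=leaky_slope,
        )


def _head_tensor(f_out: Tensor, params: HeadParams, cfg: NeuronConfig) -> Tensor:
    """Differentiable head on (n, m[, batch]); returns logits (z[, batch])."""
    spikes = soma(f_out, params.w_readout, cfg)          # (n1, m[, B]) binary
    n1 = spikes.shape[0]
    m = spikes.shape[1]
    batched = spikes.ndim == 3
    flat = spikes.reshape(n1, -1)                        # (n1, m*B)
    y1 = params.l1_w @ flat + params.l1_b.reshape(-1, 1)
    y1 = y1.leaky_relu(params.leaky_slope)
    y2 = params.l2_w @ y1 + params.l2_b.reshape(-1, 1)   # (z, m*B)
    z = y2.shape[0]
    if batched:
        y2 = y2.reshape(z, m, -1)
        pooled = (y2 * params.w_pool.reshape(1, m, 1)).sum(axis=1)  # (z, B)
        return pooled
    y2 = y2.reshape(z, m)
    return (y2 * params.w_pool.reshape(1, m)).sum(axis=1)           # (z,)


def head_forward(f_out: np.ndarray, params: HeadParams,
                 cfg: NeuronConfig) -> Prediction:
    """Classifier head on one fractal representation (n x m)."""
    logits = _head_tensor(Tensor(np.asarray(f_out, dtype=np.float64)),
                          params, cfg).data
    return Prediction(probs=_softmax(logits), logits=logits)


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class FractalSNN:
    """The complete scheme: attention, fractal block, classifier head.

    Deterministic at test time; training-time randomness (drop-path masks)
    comes from the ``rng`` handed to :meth:`forward`.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.attention = (AttentionParams.init(cfg.n, cfg.heads, rng)
                          if cfg.attention_enabled else None)
        self.fractal: FractalSpec = build_fractal(cfg.fractal_order, cfg.n, rng)
        self.head = HeadParams.init(cfg.n, cfg.n1, cfg.m, cfg.z, rng,
                                    cfg.leaky_slope)
        # per-cell feature scaling fitted on the training fold (set by the
        # training loop, carried in checkpoints so saved models accept raw
        # feature matrices)
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    # -- parameters ------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.attention is not None:
            out.extend(self.attention.tensors())
        out.extend(self.fractal.somas())
        out.extend(self.head.tensors())
        return out

    # -- forward ---------------------------------------------------------

    def forward_tensor(self, x: Tensor, training: bool = False,
                       rng: np.random.Generator | None = None,
                       force_column: int | None = None) -> Tensor:
        """Logits tensor from a feature tensor (n, m) or (n, m, B)."""
        if self.attention is not None:
            x = attention_tensor(x, self.attention)
        rep = fractal_forward(x, self.fractal, self.cfg.neuron,
                              drop=self.cfg.drop, rng=rng, training=training,
                              force_column=force_column)
        return _head_tensor(rep, self.head, self.cfg.neuron)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                force_column: int | None = None) -> Tensor:
        """Accepts (n, m) or a batch (B, n, m); returns logits (z,) / (B, z)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            return self.forward_tensor(Tensor(x), training, rng, force_column)
        if x.ndim != 3:
            raise ValueError("input must be (n, m) or (B, n, m)")
        xt = Tensor(np.moveaxis(x, 0, 2))        # (n, m, B)
        logits = self.forward_tensor(xt, training, rng, force_column)
        return logits.transpose(1, 0)            # (B, z)

    def preprocess_input(self, x: np.ndarray) -> np.ndarray:
        """Apply the stored training-fold feature scaling (identity if the
        model carries none)."""
        if self.input_mean is None:
            return np.asarray(x, dtype=np.float64)
        return (np.asarray(x, dtype=np.float64) - self.input_mean) / self.input_std

    def predict(self, x: np.ndarray, force_column: int | None = None) -> Prediction:
        logits = self.forward(x, training=False, force_column=force_column).data
        return Prediction(probs=_softmax(logits), logits=logits)

    # -- checkpointing ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        if self.attention is not None:
            for j, (wq, wk, wv) in enumerate(self.attention.heads):
                arrays[f"attention/head{j}/Wq"] = wq.data
                arrays[f"attention/head{j}/Wk"] = wk.data
                arrays[f"attention/head{j}/Wv"] = wv.data
            arrays["attention/Wio"] = self.attention.w_io.data
        for i, w in enumerate(self.fractal.somas()):
            arrays[f"fractal/soma{i}/W"] = w.data
        arrays["head/W_readout"] = self.head.w_readout.data
        arrays["head/L1_W"] = self.head.l1_w.data
        arrays["head/L1_b"] = self.head.l1_b.data
        arrays["head/L2_W"] = self.head.l2_w.data
        arrays["head/L2_b"] = self.head.l2_b.data
        arrays["head/w_pool"] = self.head.w_pool.data
        return arrays

    def save(self, path: str | Path) -> None:
        """Single-file archive: all weight matrices + the full config."""
        arrays = self.state_arrays()
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        if self.input_mean is not None:
            arrays["scaler/mean"] = self.input_mean
            arrays["scaler/std"] = self.input_std
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FractalSNN":
        with np.load(path) as npz:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(npz["config_json"]).decode()))
            model = cls(cfg)
            arrays = {k: npz[k] for k in npz.files if k != "config_json"}
        if model.attention is not None:
            for j, (wq, wk, wv) in enumerate(model.attention.heads):
                wq.data = arrays[f"attention/head{j}/Wq"]
                wk.data = arrays[f"attention/head{j}/Wk"]
                wv.data = arrays[f"attention/head{j}/Wv"]
            model.attention.w_io.data = arrays["attention/Wio"]
        for i, w in enumerate(model.fractal.somas()):
            w.data = arrays[f"fractal/soma{i}/W"]
        model.head.w_readout.data = arrays["head/W_readout"]
        model.head.l1_w.data = arrays["head/L1_W"]
        model.head.l1_b.data = arrays["head/L1_b"]
        model.head.l2_w.data = arrays["head/L2_W"]
        model.head.l2_b.data = arrays["head/L2_b"]
        model.head.w_pool.data = arrays["head/w_pool"]
        if "scaler/mean" in arrays:
            model.input_mean = arrays["scaler/mean"]
            model.input_std = arrays["scaler/std"]
        return model


def scheme_forward(x: FeatureMatrix | np.ndarray, model: FractalSNN,
                   training: bool = False,
                   rng: np.random.Generator | None = None) -> Prediction:
    """Run the full scheme on one feature matrix; deterministic when not
    training."""
    values = x.values if isinstance(x, FeatureMatrix) else np.asarray(x)
    logits = model.forward(values, training=training, rng=rng).data
    return Prediction(probs=_softmax(logits), logits=logits)
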