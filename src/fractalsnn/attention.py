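"""Per-channel multi-head self-attention over EEG feature vectors.

Each channel's length-``n`` feature vector is split into ``h`` equal parts.
For part ``x`` (length d = n/h) a head computes ``q = Wq x``, ``k = Wk x``,
``v = Wv x`` and returns ``softmax(q k^T / sqrt(d)) v`` where ``q k^T`` is the
d x d outer product and softmax is applied row-wise.  Head outputs are
concatenated and passed through an ``n x n`` output transform ``Wio``.
Channels are processed independently, so the module is equivariant to channel
permutation.  No bias terms anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate
from .features import FeatureMatrix

__all__ = ["AttentionParams", "attention_head", "apply_attention",
           "attention_tensor"]


@dataclass
class AttentionParams:
    """Learnable weights: per-head (Wq, Wk, Wv), each (n/h x n/h), plus Wio."""
    heads: list[tuple[Tensor, Tensor, Tensor]]
    w_io: Tensor

    @property
    def h(self) -> int:
        return len(self.heads)

    @property
    def n(self) -> int:
        return self.w_io.shape[0]

    def tensors(self) -> list[Tensor]:
        out = []
        for wq, wk, wv in self.heads:
            out.extend([wq, wk, wv])
        out.append(self.w_io)
        return out

    @classmethod
    def init(cls, n: int, h: int, rng: np.random.Generator) -> "AttentionParams":
        """Near-identity value/output paths, small Gaussian query/key."""
        if n % h != 0:
            raise ValueError(f"head count {h} must divide feature length {n}")
        d = n // h
        heads = []
        for _ in range(h):
            wq = Tensor(rng.normal(0.0, 0.1 / np.sqrt(d), (d, d)), requires_grad=True)
            wk = Tensor(rng.normal(0.0, 0.1 / np.sqrt(d), (d, d)), requires_grad=True)
            wv = Tensor(np.eye(d) + rng.normal(0.0, 0.01, (d, d)), requires_grad=True)
            heads.append((wq, wk, wv))
        w_io = Tensor(np.eye(n) + rng.normal(0.0, 0.01, (n, n)), requires_grad=True)
        return cls(heads, w_io)


def attention_head(x: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                   wv: np.ndarray, return_weights: bool = False):
    """Scaled dot-product attention for one head on one vector (length d).

    Returns ``A v`` with ``A = rowwise-softmax(q k^T / sqrt(d))``; every row
    of ``A`` sums to 1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = x.size
    q = wq @ x
    k = wk @ x
    v = wv @ x
    scores = np.outer(q, k) / np.sqrt(d)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    a = e / e.sum(axis=1, keepdims=True)
    out = a @ v
    if return_weights:
        return out, a
    return out


def attention_tensor(x: Tensor, params: AttentionParams) -> Tensor:
    """Differentiable attention on a feature tensor (n, m) or (n, m, B)."""
    n = x.shape[0]
    if n != params.n:
        raise ValueError(f"attention built for n={params.n}, got {n}")
    h = params.h
    d = n // h
    batched = x.ndim == 3
    if batched:
        m, b = x.shape[1], x.shape[2]
        cols = x.transpose(1, 2, 0).reshape(m * b, n)   # (C, n)
    else:
        m = x.shape[1]
        cols = x.transpose(1, 0)                        # (C, n)
    c = cols.shape[0]

    outs = []
    for j, (wq, wk, wv) in enumerate(params.heads):
        xh = cols[:, j * d:(j + 1) * d]                 # (C, d)
        q = xh @ wq.transpose(1, 0)
        k = xh @ wk.transpose(1, 0)
        v = xh @ wv.transpose(1, 0)
        scores = (q.reshape(c, d, 1) * k.reshape(c, 1, d)) * (1.0 / np.sqrt(d))
        a = scores.softmax(axis=-1)                     # rows sum to 1
        outs.append((a * v.reshape(c, 1, d)).sum(axis=-1))
    merged = outs[0] if h == 1 else concatenate(outs, axis=1)
    result = merged @ params.w_io.transpose(1, 0)       # (C, n)
    if batched:
        return result.reshape(m, b, n).transpose(2, 0, 1)
    return result.reshape(m, n).transpose(1, 0)


def apply_attention(x: FeatureMatrix | np.ndarray,
                    params: AttentionParams) -> FeatureMatrix | np.ndarray:
    """Non-training convenience wrapper; preserves type and shape (n x m)."""
    if isinstance(x, FeatureMatrix):
        values = attention_tensor(Tensor(x.values), params).data
        return FeatureMatrix(values, list(x.layout), list(x.channel_names))
    return attention_tensor(Tensor(np.asarray(x, dtype=np.float64)), params).data
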