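"""Fractal composition of spiking ops, with inverted drop-path training.

The block of order ``c`` is generated by the expansion rule::

    F_1(X)     = Axon(X)
    F_{c+1}(X) = Sum{ (F_c o Soma o F_c)(X), Axon(X) }

where ``Sum`` is the element-wise sum of its two branches.  The rule yields
``c`` aligned columns (sub-networks) whose Axon-depths are the powers of two
``{2^{k-1} : k = 1..c}``, ``2^{c-1} - 1`` Soma junctions (each with its own
unshared ``n x n`` weight matrix) and ``2^c - 1`` Axon leaves.

At every ``Sum`` layer, **inverted drop-path** randomly deactivates branches
during training: each branch is kept with probability ``1 - p`` and the sum
of survivors is rescaled by ``1/(1-p)``; at test time the plain sum is used
with no scaling.  If all branches are dropped, masks are redrawn so at least
one survives (the redraw guard can be disabled to study unbiasedness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor
from .neuron import NeuronConfig, axon, axon_forward, soma, soma_forward

__all__ = ["DropPathConfig", "FractalNode", "FractalSpec", "build_fractal",
           "enumerate_columns", "inverted_drop_path", "fractal_forward",
           "f2_forward_explicit"]


@dataclass
class DropPathConfig:
    """Drop-path behaviour at the Sum layers.

    ``mode``: "inverted" (train: mask + 1/(1-p) rescale; test: plain sum),
    "plain" (train: mask, no rescale; test: plain sum) or "none" (always the
    plain sum).
    """
    p: float = 0.15
    mode: str = "inverted"

    def __post_init__(self):
        if not (0.0 <= self.p < 1.0):
            raise ValueError("drop probability must be in [0, 1)")
        if self.mode not in ("inverted", "plain", "none"):
            raise ValueError(f"unknown drop-path mode {self.mode!r}")


@dataclass
class FractalNode:
    """Recursive structure: order-1 nodes are Axon leaves; higher orders hold
    the middle Soma weights and the two sub-blocks of the long branch."""
    order: int
    soma_w: Tensor | None = None
    left: "FractalNode | None" = None
    right: "FractalNode | None" = None


@dataclass
class FractalSpec:
    """A built fractal block: nesting order, feature width, structure tree."""
    order: int
    n: int
    root: FractalNode

    def somas(self) -> list[Tensor]:
        """All Soma weight matrices in deterministic (preorder) order."""
        out: list[Tensor] = []

        def visit(node: FractalNode) -> None:
            if node.order > 1:
                visit(node.left)
                out.append(node.soma_w)
                visit(node.right)

        visit(self.root)
        return out

    def count_axons(self) -> int:
        def visit(node: FractalNode) -> int:
            if node.order == 1:
                return 1
            return visit(node.left) + visit(node.right) + 1

        return visit(self.root)

    def count_somas(self) -> int:
        return len(self.somas())

    def count_sums(self) -> int:
        def visit(node: FractalNode) -> int:
            if node.order == 1:
                return 0
            return visit(node.left) + visit(node.right) + 1

        return visit(self.root)


def build_fractal(c: int, n: int, rng: np.random.Generator | None = None,
                  init_scale: float | None = None) -> FractalSpec:
    """Build an ``F_c`` block of width ``n`` with freshly initialised Somas.

    Soma weights are Gaussian with standard deviation ``init_scale``
    (default ``1/sqrt(n)``); every Soma instance is unshared.
    """
    if c < 1:
        raise ValueError("fractal order must be >= 1")
    if n < 1:
        raise ValueError("feature width must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    scale = init_scale if init_scale is not None else 1.0 / np.sqrt(n)

    def expand(order: int) -> FractalNode:
        if order == 1:
            return FractalNode(order=1)
        w = Tensor(rng.normal(0.0, scale, (n, n)), requires_grad=True)
        return FractalNode(order=order, soma_w=w,
                           left=expand(order - 1), right=expand(order - 1))

    return FractalSpec(order=c, n=n, root=expand(c))


def enumerate_columns(spec: FractalSpec) -> list[int]:
    """Axon-depths of the aligned columns, shortest first: ``[2^{k-1}]``."""

    def depths(node: FractalNode) -> list[int]:
        if node.order == 1:
            return [1]
        return [1] + [2 * d for d in depths(node.left)]

    return depths(spec.root)


def inverted_drop_path(inputs: Sequence, p: float,
                       rng: np.random.Generator | None = None,
                       training: bool = True,
                       redraw_guard: bool = True,
                       scale: bool = True,
                       mask: np.ndarray | None = None):
    """Combine branch outputs at a Sum layer.

    Training: draw an independent Bernoulli keep-mask (keep prob ``1-p``) per
    branch, redraw while all are dropped (unless ``redraw_guard`` is off),
    and return the sum of kept branches divided by ``1-p`` (``scale=False``
    reproduces the original drop-path, which does not rescale).  Testing:
    plain unscaled sum.  Accepts Tensors or plain arrays.
    """
    if len(inputs) == 0:
        raise ValueError("Sum layer needs at least one input")
    if not (0.0 <= p < 1.0):
        raise ValueError("drop probability must be in [0, 1)")

    def plain_sum(xs):
        out = xs[0]
        for x in xs[1:]:
            out = out + x
        return out

    if not training or p == 0.0:
        return plain_sum(list(inputs))

    if mask is None:
        if rng is None:
            raise ValueError("training-time drop-path needs an rng")
        mask = rng.random(len(inputs)) >= p
        if redraw_guard:
            while not mask.any():
                mask = rng.random(len(inputs)) >= p
    else:
        mask = np.asarray(mask, dtype=bool)

    kept = [x for x, keep in zip(inputs, mask) if keep]
    if not kept:
        z = inputs[0] * 0.0
        return z
    combined = plain_sum(kept)
    if scale:
        combined = combined * (1.0 / (1.0 - p))
    return combined


def fractal_forward(x: Tensor, spec: FractalSpec, cfg: NeuronConfig,
                    drop: DropPathConfig | None = None,
                    rng: np.random.Generator | None = None,
                    training: bool = False,
                    force_column: int | None = None,
                    mask_fn: Callable[[int], np.ndarray] | None = None) -> Tensor:
    """Evaluate the block on (n, m[, batch]) input.

    ``force_column=k`` evaluates only the sub-network of depth ``2^{k-1}``
    (k=1 is the shortest column), synchronising the choice at every Sum.
    ``mask_fn`` overrides the random masks (for analysis), called with the
    branch count at each training-time Sum layer.
    """
    x = Tensor._as_tensor(x)
    if x.shape[0] != spec.n:
        raise ValueError(f"block built for n={spec.n}, got {x.shape[0]}")
    drop = drop if drop is not None else DropPathConfig(mode="none", p=0.0)
    if force_column is not None and not (1 <= force_column <= spec.order):
        raise ValueError(f"column must be in 1..{spec.order}")

    def run(node: FractalNode, inp: Tensor, col: int | None) -> Tensor:
        if node.order == 1:
            return axon(inp, cfg)
        if col is not None:
            if col == 1:
                return axon(inp, cfg)
            inner = run(node.left, inp, col - 1)
            spiked = soma(inner, node.soma_w, cfg)
            return run(node.right, spiked, col - 1)
        inner = run(node.left, inp, None)
        spiked = soma(inner, node.soma_w, cfg)
        long_branch = run(node.right, spiked, None)
        short_branch = axon(inp, cfg)
        branches = [long_branch, short_branch]
        if drop.mode == "none" or not training:
            return inverted_drop_path(branches, 0.0, training=False)
        mask = mask_fn(len(branches)) if mask_fn is not None else None
        return inverted_drop_path(branches, drop.p, rng=rng, training=True,
                                  scale=(drop.mode == "inverted"), mask=mask)

    return run(spec.root, x, force_column)


def f2_forward_explicit(x: np.ndarray, w_bd: np.ndarray,
                        cfg: NeuronConfig) -> np.ndarray:
    """Hand-coded order-2 forward, straight from the difference equations.

    Path-1 (long): Axon -> Soma(W_BD) -> Axon; Path-2 (short): Axon.  The
    output is the element-wise sum of both paths.  Serves as the independent
    oracle for the generic builder.
    """
    x = np.asarray(x, dtype=np.float64)
    o_b = axon_forward(x, cfg)                 # Path-1: first Axon
    x_d = soma_forward(o_b, w_bd, cfg)         # Path-1: Soma spikes
    o_d = axon_forward(x_d, cfg)               # Path-1: second Axon
    o_b_short = axon_forward(x, cfg)           # Path-2
    return o_d + o_b_short
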