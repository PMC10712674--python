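"""Spiking primitives: the Axon synapse filter and the Soma neuron body.

The neuron model is written as linear constant-coefficient difference
equations (an IIR formulation).  The recurrence index runs over the **EEG
channel axis** ``i = 1..m`` — channels play the role of sequence steps, and
the ``n`` feature rows index synapses/neurons.

* ``Axon``: each synapse filters its own channel sequence with the
  second-order filter ``f[i] = a1*f[i-1] + a2*f[i-2] + b*x[i]`` where
  ``a1 = e^{-1/tau_m} + e^{-1/tau_s}``, ``a2 = -e^{-(tau_m+tau_s)/(tau_m tau_s)}``
  and ``b = e^{-1/tau_m} - e^{-1/tau_s}``.  Its impulse response is
  ``e^{-i/tau_m} - e^{-i/tau_s}``, a difference of exponentials.
* ``Soma``: per channel step, membrane potential
  ``v[i] = -lambda*r~[i] + W f[i]``, a strict Heaviside spike
  ``y[i] = 1 iff v[i] > V_thre``, and a decaying reset filter
  ``r[i] = e^{-1/tau_r} r[i-1] + V_rest y[i]``.  The printed equations are
  circular in ``r[i]``; we sequence decay -> potential -> spike ->
  reset-increment, which honours both one half-step apart.

Training uses a triangular surrogate derivative for the Heaviside step.
Filter and reset states are zero-initialised at every forward pass (the
channel axis restarts with every EEG sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .autodiff import Tensor

__all__ = [
    "NeuronConfig", "derive_coefficients", "heaviside", "surrogate_grad",
    "axon_forward", "soma_forward", "axon", "soma",
]


def derive_coefficients(tau_m: float, tau_s: float) -> tuple[float, float, float]:
    """Filter coefficients (alpha1, alpha2, beta) from the two time constants.

    With ``a = e^{-1/tau_m}`` and ``b = e^{-1/tau_s}``:
    ``alpha1 = a + b``, ``alpha2 = -a*b`` and ``beta = a - b``.
    Equal time constants give a dead filter (beta = 0) and are rejected.
    """
    if tau_m <= 0 or tau_s <= 0:
        raise ValueError("time constants must be positive")
    if tau_m == tau_s:
        raise ValueError("tau_m == tau_s makes beta = 0 (dead filter)")
    a = np.exp(-1.0 / tau_m)
    b = np.exp(-1.0 / tau_s)
    return a + b, -np.exp(-(tau_m + tau_s) / (tau_m * tau_s)), a - b


@dataclass
class NeuronConfig:
    """Fixed spiking hyperparameters shared by every Axon/Soma instance.

    Time constants are in channel-steps.  Only synaptic weight matrices are
    learnable; these constants are settings.
    """
    tau_m: float = 8.0
    tau_s: float = 2.0
    tau_r: float = 2.0
    lam: float = 1.0          # reset coupling (lambda >= 0)
    v_thre: float = 0.0       # firing threshold (around 0 works best)
    v_rest: float = 1.0       # reset increment per spike
    surrogate_width: float = 1.0

    def __post_init__(self):
        if min(self.tau_m, self.tau_s, self.tau_r) <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_m == self.tau_s:
            raise ValueError("tau_m must differ from tau_s")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.surrogate_width <= 0:
            raise ValueError("surrogate width must be positive")

    @property
    def a(self) -> float:
        return float(np.exp(-1.0 / self.tau_m))

    @property
    def b(self) -> float:
        return float(np.exp(-1.0 / self.tau_s))

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return derive_coefficients(self.tau_m, self.tau_s)

    @property
    def reset_decay(self) -> float:
        return float(np.exp(-1.0 / self.tau_r))

    def to_dict(self) -> dict:
        return {"tau_m": self.tau_m, "tau_s": self.tau_s, "tau_r": self.tau_r,
                "lam": self.lam, "v_thre": self.v_thre, "v_rest": self.v_rest,
                "surrogate_width": self.surrogate_width}


def heaviside(x: np.ndarray) -> np.ndarray:
    """Strict step: 1 where x > 0, else 0 (U(0) := 0)."""
    return (np.asarray(x) > 0).astype(np.float64)


def surrogate_grad(x: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Triangular surrogate derivative ``max(0, 1 - |x|/w) / w``."""
    return np.maximum(0.0, 1.0 - np.abs(x) / width) / width


# ---------------------------------------------------------------------------
# numpy cores (shared by forward ops, oracles and tests)
# ---------------------------------------------------------------------------

def axon_forward(x: np.ndarray, cfg: NeuronConfig, axis: int = 1) -> np.ndarray:
    """Run the second-order synapse filter along ``axis`` (zero initial state)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite input to Axon")
    a1, a2, b = cfg.coefficients
    return sps.lfilter([b], [1.0, -a1, -a2], x, axis=axis)


def soma_forward(f: np.ndarray, w: np.ndarray, cfg: NeuronConfig,
                 return_trace: bool = False):
    """Membrane update / threshold firing / reset filter, stepping channels.

    ``f`` is (in_rows, m[, batch]); ``w`` is (out_rows, in_rows).  Returns the
    strictly binary spike array (out_rows, m[, batch]) and, optionally, the
    membrane-potential trace.
    """
    f = np.asarray(f, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if f.shape[0] != w.shape[1]:
        raise ValueError(f"weight shape {w.shape} does not accept input rows "
                         f"{f.shape[0]}")
    m = f.shape[1]
    out_shape = (w.shape[0],) + f.shape[1:]
    spikes = np.zeros(out_shape)
    trace = np.zeros(out_shape)
    r = np.zeros((w.shape[0],) + f.shape[2:])
    decay = cfg.reset_decay
    for i in range(m):
        r = decay * r                                   # decayed reset
        v = -cfg.lam * r + np.tensordot(w, f[:, i], axes=(1, 0))
        y = heaviside(v - cfg.v_thre)                   # strict inequality
        r = r + cfg.v_rest * y                          # reset increment
        spikes[:, i] = y
        trace[:, i] = v
    if return_trace:
        return spikes, trace
    return spikes


# ---------------------------------------------------------------------------
# autodiff ops
# ---------------------------------------------------------------------------

def axon(x: Tensor, cfg: NeuronConfig) -> Tensor:
    """Axon as a differentiable op (linear; adjoint = time-reversed filter)."""
    x = Tensor._as_tensor(x)
    out = axon_forward(x.data, cfg, axis=1)
    a1, a2, b = cfg.coefficients

    def back(g: np.ndarray) -> np.ndarray:
        rev = np.flip(g, axis=1)
        filt = sps.lfilter([b], [1.0, -a1, -a2], rev, axis=1)
        return np.flip(filt, axis=1)

    return Tensor.from_op(out, [(x, back)])


def soma(f: Tensor, w: Tensor, cfg: NeuronConfig) -> Tensor:
    """Soma as a differentiable op.

    Forward emits strict binary spikes; backward substitutes the triangular
    surrogate for the Heaviside derivative and backpropagates through the
    reset recurrence.
    """
    f = Tensor._as_tensor(f)
    w = Tensor._as_tensor(w)
    spikes, trace = soma_forward(f.data, w.data, cfg, return_trace=True)
    m = f.data.shape[1]
    decay = cfg.reset_decay
    sg = surrogate_grad(trace - cfg.v_thre, cfg.surrogate_width)

    def back_pair(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        df = np.zeros_like(f.data)
        dw = np.zeros_like(w.data)
        acc = np.zeros(g.shape[:1] + g.shape[2:])   # dL/dr[i]
        for i in range(m - 1, -1, -1):
            dy = g[:, i] + cfg.v_rest * acc
            dv = dy * sg[:, i]
            dr_tilde = acc - cfg.lam * dv
            if dv.ndim == 1:
                dw += np.outer(dv, f.data[:, i])
            else:   # batch: sum outer products over trailing axes
                dw += np.tensordot(dv, f.data[:, i],
                                   axes=(tuple(range(1, dv.ndim)),) * 2)
            df[:, i] = np.tensordot(w.data.T, dv, axes=(1, 0))
            acc = decay * dr_tilde
        return df, dw

    # cache the shared backward computation between the two edges (keyed by
    # object identity; the stored reference keeps the keying array alive)
    cache: list = []

    def _get(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not (cache and cache[0] is g):
            df, dw = back_pair(g)
            cache[:] = [g, df, dw]
        return cache[1], cache[2]

    def back_f(g: np.ndarray) -> np.ndarray:
        return _get(g)[0]

    def back_w(g: np.ndarray) -> np.ndarray:
        return _get(g)[1]

    return Tensor.from_op(spikes, [(f, back_f), (w, back_w)])
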