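"""Spiking primitives: filter coefficients, Axon recurrence, Soma dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fractalsnn.autodiff import Tensor
from fractalsnn.neuron import (NeuronConfig, axon, axon_forward,
                               derive_coefficients, heaviside, soma,
                               soma_forward, surrogate_grad)

TAU = st.floats(0.2, 20.0)


def test_coefficients_worked_example():
    """tau_m = 1/ln2, tau_s = 1/ln4 give a = 1/2, b = 1/4."""
    a1, a2, b = derive_coefficients(1 / np.log(2), 1 / np.log(4))
    assert a1 == pytest.approx(0.75, abs=1e-12)
    assert a2 == pytest.approx(-0.125, abs=1e-12)
    assert b == pytest.approx(0.25, abs=1e-12)


def test_equal_time_constants_rejected():
    with pytest.raises(ValueError):
        derive_coefficients(2.0, 2.0)
    with pytest.raises(ValueError):
        NeuronConfig(tau_m=3.0, tau_s=3.0)


@given(tau_m=TAU, tau_s=TAU)
def test_alpha2_is_negative_product_of_decays(tau_m, tau_s):
    """alpha2 = -a*b with a = e^{-1/tau_m}, b = e^{-1/tau_s}."""
    if tau_m == tau_s:
        return
    _, a2, _ = derive_coefficients(tau_m, tau_s)
    a, b = np.exp(-1 / tau_m), np.exp(-1 / tau_s)
    assert a2 == pytest.approx(-a * b, rel=1e-12)


def test_axon_impulse_hand_recurrence():
    cfg = NeuronConfig(tau_m=1 / np.log(2), tau_s=1 / np.log(4))
    x = np.zeros((1, 5)); x[0, 0] = 1.0
    f = axon_forward(x, cfg)
    assert np.allclose(f[0, :3], [0.25, 0.1875, 0.109375], atol=1e-12)


@pytest.mark.parametrize("tau_m, tau_s", [(8.0, 2.0), (3.7, 0.9), (15.0, 1.1)])
def test_axon_impulse_matches_closed_form(tau_m, tau_s):
    """Impulse response at step i is e^{-i/tau_m} - e^{-i/tau_s}."""
    cfg = NeuronConfig(tau_m=tau_m, tau_s=tau_s)
    x = np.zeros((1, 64)); x[0, 0] = 1.0
    f = axon_forward(x, cfg)[0]
    i = np.arange(1, 65)
    closed = np.exp(-i / tau_m) - np.exp(-i / tau_s)
    assert np.abs(f - closed).max() < 1e-9


@given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 50))
def test_axon_linearity(a, b, seed):
    cfg = NeuronConfig()
    r = np.random.default_rng(seed)
    x, y = r.normal(size=(2, 7)), r.normal(size=(2, 7))
    lhs = axon_forward(a * x + b * y, cfg)
    rhs = a * axon_forward(x, cfg) + b * axon_forward(y, cfg)
    assert np.abs(lhs - rhs).max() < 1e-9


def test_axon_zero_input_and_nonfinite_rejection():
    cfg = NeuronConfig()
    assert np.array_equal(axon_forward(np.zeros((3, 6)), cfg), np.zeros((3, 6)))
    with pytest.raises(FloatingPointError):
        axon_forward(np.array([[np.nan, 0.0]]), cfg)


# ---------------------------------------------------------------------------
# Soma
# ---------------------------------------------------------------------------

def test_soma_hand_recurrence_worked_example():
    """One neuron, W=1, lambda=1, tau_r=1, V_rest=1, V_thre=0 fed 0.5s:
    spikes [1,1,0] with membrane ~ (0.5, 0.1321, -0.0032)."""
    cfg = NeuronConfig(tau_m=8, tau_s=2, tau_r=1.0, lam=1.0, v_thre=0.0,
                       v_rest=1.0)
    spikes, trace = soma_forward(np.array([[0.5, 0.5, 0.5]]),
                                 np.array([[1.0]]), cfg, return_trace=True)
    assert np.array_equal(spikes, [[1.0, 1.0, 0.0]])
    e = np.exp(-1.0)
    assert np.allclose(trace, [[0.5, 0.5 - e, 0.5 - e * (1 + e)]], atol=1e-10)


def test_soma_without_reset_coupling_is_memoryless(rng):
    """lambda = 0 decouples channel steps: y = step(W f - V_thre)."""
    cfg = NeuronConfig(lam=0.0, v_thre=0.3)
    f = rng.normal(size=(4, 9))
    w = rng.normal(size=(5, 4))
    spikes = soma_forward(f, w, cfg)
    assert np.array_equal(spikes, heaviside(w @ f - 0.3))


def test_soma_zero_input_zero_threshold_no_spikes():
    """Firing is strict: v = 0 is not > 0."""
    cfg = NeuronConfig(v_thre=0.0)
    spikes = soma_forward(np.zeros((3, 5)), np.ones((2, 3)), cfg)
    assert spikes.sum() == 0


def test_soma_output_strictly_binary_and_trace_finite(rng):
    cfg = NeuronConfig()
    spikes, trace = soma_forward(rng.normal(size=(6, 12, 4)),
                                 rng.normal(size=(6, 6)), cfg,
                                 return_trace=True)
    assert set(np.unique(spikes)) <= {0.0, 1.0}
    assert np.isfinite(trace).all()


def test_spike_count_nonincreasing_in_threshold(rng):
    f = rng.normal(size=(5, 20))
    w = rng.normal(size=(5, 5))
    counts = []
    for thre in [-1.0, -0.5, 0.0, 0.5, 1.0, 2.0]:
        cfg = NeuronConfig(v_thre=thre)
        counts.append(soma_forward(f, w, cfg).sum())
    assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# surrogate gradient
# ---------------------------------------------------------------------------

def test_heaviside_strict_at_zero():
    assert heaviside(np.array([0.0]))[0] == 0.0
    assert heaviside(np.array([1e-12]))[0] == 1.0


@pytest.mark.parametrize("width", [0.5, 1.0, 2.0])
def test_surrogate_triangle(width):
    assert surrogate_grad(np.array([0.0]), width)[0] == pytest.approx(1 / width)
    assert surrogate_grad(np.array([width]), width)[0] == 0.0
    assert surrogate_grad(np.array([-2 * width]), width)[0] == 0.0


def test_soma_gradients_flow_and_are_not_identically_zero(rng):
    f = Tensor(rng.normal(size=(4, 10)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
    out = soma(f, w, NeuronConfig())
    out.sum().backward()
    assert np.isfinite(w.grad).all() and np.isfinite(f.grad).all()
    assert np.abs(w.grad).max() > 0


def test_axon_op_gradient_matches_finite_difference(rng):
    """The adjoint (time-reversed) filter is the exact gradient."""
    cfg = NeuronConfig()
    x0 = rng.normal(size=(2, 6))
    coeffs = rng.normal(size=(2, 6))

    def value(xd):
        return float((axon_forward(xd, cfg) * coeffs).sum())

    x = Tensor(x0, requires_grad=True)
    (axon(x, cfg) * Tensor(coeffs)).sum().backward()
    eps = 1e-6
    for idx in [(0, 0), (1, 3), (0, 5)]:
        xp = x0.copy(); xp[idx] += eps
        xm = x0.copy(); xm[idx] -= eps
        num = (value(xp) - value(xm)) / (2 * eps)
        assert x.grad[idx] == pytest.approx(num, abs=1e-6)
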