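"""Neuron, synapse and steady-state dynamics tests."""

import math
from collections import deque

import numpy as np
import pytest

from wormtaxis.circuit import (
    ChemicalSynapse,
    CircuitParameters,
    CircuitState,
    GapJunction,
    NeuronParams,
    SensoryParams,
    T_CYCLE,
    oscillatory_drive,
    sensory_response,
    sigmoid_output,
    ssio_curve,
    step_network,
)

DT = 0.01


# --------------------------------------------------------------------------
# sensory dynamics


def step_history(s, j, n_n, n_m):
    """History with the last j samples at concentration s, zeros before."""
    total = n_n + n_m
    j = min(j, total)
    return [0.0] * (total - j) + [s] * j


def ramp_value(s, j, n_n, n_m):
    """Closed-form response of the differential operator to a sustained
    step of size s present in the last j samples: linear rise to a peak
    of s when the recent window fills (j = n_n), linear decay back to
    zero when the reference window fills too (j = n_n + n_m)."""
    recent = s * min(j, n_n) / n_n
    past = s * min(max(j - n_n, 0), n_m) / n_m
    return max(0.0, recent - past)


@pytest.mark.parametrize("s", [0.005, 0.02, -0.003])
def test_on_cell_step_response_matches_closed_form(s):
    p = SensoryParams(N=1.0, M=1.0, polarity="ON")
    n_n = n_m = round(1.0 / DT)
    for j in range(1, n_n + n_m + 50):
        h = step_history(s, j, n_n, n_m)
        expected = ramp_value(s, j, n_n, n_m)
        assert sensory_response(h, p, DT) == pytest.approx(expected, abs=1e-9)
    # peak exactly the step magnitude at t0 + N, zero at t0 + N + M
    if s > 0:
        assert sensory_response(step_history(s, n_n, n_n, n_m), p, DT) == pytest.approx(s, abs=1e-9)
        assert sensory_response(step_history(s, n_n + n_m, n_n, n_m), p, DT) == pytest.approx(0.0, abs=1e-9)


def test_asymmetric_rise_and_decay_windows():
    p = SensoryParams(N=0.5, M=2.0, polarity="ON")
    n_n, n_m = round(0.5 / DT), round(2.0 / DT)
    for j in (1, n_n, n_n + 37, n_n + n_m):
        h = step_history(0.01, j, n_n, n_m)
        assert sensory_response(h, p, DT) == pytest.approx(
            ramp_value(0.01, j, n_n, n_m), abs=1e-9
        )


def test_off_cell_rectifies_upsteps_and_sees_downsteps():
    p_off = SensoryParams(N=1.0, M=1.0, polarity="OFF")
    n = round(1.0 / DT)
    up = step_history(0.005, n, n, n)
    assert sensory_response(up, p_off, DT) == 0.0
    down = [0.005] * n + [0.0] * n  # recent window lower than reference
    assert sensory_response(down, p_off, DT) == pytest.approx(0.005, abs=1e-9)


def test_constant_concentration_silences_both_polarities():
    for pol in ("ON", "OFF"):
        p = SensoryParams(N=0.7, M=1.3, polarity=pol)
        h = [0.42] * (round(0.7 / DT) + round(1.3 / DT))
        assert sensory_response(h, p, DT) == pytest.approx(0.0, abs=1e-12)


def test_insufficient_history_names_required_span():
    p = SensoryParams(N=1.0, M=1.0, polarity="ON")
    with pytest.raises(ValueError, match="2.0"):
        sensory_response([0.0] * 10, p, DT)


# --------------------------------------------------------------------------
# sigmoid and oscillator


def test_sigmoid_midpoint_shift_and_value():
    assert sigmoid_output(0.0, 0.0) == 0.5
    assert sigmoid_output(-3.7, 3.7) == 0.5
    assert sigmoid_output(1.0, 0.0) == pytest.approx(0.7310585786300049, abs=1e-12)
    assert 0.0 < sigmoid_output(-30.0, 0.0) < sigmoid_output(30.0, 0.0) < 1.0


def test_oscillator_period_and_antiphase():
    assert oscillatory_drive(0.0, "dorsal") == 0.0
    assert oscillatory_drive(T_CYCLE / 4, "dorsal") == pytest.approx(1.0)
    assert oscillatory_drive(T_CYCLE / 4, "ventral") == pytest.approx(-1.0)
    for t in np.linspace(0, 3 * T_CYCLE, 50):
        assert oscillatory_drive(t, "dorsal") + oscillatory_drive(t, "ventral") == pytest.approx(0.0, abs=1e-12)
    assert oscillatory_drive(T_CYCLE, "dorsal") == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------------
# network stepping (reference implementation)


def single_neuron(tau=1.0, theta=0.0, w_self=0.0):
    return CircuitParameters(
        sensory={}, neurons={"X": NeuronParams(tau=tau, theta=theta, w_self=w_self)},
        chem=(), gaps=(),
    )


def make_state(y, t=0.0):
    return CircuitState(y=dict(y), history=deque(maxlen=500), t=t)


def test_pure_leak_step():
    state = make_state({"X": 1.0})
    step_network(state, single_neuron(tau=1.0), c_now=0.0, dt=0.01)
    assert state.y["X"] == pytest.approx(0.99, abs=1e-15)
    assert state.t == pytest.approx(0.01)


def test_zero_state_with_zero_input_is_fixed_point():
    params = CircuitParameters(
        sensory={},
        neurons={"A": NeuronParams(tau=1.0, theta=0.0), "B": NeuronParams(tau=2.0, theta=0.0)},
        chem=(), gaps=(GapJunction("A", "B", 3.0),),
    )
    state = make_state({"A": 0.0, "B": 0.0})
    for _ in range(10):
        step_network(state, params, c_now=0.0, dt=0.01)
    assert state.y == {"A": 0.0, "B": 0.0}


def test_gap_currents_are_antisymmetric():
    g = 2.5
    params = CircuitParameters(
        sensory={},
        neurons={"A": NeuronParams(tau=1.0, theta=0.0), "B": NeuronParams(tau=1.0, theta=0.0)},
        chem=(), gaps=(GapJunction("A", "B", g),),
    )
    y0 = {"A": 0.8, "B": -0.3}
    state = make_state(dict(y0))
    step_network(state, params, c_now=0.0, dt=0.01)
    # recover the net input from the Euler update: net = (y' - y(1 - dt/tau)) * tau/dt
    net_a = (state.y["A"] - y0["A"] * 0.99) / 0.01
    net_b = (state.y["B"] - y0["B"] * 0.99) / 0.01
    assert net_a == pytest.approx(g * (y0["B"] - y0["A"]), abs=1e-12)
    assert net_b == pytest.approx(-net_a, abs=1e-12)


def test_gap_current_sum_is_exactly_zero_along_trajectory(random_circuit):
    rng = np.random.default_rng(3)
    y = {n: float(rng.normal()) for n in random_circuit.neurons}
    state = CircuitState(y=y, history=deque([0.0] * 1000, maxlen=1000), t=0.0)
    for k in range(200):
        total = 0.0
        for gj in random_circuit.gaps:
            total += gj.g * (state.y[gj.b] - state.y[gj.a])
            total += gj.g * (state.y[gj.a] - state.y[gj.b])
        assert total == 0.0
        step_network(state, random_circuit, c_now=0.001 * math.sin(0.05 * k), dt=DT)


def test_nonfinite_state_raises_with_neuron_name():
    params = single_neuron(tau=1.0)
    state = make_state({"X": float("nan")})
    with pytest.raises(FloatingPointError, match="X"):
        step_network(state, params, c_now=0.0, dt=0.01)


def test_activations_bounded_for_bounded_input(random_circuit):
    state = CircuitState(
        y={n: 0.0 for n in random_circuit.neurons},
        history=deque([0.0] * 1000, maxlen=1000), t=0.0,
    )
    for k in range(2000):
        step_network(state, random_circuit, c_now=0.01 * math.sin(0.01 * k), dt=DT)
    bound = 15 * 12 + 15  # crude bound from weight ranges
    assert all(abs(v) < bound for v in state.y.values())


# --------------------------------------------------------------------------
# steady-state input-output curves


def brute_force_fixed_points(w_self, theta, I, lo=-40.0, hi=40.0, step=1e-3):
    """Oracle: dense scan + bisection for roots of w*sigma(y+theta)+I-y."""

    def f(y):
        return w_self * sigmoid_output(y, theta) + I - y

    roots = []
    y = lo
    fy = f(y)
    while y < hi:
        y2 = y + step
        fy2 = f(y2)
        if fy == 0.0:
            roots.append(y)
        if (fy < 0) != (fy2 < 0):
            a, b = y, y2
            for _ in range(80):
                m = 0.5 * (a + b)
                if (f(a) < 0) == (f(m) < 0):
                    a = m
                else:
                    b = m
            roots.append(0.5 * (a + b))
        y, fy = y2, fy2
    return roots


def test_ssio_no_self_connection_gives_logistic():
    p = NeuronParams(tau=1.0, theta=0.0, w_self=0.0)
    [(I, sols)] = ssio_curve(p, [0.0])
    assert I == 0.0 and len(sols) == 1
    out, stable = sols[0]
    assert out == pytest.approx(0.5) and stable


@pytest.mark.parametrize("w_self", [0.5, 2.0, 3.9])
def test_ssio_unistable_below_threshold(w_self):
    p = NeuronParams(tau=1.0, theta=-1.0, w_self=w_self)
    for I, sols in ssio_curve(p, np.linspace(-10, 10, 41)):
        assert len(sols) == 1
        assert sols[0][1]  # stable


def test_ssio_three_fixed_points_match_dense_scan():
    p = NeuronParams(tau=1.0, theta=-3.0, w_self=6.0)
    curve = ssio_curve(p, np.linspace(-1.5, 1.5, 13))
    found_tristable = False
    for I, sols in curve:
        oracle = brute_force_fixed_points(6.0, -3.0, I)
        assert len(sols) == len(oracle)
        for (out, _), y_star in zip(sols, sorted(oracle)):
            assert out == pytest.approx(sigmoid_output(y_star, -3.0), abs=1e-6)
        if len(sols) == 3:
            found_tristable = True
            stabilities = [s for _, s in sols]
            assert stabilities == [True, False, True]
    assert found_tristable


def test_bistability_onset_at_self_weight_four():
    """In the symmetric case theta = -w/2 the fixed-point count at I = 0
    flips from 1 to 3 as the self-weight crosses the logistic slope
    bound of 4."""
    for w in (1.0, 3.0, 3.99, 4.0):
        [(_, sols)] = ssio_curve(NeuronParams(1.0, theta=-w / 2, w_self=w), [0.0])
        assert len(sols) == 1, f"w_self={w}"
    for w in (4.05, 4.5, 6.0, 10.0):
        [(_, sols)] = ssio_curve(NeuronParams(1.0, theta=-w / 2, w_self=w), [0.0])
        assert len(sols) == 3, f"w_self={w}"


# --------------------------------------------------------------------------
# parameter containers


def test_chemical_synapse_rejects_self_loop():
    with pytest.raises(ValueError):
        ChemicalSynapse("A", "A", 1.0)


def test_gap_junction_rejects_negative_conductance():
    with pytest.raises(ValueError):
        GapJunction("A", "B", -0.1)


def test_circuit_validates_edges_and_ablation_names(random_circuit):
    with pytest.raises(KeyError):
        CircuitParameters(
            sensory={}, neurons={"A": NeuronParams(1.0, 0.0)},
            chem=(ChemicalSynapse("A", "B", 1.0),), gaps=(),
        )
    with pytest.raises(KeyError):
        random_circuit.ablate("NOSUCH")
    with pytest.raises(KeyError):
        random_circuit.block_gap("AIYL", "SMBDL")
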