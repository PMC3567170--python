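"""Neuron, synapse and gap-junction dynamics of the klinotaxis circuit.

The circuit has three stages:

* **Chemosensors** (ASEL = ON cell, ASER = OFF cell) respond to the
  recent history of attractant concentration through a differential
  operator: the mean concentration over the last ``N`` seconds minus the
  mean over the ``M`` seconds before that, rectified at zero (the OFF
  cell uses the negated difference).  ``N`` and ``M`` act as rise and
  decay times: a sustained concentration step of size ``s`` produces a
  linear rise to a peak of ``s`` at ``t0 + N`` and a linear decay back
  to zero at ``t0 + N + M``.

* **Interneurons** (AIY, AIZ pairs) are passive isopotential nodes:

  ``tau * dy/dt = -y + sum_chem w * sigma(y_pre + theta_pre)
  + sum_gap g * (y_other - y_self) + I_ext``

  where ``y`` is membrane potential relative to rest and
  ``sigma(x) = 1 / (1 + exp(-x))`` is the synaptic transfer function.
  Gap junctions are nonrectifying conductances, symmetric in both
  directions.

* **Neck motor neurons** (SMB dorsal/ventral, left/right) follow the
  same equation plus a self-connection ``w_self * sigma(y + theta)``
  (graded regenerative currents) and an oscillatory drive
  ``w_osc * sin(2 pi t / T)`` with the head-sweep period ``T = 4.2 s``;
  ventral cells receive the drive in anti-phase.

Sensory activations feed the downstream chemical-synapse sum directly
as presynaptic outputs (the rectified differential response *is* the
cell's output); set ``sensors_through_sigmoid=True`` on
:func:`step_network` to route them through the logistic instead.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

T_CYCLE = 4.2  #: locomotion cycle period, seconds
DT_DEFAULT = 0.01  #: forward-Euler time step, seconds

__all__ = [
    "T_CYCLE",
    "DT_DEFAULT",
    "SensoryParams",
    "NeuronParams",
    "ChemicalSynapse",
    "GapJunction",
    "CircuitParameters",
    "CircuitState",
    "sensory_response",
    "sigmoid_output",
    "oscillatory_drive",
    "step_network",
    "ssio_curve",
]


def sigmoid_output(y: float, theta: float) -> float:
    """Synaptic output sigma(y + theta), the standard logistic."""
    x = y + theta
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def oscillatory_drive(t: float, side: str) -> float:
    """Head-sweep oscillation, dorsal = sin(2 pi t / T), ventral anti-phase."""
    s = math.sin(2.0 * math.pi * t / T_CYCLE)
    if side == "dorsal":
        return s
    if side == "ventral":
        return -s
    raise ValueError(f"side must be 'dorsal' or 'ventral', got {side!r}")


@dataclass(frozen=True)
class SensoryParams:
    """ON/OFF chemosensor: rise time N, decay time M (seconds)."""

    N: float
    M: float
    polarity: str = "ON"

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError(f"polarity must be ON or OFF, got {self.polarity!r}")
        if self.N <= 0 or self.M <= 0:
            raise ValueError("N and M must be positive")


@dataclass(frozen=True)
class NeuronParams:
    """Passive node parameters; w_self and w_osc are zero for interneurons."""

    tau: float
    theta: float
    w_self: float = 0.0
    w_osc: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class ChemicalSynapse:
    pre: str
    post: str
    w: float

    def __post_init__(self) -> None:
        if self.pre == self.post:
            raise ValueError(
                f"self-connection {self.pre} must go through NeuronParams.w_self"
            )


@dataclass(frozen=True)
class GapJunction:
    """Nonrectifying electrical coupling with conductance g >= 0."""

    a: str
    b: str
    g: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"gap conductance must be >= 0, got {self.g}")

    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class CircuitParameters:
    """Complete parameter set of a klinotaxis circuit.

    ``sensory`` maps sensor names to :class:`SensoryParams`; ``neurons``
    maps state-neuron names to :class:`NeuronParams`.  ``ablated`` names
    cells whose output is clamped to zero and whose activation is held
    at rest (simulated laser ablation).  ``provenance`` carries seed /
    configuration metadata from the run that produced the parameters.
    """

    sensory: dict[str, SensoryParams]
    neurons: dict[str, NeuronParams]
    chem: tuple[ChemicalSynapse, ...]
    gaps: tuple[GapJunction, ...]
    w_nmj: float = 1.0
    ablated: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        known = set(self.sensory) | set(self.neurons)
        for syn in self.chem:
            if syn.pre not in known or syn.post not in known:
                raise KeyError(f"chemical synapse {syn.pre}->{syn.post} references unknown neuron")
            if syn.post in self.sensory:
                raise ValueError(f"sensor {syn.post} cannot be postsynaptic")
        for gj in self.gaps:
            if gj.a not in self.neurons or gj.b not in self.neurons:
                raise KeyError(f"gap junction {gj.a}-{gj.b} references unknown neuron")
        for name in self.ablated:
            if name not in known:
                raise KeyError(f"cannot ablate unknown neuron {name!r}")

    def motor_names(self) -> list[str]:
        return [n for n in self.neurons if n.startswith("SMB")]

    def osc_sign(self, name: str) -> float:
        """+1 for dorsal motor neurons, -1 for ventral, 0 otherwise."""
        if name.startswith("SMBD"):
            return 1.0
        if name.startswith("SMBV"):
            return -1.0
        return 0.0

    def ablate(self, neuron: str) -> "CircuitParameters":
        if neuron not in set(self.sensory) | set(self.neurons):
            raise KeyError(f"unknown neuron {neuron!r}")
        return replace(self, ablated=self.ablated | {neuron})

    def block_gap(self, a: str, b: str) -> "CircuitParameters":
        pair = (a, b) if a <= b else (b, a)
        if pair not in {gj.pair() for gj in self.gaps}:
            raise KeyError(f"no gap junction between {a} and {b}")
        new_gaps = tuple(
            replace(gj, g=0.0) if gj.pair() == pair else gj for gj in self.gaps
        )
        return replace(self, gaps=new_gaps)


@dataclass
class CircuitState:
    """Dynamical state: activations, concentration history, time.

    ``history`` holds concentration samples at ``dt`` spacing, most
    recent last, spanning at least ``N + M`` seconds.
    """

    y: dict[str, float]
    history: deque[float]
    t: float = 0.0


def sensory_response(history, p: SensoryParams, dt: float) -> float:
    """Rectified differential response from a concentration history.

    ``history`` is a sequence of samples at ``dt`` spacing ending at the
    current time; the last ``round(N/dt)`` samples form the recent
    window and the ``round(M/dt)`` before them the reference window.
    """
    n_n = max(1, round(p.N / dt))
    n_m = max(1, round(p.M / dt))
    if len(history) < n_n + n_m:
        raise ValueError(
            f"history must span N+M = {p.N + p.M:.3f} s "
            f"({n_n + n_m} samples at dt={dt}), got {len(history)}"
        )
    h = list(history)
    recent = h[-n_n:]
    past = h[-(n_n + n_m):-n_n]
    diff = sum(recent) / n_n - sum(past) / n_m
    if p.polarity == "OFF":
        diff = -diff
    return max(0.0, diff)


def _inputs(params: CircuitParameters, y: dict[str, float],
            sensor_out: dict[str, float], t: float,
            external: dict[str, float] | None) -> dict[str, float]:
    """Net non-leak input to every state neuron at time t."""
    net = {name: 0.0 for name in params.neurons}
    for syn in params.chem:
        if syn.pre in params.ablated or syn.post in params.sensory:
            continue
        if syn.pre in params.sensory:
            out = 0.0 if syn.pre in params.ablated else sensor_out[syn.pre]
        else:
            pre_p = params.neurons[syn.pre]
            out = sigmoid_output(y[syn.pre], pre_p.theta)
        net[syn.post] += syn.w * out
    for gj in params.gaps:
        ya = 0.0 if gj.a in params.ablated else y[gj.a]
        yb = 0.0 if gj.b in params.ablated else y[gj.b]
        net[gj.a] += gj.g * (yb - ya)
        net[gj.b] += gj.g * (ya - yb)
    for name, p in params.neurons.items():
        if p.w_self:
            net[name] += p.w_self * sigmoid_output(y[name], p.theta)
        if p.w_osc:
            sign = params.osc_sign(name)
            net[name] += p.w_osc * sign * math.sin(2.0 * math.pi * t / T_CYCLE)
        if external:
            net[name] += external.get(name, 0.0)
    return net


def step_network(
    state: CircuitState,
    params: CircuitParameters,
    c_now: float,
    dt: float,
    external: dict[str, float] | None = None,
    sensors_through_sigmoid: bool = False,
) -> CircuitState:
    """One forward-Euler step of the whole network.

    Appends ``c_now`` to the concentration history, computes sensory
    activations over their windows, updates every state neuron's ``y``
    and advances time by ``dt``.  Reference implementation; the batched
    kernel in :mod:`wormtaxis.engine` must agree with it step for step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.history.append(c_now)
    sensor_out: dict[str, float] = {}
    for name, sp in params.sensory.items():
        a = sensory_response(state.history, sp, dt)
        if sensors_through_sigmoid:
            a = sigmoid_output(a, 0.0)
        sensor_out[name] = a
    net = _inputs(params, state.y, sensor_out, state.t, external)
    new_y: dict[str, float] = {}
    for name, p in params.neurons.items():
        if name in params.ablated:
            new_y[name] = 0.0
            continue
        yv = state.y[name] + dt / p.tau * (-state.y[name] + net[name])
        if not math.isfinite(yv):
            raise FloatingPointError(f"activation of {name} became non-finite")
        new_y[name] = yv
    state.y = new_y
    state.t += dt
    return state


def _logistic_prime(x: float) -> float:
    s = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
    return s * (1.0 - s)


def _bisect(f, lo: float, hi: float, tol: float = 1e-12) -> float:
    flo = f(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ssio_curve(
    p: NeuronParams, input_grid, y_span: float = 60.0
) -> list[tuple[float, list[tuple[float, bool]]]]:
    """Steady-state input-output curve of a self-connected neuron.

    For each static net input ``I`` solves ``y = w_self*sigma(y+theta) + I``
    and reports every fixed point as ``(output, stable)`` where output is
    ``sigma(y* + theta)`` and stability is the sign of
    ``d/dy [-y + w_self*sigma(y+theta)]``.

    The logistic's maximum slope is 1/4, so the map is monotone (a
    single fixed point at every input) whenever ``w_self <= 4``; above
    4 there is an input interval with three fixed points.  Roots are
    isolated by splitting at the critical points of the map and
    bisecting each monotone branch.
    """
    w = p.w_self
    results = []
    for I in input_grid:

        def f(y, I=I):
            return w * sigmoid_output(y, p.theta) + I - y

        # Critical points of f: where w * sigma'(y+theta) = 1.
        crits: list[float] = []
        if w > 4.0:
            r = math.sqrt(1.0 - 4.0 / w)
            for s in ((1 - r) / 2.0, (1 + r) / 2.0):
                x = math.log(s / (1.0 - s))
                crits.append(x - p.theta)
        lo = min(I, I + w) - y_span if w >= 0 else I + w - y_span
        hi = max(I, I + w) + y_span
        knots = [lo] + sorted(c for c in crits if lo < c < hi) + [hi]
        roots: list[float] = []
        for a, b in zip(knots, knots[1:]):
            fa, fb = f(a), f(b)
            if fa == 0.0:
                roots.append(a)
            if (fa < 0) != (fb < 0):
                roots.append(_bisect(f, a, b))
        # Deduplicate near-coincident roots at knot boundaries.
        uniq: list[float] = []
        for r_ in sorted(roots):
            if not uniq or abs(r_ - uniq[-1]) > 1e-8:
                uniq.append(r_)
        sols = []
        for y_star in uniq:
            stable = -1.0 + w * _logistic_prime(y_star + p.theta) < 0
            sols.append((sigmoid_output(y_star, p.theta), stable))
        results.append((float(I), sols))
    return results
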