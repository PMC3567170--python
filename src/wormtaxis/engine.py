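"""Compiled simulation kernel for whole-assay runs.

The forward-Euler network update in :mod:`wormtaxis.circuit` is the
readable reference; this module compiles a :class:`CircuitParameters`
into flat arrays and advances the coupled brain-body-environment system
with a numba-JIT loop (50 000 steps for a standard 500 s assay at
dt = 0.01 s).  A unit test pins the kernel to the reference
implementation step for step.

Two concentration modes are supported: ``spatial`` (the worm samples a
conical or Gaussian gradient at its current position — closed-loop
chemotaxis) and ``scheduled`` (a prescribed concentration time course,
used for open-loop step-response and sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .circuit import T_CYCLE, CircuitParameters

TWO_PI = 2.0 * np.pi

MODE_SPATIAL = 0
MODE_SCHEDULED = 1
SHAPE_CONICAL = 0
SHAPE_GAUSSIAN = 1

__all__ = ["CompiledCircuit", "compile_circuit", "simulate", "SimResult"]


@dataclass
class CompiledCircuit:
    """Flat-array view of a circuit, ready for the kernel."""

    names: list[str]            # state neurons, fixed order
    sensor_names: list[str]
    tau: np.ndarray
    theta: np.ndarray
    w_self: np.ndarray
    w_osc: np.ndarray
    osc_sign: np.ndarray
    alive: np.ndarray           # 0.0 for ablated state neurons
    ce_pre: np.ndarray          # chem edges between state neurons
    ce_post: np.ndarray
    ce_w: np.ndarray
    se_idx: np.ndarray          # sensor -> state chem edges
    se_post: np.ndarray
    se_w: np.ndarray
    sens_nN: np.ndarray
    sens_nM: np.ndarray
    sens_pol: np.ndarray        # +1 ON, -1 OFF
    sens_alive: np.ndarray
    ga: np.ndarray              # gap junctions
    gb: np.ndarray
    gg: np.ndarray
    motor_idx: np.ndarray       # indices of SMBDL, SMBDR, SMBVL, SMBVR (-1 if absent)
    w_nmj: float

    def index(self, name: str) -> int:
        return self.names.index(name)


def compile_circuit(params: CircuitParameters, dt: float) -> CompiledCircuit:
    names = list(params.neurons)
    sensor_names = list(params.sensory)
    nidx = {n: i for i, n in enumerate(names)}
    sidx = {n: i for i, n in enumerate(sensor_names)}
    n = len(names)
    tau = np.array([params.neurons[m].tau for m in names])
    theta = np.array([params.neurons[m].theta for m in names])
    w_self = np.array([params.neurons[m].w_self for m in names])
    w_osc = np.array([params.neurons[m].w_osc for m in names])
    osc_sign = np.array([params.osc_sign(m) for m in names])
    alive = np.array([0.0 if m in params.ablated else 1.0 for m in names])
    ce, se = [], []
    for syn in params.chem:
        if syn.pre in sidx:
            se.append((sidx[syn.pre], nidx[syn.post], syn.w))
        else:
            ce.append((nidx[syn.pre], nidx[syn.post], syn.w))
    ce_pre = np.array([e[0] for e in ce], dtype=np.int64)
    ce_post = np.array([e[1] for e in ce], dtype=np.int64)
    ce_w = np.array([e[2] for e in ce], dtype=np.float64)
    se_idx = np.array([e[0] for e in se], dtype=np.int64)
    se_post = np.array([e[1] for e in se], dtype=np.int64)
    se_w = np.array([e[2] for e in se], dtype=np.float64)
    sens_nN = np.array(
        [max(1, round(params.sensory[s].N / dt)) for s in sensor_names], dtype=np.int64
    )
    sens_nM = np.array(
        [max(1, round(params.sensory[s].M / dt)) for s in sensor_names], dtype=np.int64
    )
    sens_pol = np.array(
        [1.0 if params.sensory[s].polarity == "ON" else -1.0 for s in sensor_names]
    )
    sens_alive = np.array(
        [0.0 if s in params.ablated else 1.0 for s in sensor_names]
    )
    ga = np.array([nidx[g.a] for g in params.gaps], dtype=np.int64)
    gb = np.array([nidx[g.b] for g in params.gaps], dtype=np.int64)
    gg = np.array([g.g for g in params.gaps], dtype=np.float64)
    motor_idx = np.array(
        [nidx.get(m, -1) for m in ("SMBDL", "SMBDR", "SMBVL", "SMBVR")], dtype=np.int64
    )
    assert n == len(tau)
    return CompiledCircuit(
        names, sensor_names, tau, theta, w_self, w_osc, osc_sign, alive,
        ce_pre, ce_post, ce_w, se_idx, se_post, se_w,
        sens_nN, sens_nM, sens_pol, sens_alive, ga, gb, gg,
        motor_idx, params.w_nmj,
    )


@njit(cache=True)
def _sigma(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _kernel(
    tau, theta, w_self, w_osc, osc_sign, alive,
    ce_pre, ce_post, ce_w,
    se_idx, se_post, se_w,
    sens_nN, sens_nM, sens_pol, sens_alive,
    ga, gb, gg,
    motor_idx, w_nmj,
    mode, grad_shape, peak_x, peak_y, alpha, amp, sigma_g, baseline,
    c_sched,
    v, pirouette_rate,
    y_init, x0, ypos0, mu0, t0,
    dt, n_steps,
    u_pir, u_head,
    xs, ys, mus, phis, cs, hs,
    outputs, sens_traces, record_outputs,
):
    n = tau.shape[0]
    ns = sens_nN.shape[0]
    y = y_init.copy()
    for i in range(n):
        y[i] *= alive[i]
    x = x0
    yp = ypos0
    mu = mu0
    t = t0
    # concentration at start pose / schedule start, used to backfill history
    if mode == MODE_SPATIAL:
        dx = x - peak_x
        dy = yp - peak_y
        dist = np.sqrt(dx * dx + dy * dy)
        if grad_shape == SHAPE_CONICAL:
            c0 = baseline + alpha * dist
        else:
            c0 = baseline + amp * np.exp(-dist * dist / (2.0 * sigma_g * sigma_g))
    else:
        c0 = c_sched[0]
    maxlen = 0
    for s in range(ns):
        L = sens_nN[s] + sens_nM[s]
        if L > maxlen:
            maxlen = L
    buf = np.empty((ns, maxlen))
    head = np.zeros(ns, dtype=np.int64)
    sumN = np.empty(ns)
    sumM = np.empty(ns)
    for s in range(ns):
        L = sens_nN[s] + sens_nM[s]
        for k in range(L):
            buf[s, k] = c0
        sumN[s] = c0 * sens_nN[s]
        sumM[s] = c0 * sens_nM[s]
    xs[0] = x
    ys[0] = yp
    mus[0] = mu
    hs[0] = np.sqrt((x - peak_x) ** 2 + (yp - peak_y) ** 2)
    cs[0] = c0
    dist = hs[0]
    net = np.empty(n)
    sens_a = np.empty(ns)
    dt_over_tau = np.empty(n)
    for i in range(n):
        dt_over_tau[i] = dt / tau[i]
    inv_nN = np.empty(ns)
    inv_nM = np.empty(ns)
    for s in range(ns):
        inv_nN[s] = 1.0 / sens_nN[s]
        inv_nM[s] = 1.0 / sens_nM[s]
    # Cached synaptic outputs sigma(y + theta); motor entries are kept
    # current across iterations (phi needs post-update motor output, the
    # chemical sums need pre-update output of every cell).
    out = np.empty(n)
    is_motor = np.zeros(n, dtype=np.bool_)
    for j in range(4):
        if motor_idx[j] >= 0:
            is_motor[motor_idx[j]] = True
    for i in range(n):
        out[i] = _sigma(y[i] + theta[i]) * alive[i]
    for k in range(n_steps):
        # --- sense ---
        if mode == MODE_SPATIAL:
            if grad_shape == SHAPE_CONICAL:
                c_now = baseline + alpha * dist
            else:
                c_now = baseline + amp * np.exp(-dist * dist / (2.0 * sigma_g * sigma_g))
        else:
            c_now = c_sched[k]
        for s in range(ns):
            L = sens_nN[s] + sens_nM[s]
            evicted = buf[s, head[s]]
            j = head[s] + sens_nM[s]
            if j >= L:
                j -= L
            transfer = buf[s, j]
            sumM[s] += transfer - evicted
            sumN[s] += c_now - transfer
            buf[s, head[s]] = c_now
            head[s] += 1
            if head[s] >= L:
                head[s] = 0
            a = sens_pol[s] * (sumN[s] * inv_nN[s] - sumM[s] * inv_nM[s])
            if a < 0.0:
                a = 0.0
            sens_a[s] = a * sens_alive[s]
        # --- network step (forward Euler) ---
        for i in range(n):
            if not is_motor[i]:
                out[i] = _sigma(y[i] + theta[i]) * alive[i]
        osc = np.sin(TWO_PI * t / T_CYCLE)
        for i in range(n):
            net[i] = w_osc[i] * osc_sign[i] * osc
        for e in range(ce_w.shape[0]):
            net[ce_post[e]] += ce_w[e] * out[ce_pre[e]]
        for e in range(se_w.shape[0]):
            net[se_post[e]] += se_w[e] * sens_a[se_idx[e]]
        for e in range(gg.shape[0]):
            d = gg[e] * (y[gb[e]] - y[ga[e]])
            net[ga[e]] += d
            net[gb[e]] -= d
        for i in range(n):
            if w_self[i] != 0.0:
                net[i] += w_self[i] * out[i]
        for i in range(n):
            y[i] = (y[i] + dt_over_tau[i] * (-y[i] + net[i])) * alive[i]
        t += dt
        # --- motor output -> turning angle (post-update outputs) ---
        if motor_idx[0] >= 0:
            for j in range(4):
                m = motor_idx[j]
                out[m] = _sigma(y[m] + theta[m]) * alive[m]
            phi = w_nmj * (
                (out[motor_idx[0]] + out[motor_idx[1]])
                - (out[motor_idx[2]] + out[motor_idx[3]])
            ) * dt
        else:
            phi = 0.0
        # --- pirouette, then pose update ---
        if pirouette_rate > 0.0 and u_pir[k] < pirouette_rate * dt:
            mu = -np.pi + TWO_PI * u_head[k]
        mu = mu + phi
        if mu > np.pi:
            mu -= TWO_PI
        elif mu <= -np.pi:
            mu += TWO_PI
        x += v * np.cos(mu) * dt
        yp += v * np.sin(mu) * dt
        xs[k + 1] = x
        ys[k + 1] = yp
        mus[k + 1] = mu
        phis[k] = phi
        cs[k + 1] = c_now
        dx = x - peak_x
        dy = yp - peak_y
        dist = np.sqrt(dx * dx + dy * dy)
        hs[k + 1] = dist
        if record_outputs:
            for i in range(n):
                outputs[k, i] = _sigma(y[i] + theta[i]) * alive[i]
            for s in range(ns):
                sens_traces[k, s] = sens_a[s]
    return y


@dataclass
class SimResult:
    """Raw kernel output.  ``phi`` has one entry per step; pose and
    distance series have ``n_steps + 1`` samples including t = 0."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    phi: np.ndarray
    c: np.ndarray
    h: np.ndarray
    outputs: np.ndarray | None
    sensor_outputs: np.ndarray | None
    y_final: np.ndarray
    names: list[str]
    sensor_names: list[str]


def simulate(
    compiled: CompiledCircuit,
    dt: float,
    n_steps: int,
    *,
    gradient=None,
    c_schedule: np.ndarray | None = None,
    y_init: np.ndarray | None = None,
    pose0: tuple[float, float, float] = (0.0, 0.0, 0.0),
    t0: float = 0.0,
    v: float = 0.022,
    pirouette_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    record_outputs: bool = False,
) -> SimResult:
    """Run the kernel for ``n_steps`` of size ``dt``.

    Exactly one of ``gradient`` (a :class:`wormtaxis.world.GradientSpec`)
    or ``c_schedule`` (per-step concentrations, length ``n_steps``)
    must be given.
    """
    if (gradient is None) == (c_schedule is None):
        raise ValueError("provide exactly one of gradient or c_schedule")
    n = len(compiled.names)
    ns = len(compiled.sensor_names)
    if y_init is None:
        y_init = np.zeros(n)
    y_init = np.asarray(y_init, dtype=np.float64)
    if gradient is not None:
        mode = MODE_SPATIAL
        shape = SHAPE_CONICAL if gradient.shape == "conical" else SHAPE_GAUSSIAN
        peak_x, peak_y = gradient.peak
        alpha, amp, sigma_g, baseline = (
            gradient.alpha, gradient.amp, gradient.sigma, gradient.baseline,
        )
        c_sched = np.zeros(1)
    else:
        mode = MODE_SCHEDULED
        shape = SHAPE_CONICAL
        peak_x = peak_y = alpha = amp = baseline = 0.0
        sigma_g = 1.0
        c_sched = np.ascontiguousarray(c_schedule, dtype=np.float64)
        if c_sched.shape[0] != n_steps:
            raise ValueError("c_schedule must have n_steps entries")
    if pirouette_rate > 0.0:
        if rng is None:
            raise ValueError("pirouettes require an rng")
        u_pir = rng.random(n_steps)
        u_head = rng.random(n_steps)
    else:
        u_pir = np.zeros(1)
        u_head = np.zeros(1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    mus = np.empty(n_steps + 1)
    phis = np.empty(n_steps)
    cs = np.empty(n_steps + 1)
    hs = np.empty(n_steps + 1)
    if record_outputs:
        outputs = np.empty((n_steps, n))
        sens_traces = np.empty((n_steps, ns))
    else:
        outputs = np.empty((1, 1))
        sens_traces = np.empty((1, 1))
    x0, ypos0, mu0 = pose0
    y_final = _kernel(
        compiled.tau, compiled.theta, compiled.w_self, compiled.w_osc,
        compiled.osc_sign, compiled.alive,
        compiled.ce_pre, compiled.ce_post, compiled.ce_w,
        compiled.se_idx, compiled.se_post, compiled.se_w,
        compiled.sens_nN, compiled.sens_nM, compiled.sens_pol, compiled.sens_alive,
        compiled.ga, compiled.gb, compiled.gg,
        compiled.motor_idx, compiled.w_nmj,
        mode, shape, peak_x, peak_y, alpha, amp, sigma_g, baseline,
        c_sched,
        v, pirouette_rate,
        y_init, x0, ypos0, mu0, t0,
        dt, n_steps,
        u_pir, u_head,
        xs, ys, mus, phis, cs, hs,
        outputs, sens_traces, record_outputs,
    )
    if not np.all(np.isfinite(y_final)):
        bad = [compiled.names[i] for i in np.flatnonzero(~np.isfinite(y_final))]
        raise FloatingPointError(f"non-finite activation in neurons {bad}")
    t = t0 + dt * np.arange(n_steps + 1)
    return SimResult(
        t=t, x=xs, y=ys, mu=mus, phi=phis, c=cs, h=hs,
        outputs=outputs if record_outputs else None,
        sensor_outputs=sens_traces if record_outputs else None,
        y_final=y_final, names=compiled.names, sensor_names=compiled.sensor_names,
    )
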