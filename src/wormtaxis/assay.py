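"""Chemotaxis assays and performance statistics.

An assay places the model worm 4.5 cm from the gradient peak with a
random heading and random motor-neuron activations, runs the coupled
brain-body-environment simulation for 500 s (default), and scores the
run with a chemotaxis index

    CI = 1 - (1 / T) * integral of h(t) / h(0) dt

where ``h(t)`` is the distance to the peak: CI = 1 for a worm sitting
on the peak throughout, 0 for no net approach (negative values are
clamped to zero).  *Reliability* is the proportion of assays in which
the worm enters a 0.1 cm disk around the peak at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .circuit import DT_DEFAULT, CircuitParameters
from .world import PIROUETTE_RATE, V_SPEED, GradientSpec

PEAK_RADIUS = 0.1  #: cm; entering this disk counts as reaching the peak

__all__ = ["AssayConfig", "AssayResult", "run_assay", "chemotaxis_index", "reliability"]


@dataclass(frozen=True)
class AssayConfig:
    duration: float = 500.0
    start_distance: float = 4.5
    dt: float = DT_DEFAULT
    pirouette_rate: float = PIROUETTE_RATE
    gradient: GradientSpec = field(default_factory=GradientSpec)
    v: float = V_SPEED
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.start_distance <= 0 or self.dt <= 0:
            raise ValueError("duration, start_distance and dt must be positive")


@dataclass
class AssayResult:
    trajectory: pd.DataFrame | None
    h: np.ndarray
    ci: float
    reached_peak: bool
    sim: engine.SimResult


def chemotaxis_index(h: np.ndarray, h0: float, duration: float) -> float:
    """Normalized time-average proximity to the peak (trapezoidal).

    ``h`` is sampled uniformly over [0, duration].
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty distance series")
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    if h.size == 1:
        mean_h = float(h[0])
    else:
        dt = duration / (h.size - 1)
        mean_h = float(np.trapezoid(h, dx=dt)) / duration
    return max(0.0, 1.0 - mean_h / h0)


def run_assay(
    params: CircuitParameters,
    cfg: AssayConfig,
    rng: np.random.Generator | None = None,
    record_neurons: bool = False,
    compiled: engine.CompiledCircuit | None = None,
    build_trajectory: bool = True,
) -> AssayResult:
    """Run one chemotaxis assay.

    Initial heading is uniform on (-pi, pi], motor activations uniform
    on [0, 1], interneurons start at rest.  All randomness (heading,
    initializations, pirouettes) flows from ``rng`` (or ``cfg.seed``),
    so a fixed seed reproduces the trajectory bit for bit.  Passing a
    pre-compiled circuit skips recompilation in tight loops.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if compiled is None:
        compiled = engine.compile_circuit(params, cfg.dt)
    n_steps = int(round(cfg.duration / cfg.dt))
    heading = rng.uniform(-np.pi, np.pi)
    y0 = np.zeros(len(compiled.names))
    for m in ("SMBDL", "SMBDR", "SMBVL", "SMBVR"):
        if m in compiled.names:
            y0[compiled.index(m)] = rng.uniform(0.0, 1.0)
    px, py = cfg.gradient.peak
    start = (px + cfg.start_distance, py)
    sim = engine.simulate(
        compiled, cfg.dt, n_steps,
        gradient=cfg.gradient,
        y_init=y0,
        pose0=(start[0], start[1], heading),
        v=cfg.v,
        pirouette_rate=cfg.pirouette_rate,
        rng=rng,
        record_outputs=record_neurons,
    )
    ci = chemotaxis_index(sim.h, cfg.start_distance, cfg.duration)
    traj = None
    if build_trajectory:
        traj = pd.DataFrame(
            {
                "t": sim.t, "x": sim.x, "y": sim.y, "mu": sim.mu,
                "concentration": sim.c,
                "phi": np.concatenate([sim.phi, [np.nan]]),
            }
        )
        if record_neurons:
            for i, name in enumerate(sim.names):
                traj[name] = np.concatenate([[np.nan], sim.outputs[:, i]])
            for s, name in enumerate(sim.sensor_names):
                traj[name] = np.concatenate([[np.nan], sim.sensor_outputs[:, s]])
    return AssayResult(
        trajectory=traj,
        h=sim.h,
        ci=ci,
        reached_peak=bool(sim.h.min() <= PEAK_RADIUS),
        sim=sim,
    )


def reliability(results: list[AssayResult]) -> float:
    """Proportion of assays whose worm reached the 0.1 cm peak disk."""
    if not results:
        raise ValueError("reliability requires at least one assay result")
    return sum(r.reached_peak for r in results) / len(results)


def analysis_config(**overrides) -> AssayConfig:
    """Assay configuration used in the analysis battery: pirouettes off,
    Gaussian gradient, 300 s duration unless overridden."""
    base = AssayConfig(
        duration=300.0,
        pirouette_rate=0.0,
        gradient=GradientSpec(shape="gaussian"),
    )
    return replace(base, **overrides)
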