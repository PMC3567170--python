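"""Behavioral and circuit-level analyses of evolved klinotaxis models.

Terminology (all analyses run with pirouettes off):

* A **locomotion cycle** is one period T = 4.2 s of the head-sweep
  oscillation.  The **direction of translation** is the unit vector
  between trajectory points one cycle apart; the **normal direction**
  is its 90-degree counter-clockwise rotation.
* **Bearing** is the signed angle from the line of steepest gradient
  ascent to the direction of translation (positive counter-clockwise).
  Klinotaxis requires the **turning bias** — the sum of per-step turning
  angles over one cycle, positive = counter-clockwise — to carry the
  opposite sign to the bearing.
* The **sensitivity curve** of a neuron maps sustained concentration
  steps (grid of magnitudes over +/- 0.02, the range encountered during
  gradient climbs) to the deviation of its mean output over the cycle
  after step onset from the no-input mean.  **Coverage** is the
  fraction of adjacent grid pairs whose mean outputs differ by more
  than 1e-4.  Interneurons are typed from the curve: A insensitive,
  B one-sided, C two-sided with same-direction deflections, D two-sided
  with opposite-direction deflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .assay import AssayConfig, analysis_config, run_assay
from .circuit import T_CYCLE, CircuitParameters
from .world import GradientSpec, gradient_at, wrap_angle

COVERAGE_THRESHOLD = 1e-4
SENSORY_RANGE = 0.02
SENSORY_STEP = 5e-4

__all__ = [
    "CycleFrame",
    "SensitivityCurve",
    "cycle_frames",
    "bias_vs_bearing",
    "bias_vs_gradient_components",
    "phase_step_response",
    "phase_response_curve",
    "neuron_step_traces",
    "sensitivity_curve",
    "coverage",
    "covered_points",
    "combined_coverage",
    "classify_interneuron",
    "ablate",
    "block_gap",
    "ablation_study",
    "gap_block_coverage_loss",
    "perturbation_scan",
    "ensemble_experiments",
    "default_step_grid",
]


# --------------------------------------------------------------------------
# cycle frames and turning-bias statistics


@dataclass(frozen=True)
class CycleFrame:
    """Per-cycle kinematic frame extracted from a trajectory."""

    start_index: int
    translation: tuple[float, float]   # unit vector
    normal: tuple[float, float]        # 90 deg CCW of translation
    bearing: float                     # radians, NaN without a gradient
    turning_bias: float                # radians per cycle
    grad_normal: float                 # directional derivative of c, 1/cm
    grad_translation: float
    start_distance: float              # cm from gradient peak


def cycle_frames(
    sim: engine.SimResult,
    gradient: GradientSpec | None,
    dt: float,
) -> list[CycleFrame]:
    """Split a trajectory into consecutive locomotion cycles."""
    spc = int(round(T_CYCLE / dt))
    n_steps = len(sim.phi)
    if n_steps < spc:
        raise ValueError(
            f"trajectory spans {n_steps * dt:.1f} s, shorter than one cycle ({T_CYCLE} s)"
        )
    frames = []
    for k in range(n_steps // spc):
        i0, i1 = k * spc, (k + 1) * spc
        dx = sim.x[i1] - sim.x[i0]
        dy = sim.y[i1] - sim.y[i0]
        norm = math.hypot(dx, dy)
        if norm == 0.0:
            continue
        trans = (dx / norm, dy / norm)
        normal = (-trans[1], trans[0])
        bias = float(sim.phi[i0:i1].sum())
        if gradient is not None:
            gx, gy = gradient_at(gradient, sim.x[i0], sim.y[i0])
            gnorm = math.hypot(gx, gy)
            bearing = (
                wrap_angle(math.atan2(trans[1], trans[0]) - math.atan2(gy, gx))
                if gnorm > 0 else float("nan")
            )
            grad_n = gx * normal[0] + gy * normal[1]
            grad_t = gx * trans[0] + gy * trans[1]
            dist = math.hypot(
                sim.x[i0] - gradient.peak[0], sim.y[i0] - gradient.peak[1]
            )
        else:
            bearing, grad_n, grad_t, dist = float("nan"), 0.0, 0.0, float("nan")
        frames.append(
            CycleFrame(
                start_index=i0, translation=trans, normal=normal, bearing=bearing,
                turning_bias=bias, grad_normal=grad_n, grad_translation=grad_t,
                start_distance=dist,
            )
        )
    return frames


def _collect_frames(
    params: CircuitParameters,
    cfg: AssayConfig,
    n_assays: int,
    seed: int,
    min_peak_distance: float,
) -> pd.DataFrame:
    compiled = engine.compile_circuit(params, cfg.dt)
    rows = []
    for a in range(n_assays):
        rng = np.random.default_rng((seed, a))
        res = run_assay(params, cfg, rng=rng, compiled=compiled, build_trajectory=False)
        for f in cycle_frames(res.sim, cfg.gradient, cfg.dt):
            if f.start_distance >= min_peak_distance and math.isfinite(f.bearing):
                rows.append(
                    {"assay": a, "bearing": f.bearing, "bias": f.turning_bias,
                     "grad_normal": f.grad_normal, "grad_translation": f.grad_translation}
                )
    return pd.DataFrame(rows)


def bias_vs_bearing(
    params: CircuitParameters,
    cfg: AssayConfig | None = None,
    n_assays: int = 50,
    bins: int = 18,
    seed: int = 0,
    min_peak_distance: float = 0.3,
) -> pd.DataFrame:
    """Binned mean turning bias (+/- SEM) as a function of bearing.

    Pools cycles from ``n_assays`` Gaussian-gradient assays with
    pirouettes off; cycles starting within ``min_peak_distance`` of the
    peak are dropped (bearing is ill-conditioned there).  Empty bins
    appear with NaN statistics.
    """
    if cfg is None:
        cfg = analysis_config()
    df = _collect_frames(params, cfg, n_assays, seed, min_peak_distance)
    edges = np.linspace(-math.pi, math.pi, bins + 1)
    idx = np.clip(np.digitize(df["bearing"], edges) - 1, 0, bins - 1)
    out = []
    for b in range(bins):
        sel = df["bias"][idx == b]
        out.append(
            {
                "bearing_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_bias": sel.mean() if len(sel) else np.nan,
                "sem_bias": sel.sem() if len(sel) > 1 else np.nan,
                "n_cycles": len(sel),
            }
        )
    return pd.DataFrame(out)


def bias_vs_gradient_components(
    params: CircuitParameters,
    cfg: AssayConfig | None = None,
    n_assays: int = 50,
    bins: int = 10,
    seed: int = 0,
    min_peak_distance: float = 0.3,
) -> dict:
    """Turning bias against the normal and translational gradient components.

    Returns the regression of bias on the normal component (slope,
    intercept, R^2), equal-count binned means for both components, and
    the translational analysis split by the sign of the bias.
    """
    if cfg is None:
        cfg = analysis_config()
    df = _collect_frames(params, cfg, n_assays, seed, min_peak_distance)

    def binned(frame: pd.DataFrame, col: str) -> pd.DataFrame:
        q = pd.qcut(frame[col], bins, duplicates="drop")
        g = frame.groupby(q, observed=True)["bias"]
        centers = frame.groupby(q, observed=True)[col].mean()
        return pd.DataFrame(
            {"component": centers.values, "mean_bias": g.mean().values,
             "sem_bias": g.sem().values, "n_cycles": g.count().values}
        )

    x = df["grad_normal"].to_numpy()
    y = df["bias"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    r2 = 1.0 - np.sum((y - slope * x - intercept) ** 2) / np.sum((y - y.mean()) ** 2)
    normal_binned = binned(df, "grad_normal")
    xb = normal_binned["component"].to_numpy()
    yb = normal_binned["mean_bias"].to_numpy()
    slope_b, icpt_b = np.polyfit(xb, yb, 1)
    r2_b = 1.0 - np.sum((yb - slope_b * xb - icpt_b) ** 2) / np.sum((yb - yb.mean()) ** 2)
    return {
        "cycles": df,
        "normal_fit": {"slope": float(slope), "intercept": float(intercept),
                       "r_squared": float(r2)},
        "normal_binned_fit": {"slope": float(slope_b), "intercept": float(icpt_b),
                              "r_squared": float(r2_b)},
        "normal_binned": normal_binned,
        "translation_binned": binned(df, "grad_translation"),
        "translation_binned_positive_bias": binned(df[df["bias"] > 0], "grad_translation"),
        "translation_binned_negative_bias": binned(df[df["bias"] < 0], "grad_translation"),
    }


# --------------------------------------------------------------------------
# open-loop step responses


def _settled_run(
    compiled: engine.CompiledCircuit,
    dt: float,
    n_steps: int,
    schedule: np.ndarray,
) -> engine.SimResult:
    return engine.simulate(
        compiled, dt, n_steps, c_schedule=schedule, record_outputs=True
    )


def phase_step_response(
    params: CircuitParameters,
    phase: float,
    magnitude: float,
    dt: float = 0.01,
    settle_cycles: int = 60,
    drift_tol: float = 1e-5,
    compiled: engine.CompiledCircuit | None = None,
) -> float:
    """Turning-bias change caused by a sustained concentration step.

    The circuit settles onto its limit cycle in a gradient-free
    environment, a step of the given magnitude is injected at the given
    oscillator phase, and the turning bias over the following full
    cycle is compared with the unstepped baseline.
    """
    if not 0.0 <= phase < 2.0 * math.pi:
        raise ValueError("phase must lie in [0, 2 pi)")
    spc = int(round(T_CYCLE / dt))
    offset = int(round(phase / (2.0 * math.pi) * spc))
    settle = settle_cycles * spc
    n = settle + offset + spc
    if compiled is None:
        compiled = engine.compile_circuit(params, dt)
    base_sched = np.zeros(n)
    base = engine.simulate(compiled, dt, n, c_schedule=base_sched)
    w0 = settle + offset
    base_bias = float(base.phi[w0:w0 + spc].sum())
    prev_bias = float(base.phi[w0 - spc:w0].sum())
    if abs(base_bias - prev_bias) > drift_tol:
        raise RuntimeError(
            f"circuit not settled after {settle_cycles} cycles: "
            f"baseline bias drift {abs(base_bias - prev_bias):.2e} > {drift_tol:.0e}"
        )
    sched = np.zeros(n)
    sched[w0:] = magnitude
    stepped = engine.simulate(compiled, dt, n, c_schedule=sched)
    return float(stepped.phi[w0:w0 + spc].sum()) - base_bias


def phase_response_curve(
    params: CircuitParameters,
    magnitudes=(0.005, 0.00333, 0.00166),
    n_phases: int = 16,
    dt: float = 0.01,
    **kwargs,
) -> pd.DataFrame:
    """Phase-response curves for a set of signed step magnitudes."""
    compiled = engine.compile_circuit(params, dt)
    phases = np.arange(n_phases) * 2.0 * math.pi / n_phases
    rows = []
    for m in magnitudes:
        for ph in phases:
            rows.append(
                {"magnitude": m, "phase": float(ph),
                 "bias_response": phase_step_response(
                     params, float(ph), m, dt=dt, compiled=compiled, **kwargs)}
            )
    return pd.DataFrame(rows)


def neuron_step_traces(
    params: CircuitParameters,
    steps=(0.005, -0.005),
    dt: float = 0.01,
    settle_cycles: int = 60,
    record_cycles: int = 3,
) -> dict:
    """Output time series of every neuron for sustained steps at phase 0.

    Returns ``{"t": times, "baseline": DataFrame, <magnitude>: DataFrame}``
    with one column per neuron (sensors included), covering
    ``record_cycles`` cycles from step onset.
    """
    spc = int(round(T_CYCLE / dt))
    settle = settle_cycles * spc
    n = settle + record_cycles * spc
    compiled = engine.compile_circuit(params, dt)

    def run(mag: float) -> pd.DataFrame:
        sched = np.zeros(n)
        sched[settle:] = mag
        sim = _settled_run(compiled, dt, n, sched)
        cols = {
            name: sim.outputs[settle:, i] for i, name in enumerate(sim.names)
        }
        cols.update(
            {name: sim.sensor_outputs[settle:, s] for s, name in enumerate(sim.sensor_names)}
        )
        return pd.DataFrame(cols)

    out = {"t": dt * np.arange(record_cycles * spc), "baseline": run(0.0)}
    for m in steps:
        out[m] = run(m)
    return out


# --------------------------------------------------------------------------
# sensitivity curves, coverage and interneuron types


def default_step_grid() -> np.ndarray:
    """Signed step magnitudes -0.02 .. 0.02 in 5e-4 increments (81 points)."""
    n = int(round(2 * SENSORY_RANGE / SENSORY_STEP))
    return np.linspace(-SENSORY_RANGE, SENSORY_RANGE, n + 1)


@dataclass(frozen=True)
class SensitivityCurve:
    """Mean-output deviation as a function of concentration-step size."""

    neuron: str
    grid: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.response.shape:
            raise ValueError("grid and response must have matching shapes")


def sensitivity_curve(
    params: CircuitParameters,
    neuron: str,
    dt: float = 0.01,
    settle_cycles: int = 60,
    grid: np.ndarray | None = None,
    compiled: engine.CompiledCircuit | None = None,
) -> SensitivityCurve:
    """Mean output over the cycle after step onset, relative to no input.

    Steps are injected at phase 0 after settling; the averaging window
    is one full locomotion cycle, matching the turning-bias timescale.
    """
    if grid is None:
        grid = default_step_grid()
    if compiled is None:
        compiled = engine.compile_circuit(params, dt)
    if neuron in compiled.names:
        col = ("state", compiled.names.index(neuron))
    elif neuron in compiled.sensor_names:
        col = ("sensor", compiled.sensor_names.index(neuron))
    else:
        raise KeyError(f"unknown neuron {neuron!r}")
    spc = int(round(T_CYCLE / dt))
    settle = settle_cycles * spc
    n = settle + spc

    def window_mean(mag: float) -> float:
        sched = np.zeros(n)
        sched[settle:] = mag
        sim = _settled_run(compiled, dt, n, sched)
        arr = sim.outputs if col[0] == "state" else sim.sensor_outputs
        return float(arr[settle:, col[1]].mean())

    base = window_mean(0.0)
    response = np.array([
        0.0 if mag == 0.0 else window_mean(mag) - base for mag in grid
    ])
    return SensitivityCurve(neuron=neuron, grid=grid, response=response)


def covered_points(curve: SensitivityCurve, threshold: float = COVERAGE_THRESHOLD) -> np.ndarray:
    """Boolean mask over adjacent grid pairs: mean output changed detectably."""
    return np.abs(np.diff(curve.response)) > threshold


def coverage(curve: SensitivityCurve, threshold: float = COVERAGE_THRESHOLD) -> float:
    """Proportion of the sensory range over which the neuron is sensitive."""
    mask = covered_points(curve, threshold)
    return float(mask.sum()) / mask.size


def combined_coverage(
    a: SensitivityCurve, b: SensitivityCurve, threshold: float = COVERAGE_THRESHOLD
) -> float:
    """Coverage of the union of two cells' responsive grid intervals."""
    mask = covered_points(a, threshold) | covered_points(b, threshold)
    return float(mask.sum()) / mask.size


def classify_interneuron(
    curve: SensitivityCurve, threshold: float = COVERAGE_THRESHOLD
) -> str:
    """Type a cell from its sensitivity curve.

    A: insensitive everywhere.  B: responsive to only one step sign.
    C: responsive to both signs but deflecting in the same direction
    (ambiguous: an upstep and a downstep can produce the same output).
    D: responsive to both signs with opposite-direction deflections.
    """
    resp = curve.response
    pos = resp[(curve.grid > 0) & (np.abs(resp) > threshold)]
    neg = resp[(curve.grid < 0) & (np.abs(resp) > threshold)]
    if pos.size == 0 and neg.size == 0:
        return "A"
    if pos.size == 0 or neg.size == 0:
        return "B"
    sp = np.sign(pos[np.argmax(np.abs(pos))])
    sn = np.sign(neg[np.argmax(np.abs(neg))])
    return "C" if sp == sn else "D"


# --------------------------------------------------------------------------
# ablations, gap blocks, perturbations


def ablate(params: CircuitParameters, neuron: str) -> CircuitParameters:
    """Clamp a neuron's activation to rest and its output to zero."""
    return params.ablate(neuron)


def block_gap(params: CircuitParameters, a: str, b: str) -> CircuitParameters:
    """Set the conductance of one gap junction to zero."""
    return params.block_gap(a, b)


def _matched_ci(
    params: CircuitParameters,
    n_assays: int,
    seed: int,
    duration: float = 500.0,
    dt: float = 0.01,
) -> float:
    """Mean CI over assays with seeds shared across conditions
    (pirouettes off, conical gradients of seed-drawn steepness)."""
    compiled = engine.compile_circuit(params, dt)
    total = 0.0
    for a in range(n_assays):
        rng = np.random.default_rng((seed, a))
        alpha = rng.uniform(-0.38, -0.01)
        cfg = AssayConfig(
            duration=duration, dt=dt, pirouette_rate=0.0,
            gradient=GradientSpec(shape="conical", alpha=alpha),
        )
        total += run_assay(params, cfg, rng=rng, compiled=compiled,
                           build_trajectory=False).ci
    return total / n_assays


def ablation_study(
    params: CircuitParameters,
    neurons: list[str] | None = None,
    n_assays: int = 10,
    seed: int = 0,
    duration: float = 500.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """CI of the intact circuit and of each single-neuron ablation,
    evaluated on matched assay seeds."""
    if neurons is None:
        neurons = list(params.sensory) + list(params.neurons)
    rows = [{"neuron": "intact",
             "ci": _matched_ci(params, n_assays, seed, duration, dt)}]
    for nrn in neurons:
        rows.append(
            {"neuron": nrn,
             "ci": _matched_ci(ablate(params, nrn), n_assays, seed, duration, dt)}
        )
    return pd.DataFrame(rows)


def gap_block_coverage_loss(
    params: CircuitParameters,
    pair_cells: dict[str, tuple[str, str]] | None = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Coverage of each interneuron pair with its lateral gap junction
    intact versus blocked."""
    if pair_cells is None:
        pair_cells = {"AIY": ("AIYL", "AIYR"), "AIZ": ("AIZL", "AIZR")}
    rows = []
    for pair, (left, right) in pair_cells.items():
        blocked = block_gap(params, left, right)
        cov_n = [coverage(sensitivity_curve(params, c, dt=dt)) for c in (left, right)]
        cov_b = [coverage(sensitivity_curve(blocked, c, dt=dt)) for c in (left, right)]
        rows.append(
            {
                "pair": pair,
                "coverage_normal": float(np.mean(cov_n)),
                "coverage_blocked": float(np.mean(cov_b)),
                "coverage_loss": float(np.mean(cov_n) - np.mean(cov_b)),
            }
        )
    return pd.DataFrame(rows)


def _scalar_parameters(params: CircuitParameters) -> list[tuple]:
    keys: list[tuple] = []
    for name, sp in params.sensory.items():
        keys.append(("sensory", name, "N"))
        keys.append(("sensory", name, "M"))
    for name, p in params.neurons.items():
        keys.append(("theta", name, None))
        if p.w_self != 0.0:
            keys.append(("w_self", name, None))
    for syn in params.chem:
        keys.append(("chem", syn.pre, syn.post))
    for gj in params.gaps:
        keys.append(("gap", gj.a, gj.b))
    return keys


def _scaled(params: CircuitParameters, key: tuple, factor: float) -> CircuitParameters:
    from dataclasses import replace

    kind, a, b = key
    if kind == "sensory":
        sp = params.sensory[a]
        new = replace(sp, **{b: getattr(sp, b) * factor})
        return replace(params, sensory={**params.sensory, a: new})
    if kind in ("theta", "w_self"):
        np_ = params.neurons[a]
        new = replace(np_, **{kind: getattr(np_, kind) * factor})
        return replace(params, neurons={**params.neurons, a: new})
    if kind == "chem":
        chem = tuple(
            replace(s, w=s.w * factor) if (s.pre, s.post) == (a, b) else s
            for s in params.chem
        )
        return replace(params, chem=chem)
    if kind == "gap":
        gaps = tuple(
            replace(g, g=g.g * factor) if (g.a, g.b) == (a, b) else g
            for g in params.gaps
        )
        return replace(params, gaps=gaps)
    raise KeyError(key)


def perturbation_scan(
    params: CircuitParameters,
    fraction: float = 0.10,
    n_grid: int = 9,
    n_assays: int = 10,
    seed: int = 0,
    duration: float = 500.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """CI as each scalar parameter is independently scaled over
    [1-fraction, 1+fraction]; assay seeds are matched so the zero
    perturbation reproduces the baseline CI exactly."""
    factors = np.linspace(1.0 - fraction, 1.0 + fraction, n_grid)
    rows = []
    for key in _scalar_parameters(params):
        label = ":".join(str(k) for k in key if k is not None)
        for f in factors:
            ci = _matched_ci(_scaled(params, key, float(f)), n_assays, seed,
                             duration, dt)
            rows.append({"parameter": label, "factor": float(f), "ci": ci})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ensemble-level report


def ensemble_experiments(
    ensemble: list[CircuitParameters],
    n_assays: int = 10,
    seed: int = 0,
    dt: float = 0.01,
) -> dict:
    """Run the interneuron-coverage, gap-block and ablation battery over
    an ensemble of circuits and aggregate the distributions."""
    if not ensemble:
        raise ValueError("ensemble must be nonempty")
    per_circuit = []
    for ci_idx, params in enumerate(ensemble):
        curves = {
            c: sensitivity_curve(params, c, dt=dt)
            for c in ("AIYL", "AIYR", "AIZL", "AIZR")
        }
        cov = {c: coverage(k) for c, k in curves.items()}
        combined = {
            "AIY": combined_coverage(curves["AIYL"], curves["AIYR"]),
            "AIZ": combined_coverage(curves["AIZL"], curves["AIZR"]),
        }
        gain = {
            pair: combined[pair] - 0.5 * (cov[pair + "L"] + cov[pair + "R"])
            for pair in ("AIY", "AIZ")
        }
        block = gap_block_coverage_loss(params, dt=dt).set_index("pair")
        abl = ablation_study(params, n_assays=n_assays, seed=seed, dt=dt)
        g = {gj.pair(): gj.g for gj in params.gaps}
        g_aiy = g.get(("AIYL", "AIYR"), 0.0)
        g_aiz = g.get(("AIZL", "AIZR"), 0.0)
        per_circuit.append(
            {
                "index": ci_idx,
                "coverage": cov,
                "combined_coverage": combined,
                "coverage_gain": gain,
                "types": {c: classify_interneuron(k) for c, k in curves.items()},
                "gap_block_loss": block["coverage_loss"].to_dict(),
                "ablation_ci": abl.set_index("neuron")["ci"].to_dict(),
                "gap_ratio_aiy_aiz": g_aiy / g_aiz if g_aiz > 0 else float("inf"),
            }
        )

    def dist(values) -> dict:
        arr = np.asarray(list(values), dtype=float)
        return {
            "median": float(np.median(arr)),
            "q25": float(np.quantile(arr, 0.25)),
            "q75": float(np.quantile(arr, 0.75)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    abl_names = list(per_circuit[0]["ablation_ci"])
    return {
        "per_circuit": per_circuit,
        "coverage_gain_AIY": dist(c["coverage_gain"]["AIY"] for c in per_circuit),
        "coverage_gain_AIZ": dist(c["coverage_gain"]["AIZ"] for c in per_circuit),
        "gap_block_loss_AIY": dist(c["gap_block_loss"]["AIY"] for c in per_circuit),
        "gap_block_loss_AIZ": dist(c["gap_block_loss"]["AIZ"] for c in per_circuit),
        "gap_ratio": dist(c["gap_ratio_aiy_aiz"] for c in per_circuit),
        "ablation_ci": {
            name: dist(c["ablation_ci"][name] for c in per_circuit)
            for name in abl_names
        },
    }
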