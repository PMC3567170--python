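"""Genotype encoding and the genetic algorithm.

The unknown electrophysiology of the minimal klinotaxis circuit is
encoded as a 20-element real vector on [-1, 1]; each slot maps linearly
onto one (or several, dorsoventrally shared) circuit parameters:

* sensor rise/decay times ``N``, ``M`` on [0.1, 4.2] s (shared by the
  ON and OFF cell),
* chemical weights and biases on [-15, 15],
* gap-junction conductances on [0, 15],
* motor self-connections on [-15, 15].

Dorsal and ventral motor neurons on the same side receive identical
copies of shared slots (dorsoventral symmetry), so SMBDL/SMBVL share
the AIZ input weight, bias and self-weight, as do SMBDR/SMBVR.  The
neuron time constant, the oscillator input weight and the neuromuscular
gain are held at fixed defaults (1.5 s, 10, 1) and are configurable
through the map's constants; the 20 slots cannot carry every parameter
of the model at once, and alternative slot assignments can be expressed
as data without code changes.

Fitness of a genotype is the mean chemotaxis index over independent
assays on conical gradients whose steepness is drawn uniformly from
[-0.38, -0.01], with random initial heading and motor activations and
pirouettes at the baseline rate.  The GA is elitist truncation
selection (top third reproduce) with per-gene Gaussian mutation;
fitness is re-sampled every generation so lucky assays are not locked
in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .assay import AssayConfig, run_assay
from .circuit import (
    ChemicalSynapse,
    CircuitParameters,
    GapJunction,
    NeuronParams,
    SensoryParams,
)
from .world import GradientSpec

PARAMETER_MAP_VERSION = "1"

NEURON_ORDER = ("AIYL", "AIYR", "AIZL", "AIZR", "SMBDL", "SMBVL", "SMBDR", "SMBVR")

__all__ = [
    "Slot",
    "ParameterMap",
    "default_parameter_map",
    "GAConfig",
    "GAResult",
    "decode",
    "encode",
    "fitness",
    "run_ga",
    "retest_ci",
]


@dataclass(frozen=True)
class Slot:
    """One genotype slot: a named linear map onto one or more targets.

    ``kind`` is one of ``sensory_N``, ``sensory_M``, ``chem``, ``gap``,
    ``theta``, ``w_self``; ``targets`` are sensor/neuron names or
    ``(pre, post)`` pairs depending on the kind.
    """

    name: str
    kind: str
    targets: tuple
    low: float
    high: float

    def to_value(self, gene: float) -> float:
        if not -1.0 <= gene <= 1.0:
            raise ValueError(f"gene for slot {self.name} out of [-1, 1]: {gene}")
        return self.low + (gene + 1.0) * 0.5 * (self.high - self.low)

    def to_gene(self, value: float) -> float:
        return 2.0 * (value - self.low) / (self.high - self.low) - 1.0


@dataclass(frozen=True)
class ParameterMap:
    slots: tuple[Slot, ...]
    constants: dict = field(
        default_factory=lambda: {"tau": 1.5, "w_osc": 10.0, "w_nmj": 1.0}
    )
    version: str = PARAMETER_MAP_VERSION

    def __len__(self) -> int:
        return len(self.slots)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "constants": dict(self.constants),
            "slots": [
                {
                    "name": s.name, "kind": s.kind,
                    "targets": [list(t) if isinstance(t, tuple) else t for t in s.targets],
                    "low": s.low, "high": s.high,
                }
                for s in self.slots
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterMap":
        if d.get("version") != PARAMETER_MAP_VERSION:
            raise ValueError(
                f"unsupported parameter map version {d.get('version')!r}; "
                f"this build reads version {PARAMETER_MAP_VERSION}"
            )
        slots = tuple(
            Slot(
                name=s["name"], kind=s["kind"],
                targets=tuple(tuple(t) if isinstance(t, list) else t for t in s["targets"]),
                low=float(s["low"]), high=float(s["high"]),
            )
            for s in d["slots"]
        )
        return cls(slots=slots, constants=dict(d.get("constants", {})))


def default_parameter_map() -> ParameterMap:
    """The default 20-slot map for the minimal klinotaxis circuit."""
    W = (-15.0, 15.0)
    G = (0.0, 15.0)
    NM = (0.1, 4.2)
    slots = (
        Slot("N", "sensory_N", ("ASEL", "ASER"), *NM),
        Slot("M", "sensory_M", ("ASEL", "ASER"), *NM),
        Slot("w_ASEL_AIYL", "chem", (("ASEL", "AIYL"),), *W),
        Slot("w_ASEL_AIYR", "chem", (("ASEL", "AIYR"),), *W),
        Slot("w_ASER_AIYL", "chem", (("ASER", "AIYL"),), *W),
        Slot("w_ASER_AIYR", "chem", (("ASER", "AIYR"),), *W),
        Slot("theta_AIYL", "theta", ("AIYL",), *W),
        Slot("theta_AIYR", "theta", ("AIYR",), *W),
        Slot("g_AIY", "gap", (("AIYL", "AIYR"),), *G),
        Slot("w_AIYL_AIZL", "chem", (("AIYL", "AIZL"),), *W),
        Slot("w_AIYR_AIZR", "chem", (("AIYR", "AIZR"),), *W),
        Slot("theta_AIZL", "theta", ("AIZL",), *W),
        Slot("theta_AIZR", "theta", ("AIZR",), *W),
        Slot("g_AIZ", "gap", (("AIZL", "AIZR"),), *G),
        Slot("w_AIZL_SMBL", "chem", (("AIZL", "SMBDL"), ("AIZL", "SMBVL")), *W),
        Slot("w_AIZR_SMBR", "chem", (("AIZR", "SMBDR"), ("AIZR", "SMBVR")), *W),
        Slot("theta_SMBL", "theta", ("SMBDL", "SMBVL"), *W),
        Slot("theta_SMBR", "theta", ("SMBDR", "SMBVR"), *W),
        Slot("wself_SMBL", "w_self", ("SMBDL", "SMBVL"), *W),
        Slot("wself_SMBR", "w_self", ("SMBDR", "SMBVR"), *W),
    )
    return ParameterMap(slots=slots)


def decode(genotype: np.ndarray, pmap: ParameterMap | None = None) -> CircuitParameters:
    """Linearly map a genotype onto a full circuit parameter set."""
    if pmap is None:
        pmap = default_parameter_map()
    genotype = np.asarray(genotype, dtype=float)
    if genotype.shape != (len(pmap),):
        raise ValueError(f"genotype must have {len(pmap)} entries, got {genotype.shape}")
    if np.any(np.abs(genotype) > 1.0):
        raise ValueError("genotype entries must lie in [-1, 1]")
    tau = float(pmap.constants.get("tau", 1.5))
    w_osc = float(pmap.constants.get("w_osc", 10.0))
    w_nmj = float(pmap.constants.get("w_nmj", 1.0))
    sens_N: dict[str, float] = {}
    sens_M: dict[str, float] = {}
    theta = {n: 0.0 for n in NEURON_ORDER}
    w_self = {n: 0.0 for n in NEURON_ORDER}
    chem_w: dict[tuple[str, str], float] = {}
    gap_g: dict[tuple[str, str], float] = {}
    for slot, gene in zip(pmap.slots, genotype):
        value = slot.to_value(float(gene))
        if slot.kind == "sensory_N":
            for t in slot.targets:
                sens_N[t] = value
        elif slot.kind == "sensory_M":
            for t in slot.targets:
                sens_M[t] = value
        elif slot.kind == "chem":
            for t in slot.targets:
                chem_w[tuple(t)] = value
        elif slot.kind == "gap":
            for t in slot.targets:
                gap_g[tuple(t)] = value
        elif slot.kind == "theta":
            for t in slot.targets:
                theta[t] = value
        elif slot.kind == "w_self":
            for t in slot.targets:
                w_self[t] = value
        else:
            raise ValueError(f"unknown slot kind {slot.kind!r}")
    sensory = {
        "ASEL": SensoryParams(N=sens_N["ASEL"], M=sens_M["ASEL"], polarity="ON"),
        "ASER": SensoryParams(N=sens_N["ASER"], M=sens_M["ASER"], polarity="OFF"),
    }
    neurons = {
        n: NeuronParams(
            tau=tau,
            theta=theta[n],
            w_self=w_self[n],
            w_osc=w_osc if n.startswith("SMB") else 0.0,
        )
        for n in NEURON_ORDER
    }
    chem = tuple(ChemicalSynapse(pre, post, w) for (pre, post), w in chem_w.items())
    gaps = tuple(GapJunction(a, b, g) for (a, b), g in gap_g.items())
    return CircuitParameters(
        sensory=sensory, neurons=neurons, chem=chem, gaps=gaps, w_nmj=w_nmj,
        provenance={"parameter_map": pmap.to_dict(),
                    "genotype": [float(g) for g in genotype]},
    )


def encode(params: CircuitParameters, pmap: ParameterMap | None = None) -> np.ndarray:
    """Inverse of :func:`decode`: read each slot's value back off the circuit."""
    if pmap is None:
        pmap = default_parameter_map()
    chem_w = {(s.pre, s.post): s.w for s in params.chem}
    gap_g = {(g.a, g.b): g.g for g in params.gaps}
    genes = np.empty(len(pmap))
    for i, slot in enumerate(pmap.slots):
        t = slot.targets[0]
        if slot.kind == "sensory_N":
            value = params.sensory[t].N
        elif slot.kind == "sensory_M":
            value = params.sensory[t].M
        elif slot.kind == "chem":
            value = chem_w[tuple(t)]
        elif slot.kind == "gap":
            value = gap_g[tuple(t)]
        elif slot.kind == "theta":
            value = params.neurons[t].theta
        elif slot.kind == "w_self":
            value = params.neurons[t].w_self
        else:
            raise ValueError(f"unknown slot kind {slot.kind!r}")
        genes[i] = slot.to_gene(value)
    return genes


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``selection`` is either ``"truncation"`` (the top ``elite_fraction``
    of the population is copied unchanged and cloned-with-mutation to
    fill the rest) or ``"tournament"`` (binary tournaments pick parents
    from the whole population; offspring undergo uniform crossover with
    probability ``crossover_prob`` and Gaussian mutation; the top
    ``elite_count`` individuals survive unchanged).
    """

    population_size: int = 60
    generations: int = 300
    assays_per_fitness: int = 50
    selection: str = "tournament"
    elite_fraction: float = 1.0 / 3.0
    elite_count: int = 2
    tournament_size: int = 2
    crossover_prob: float = 0.5
    mutation_sigma: float = 0.05
    assay_duration: float = 500.0
    dt: float = 0.01
    pirouette_rate: float = 0.033
    alpha_range: tuple[float, float] = (-0.38, -0.01)
    start_distance: float = 4.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.selection not in ("truncation", "tournament"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")


def fitness(
    genotype: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    pmap: ParameterMap | None = None,
    assay_seeds: list[int] | None = None,
) -> float:
    """Mean CI over ``assays_per_fitness`` randomized conical-gradient assays.

    When ``assay_seeds`` is given, assay ``a`` derives all its
    randomness (steepness, heading, motor initialization, pirouettes)
    from ``assay_seeds[a]`` instead of the shared stream; evaluating a
    whole population on one seed list compares individuals under
    common random conditions, which sharpens selection under noisy
    fitness.
    """
    params = decode(genotype, pmap)
    compiled = engine.compile_circuit(params, cfg.dt)
    total = 0.0
    for a in range(cfg.assays_per_fitness):
        if assay_seeds is not None:
            rng = np.random.default_rng(assay_seeds[a])
        alpha = rng.uniform(*cfg.alpha_range)
        acfg = AssayConfig(
            duration=cfg.assay_duration,
            start_distance=cfg.start_distance,
            dt=cfg.dt,
            pirouette_rate=cfg.pirouette_rate,
            gradient=GradientSpec(shape="conical", alpha=alpha),
        )
        total += run_assay(
            params, acfg, rng=rng, compiled=compiled, build_trajectory=False
        ).ci
    return total / cfg.assays_per_fitness


@dataclass
class GAResult:
    best_genotype: np.ndarray
    best_fitness: float
    best_circuit: CircuitParameters
    trace: "object"  # pandas DataFrame: generation, best, mean, best_so_far


def run_ga(
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
    pmap: ParameterMap | None = None,
    fitness_fn=None,
    log=None,
) -> GAResult:
    """Evolve a population and return the final generation's best individual.

    ``fitness_fn(genotype, rng) -> float`` may replace the default
    assay-based fitness (used for surrogate-objective sanity checks).
    ``log`` is an optional callable receiving one line per generation.
    """
    import pandas as pd

    if pmap is None:
        pmap = default_parameter_map()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    use_crn = fitness_fn is None
    n_genes = len(pmap)
    pop = rng.uniform(-1.0, 1.0, size=(cfg.population_size, n_genes))
    n_elite = max(1, round(cfg.population_size * cfg.elite_fraction))
    rows = []
    best_so_far = -np.inf
    fits = np.empty(cfg.population_size)
    order = np.arange(cfg.population_size)
    for gen in range(cfg.generations):
        if use_crn:
            seeds = [int(s) for s in
                     rng.integers(0, 2**31 - 1, size=cfg.assays_per_fitness)]
            for i in range(cfg.population_size):
                fits[i] = fitness(pop[i], cfg, rng, pmap, assay_seeds=seeds)
        else:
            for i in range(cfg.population_size):
                fits[i] = fitness_fn(pop[i], rng)
        order = np.argsort(-fits)
        best = float(fits[order[0]])
        best_so_far = max(best_so_far, best)
        rows.append(
            {"generation": gen, "best": best, "mean": float(fits.mean()),
             "best_so_far": best_so_far}
        )
        if log is not None:
            log(f"generation {gen:4d}  best {best:.4f}  mean {fits.mean():.4f}")
        if gen == cfg.generations - 1:
            break
        if cfg.selection == "truncation":
            elites = pop[order[:n_elite]]
            children = []
            i = 0
            while len(children) < cfg.population_size - n_elite:
                parent = elites[i % n_elite]
                child = parent + rng.normal(0.0, cfg.mutation_sigma, size=n_genes)
                children.append(np.clip(child, -1.0, 1.0))
                i += 1
            pop = np.vstack([elites, np.array(children)])
        else:  # tournament
            elites = pop[order[:cfg.elite_count]].copy()
            children = []
            while len(children) < cfg.population_size - cfg.elite_count:
                cand = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                p1 = pop[cand[np.argmax(fits[cand])]]
                if rng.random() < cfg.crossover_prob:
                    cand = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                    p2 = pop[cand[np.argmax(fits[cand])]]
                    mask = rng.random(n_genes) < 0.5
                    child = np.where(mask, p1, p2)
                else:
                    child = p1.copy()
                child = child + rng.normal(0.0, cfg.mutation_sigma, size=n_genes)
                children.append(np.clip(child, -1.0, 1.0))
            pop = np.vstack([elites, np.array(children)])
    best_geno = pop[order[0]].copy()
    circuit = decode(best_geno, pmap)
    circuit = replace(
        circuit,
        provenance={**circuit.provenance,
                    "ga_config": {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in vars(cfg).items()},
                    "final_generation_fitness": float(fits[order[0]])},
    )
    return GAResult(
        best_genotype=best_geno,
        best_fitness=float(fits[order[0]]),
        best_circuit=circuit,
        trace=pd.DataFrame(rows),
    )


def retest_ci(
    params: CircuitParameters,
    n_assays: int = 50,
    duration: float = 1000.0,
    gradient_shape: str = "conical",
    alpha_range: tuple[float, float] = (-0.38, -0.01),
    pirouette_rate: float = 0.033,
    dt: float = 0.01,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Re-test a circuit on longer assays; returns (mean CI, reliability)."""
    rng = np.random.default_rng(seed)
    compiled = engine.compile_circuit(params, dt)
    cis, reached = [], []
    for _ in range(n_assays):
        if gradient_shape == "conical":
            grad = GradientSpec(shape="conical", alpha=rng.uniform(*alpha_range))
        else:
            grad = GradientSpec(shape="gaussian")
        acfg = AssayConfig(
            duration=duration, dt=dt, pirouette_rate=pirouette_rate, gradient=grad
        )
        res = run_assay(params, acfg, rng=rng, compiled=compiled,
                        build_trajectory=False)
        cis.append(res.ci)
        reached.append(res.reached_peak)
    return float(np.mean(cis)), float(np.mean(reached))
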