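"""Run repeated GA searches and collect an ensemble of evolved circuits.

Each run evolves a population against the chemotaxis-index fitness on
conical gradients, then re-tests the best individual on longer assays
at the standard integration step.  Circuits are written as JSON with
their fitness trace and re-test statistics embedded in provenance.

Usage:
    python scripts/evolve_ensemble.py --runs 14 --seed-base 1000 \
        --generations 150 --assays 25 --dt 0.02 --out scratch/ensemble_runs
"""

from __future__ import annotations

import argparse
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from wormtaxis import evolution, fixtures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--runs", type=int, default=14)
    ap.add_argument("--seed-base", type=int, default=1000)
    ap.add_argument("--population", type=int, default=60)
    ap.add_argument("--generations", type=int, default=150)
    ap.add_argument("--assays", type=int, default=25)
    ap.add_argument("--dt", type=float, default=0.02)
    ap.add_argument("--retest-assays", type=int, default=25)
    ap.add_argument("--retest-duration", type=float, default=1000.0)
    ap.add_argument("--out", type=Path, default=Path("scratch/ensemble_runs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    summary = []
    for r in range(args.runs):
        seed = args.seed_base + r
        cfg = evolution.GAConfig(
            population_size=args.population,
            generations=args.generations,
            assays_per_fitness=args.assays,
            dt=args.dt,
            seed=seed,
        )
        log_path = args.out / f"run_{seed}.log"
        t0 = time.time()
        with open(log_path, "w") as fh:
            res = evolution.run_ga(
                cfg, log=lambda s: (fh.write(s + "\n"), fh.flush())
            )
        ci_con, rel_con = evolution.retest_ci(
            res.best_circuit, n_assays=args.retest_assays,
            duration=args.retest_duration, gradient_shape="conical",
            dt=0.01, seed=seed,
        )
        ci_gau, rel_gau = evolution.retest_ci(
            res.best_circuit, n_assays=args.retest_assays,
            duration=args.retest_duration, gradient_shape="gaussian",
            dt=0.01, seed=seed,
        )
        circuit = replace(
            res.best_circuit,
            provenance={
                **res.best_circuit.provenance,
                "seed": seed,
                "retest": {
                    "ci_conical": ci_con, "reliability_conical": rel_con,
                    "ci_gaussian": ci_gau, "reliability_gaussian": rel_gau,
                    "n_assays": args.retest_assays,
                    "duration": args.retest_duration,
                },
            },
        )
        fixtures.save_circuit(circuit, args.out / f"circuit_{seed}.json")
        res.trace.to_csv(args.out / f"trace_{seed}.csv", index=False)
        row = {
            "seed": seed,
            "final_fitness": res.best_fitness,
            "ci_conical": ci_con, "reliability_conical": rel_con,
            "ci_gaussian": ci_gau, "reliability_gaussian": rel_gau,
            "minutes": (time.time() - t0) / 60.0,
        }
        summary.append(row)
        print(json.dumps(row), flush=True)
        (args.out / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
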