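"""Build an ensemble of klinotaxis circuits by derandomized refinement.

Starting from a seed genotype (typically the best circuit from a prior
search), each run perturbs the genotype, re-refines it with Nelder-Mead
on a common-random-number chemotaxis-index objective (stratified
gradient steepness and start headings, pirouettes on), re-tests the
result on fresh long assays at the standard integration step, and
writes the circuit with full provenance.

Usage:
    python scripts/refine_ensemble.py --seed-genome scratch/final_opt_genome.npy \
        --runs 8 --out scratch/refined_ensemble
"""

from __future__ import annotations

import argparse
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from wormtaxis import engine, evolution, fixtures
from wormtaxis.assay import chemotaxis_index
from wormtaxis.world import GradientSpec

ALPHAS = (-0.35, -0.25, -0.15, -0.08, -0.03)
HEADS = (0.3, 1.4, 2.4, -0.8, -1.9, -2.9)


def crn_objective(pm, dt=0.02, dur=800.0, pir=0.033, seed_round=0):
    conds = [(al, hd, 100_000 * seed_round + 17 * i + j)
             for i, al in enumerate(ALPHAS) for j, hd in enumerate(HEADS)]

    def obj(genes):
        g = np.clip(genes, -1, 1)
        params = evolution.decode(g, pm)
        comp = engine.compile_circuit(params, dt)
        tot = 0.0
        for al, hd, sd in conds:
            rng = np.random.default_rng(sd)
            y0 = np.zeros(8)
            y0[4:] = rng.uniform(0, 1, 4)
            sim = engine.simulate(
                comp, dt, int(dur / dt),
                gradient=GradientSpec(shape="conical", alpha=al),
                y_init=y0, pose0=(4.5, 0.0, float(np.pi + hd)),
                pirouette_rate=pir, rng=rng,
            )
            tot += chemotaxis_index(sim.h, 4.5, dur)
        return -tot / len(conds)

    return obj


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed-genome", type=Path, required=True)
    ap.add_argument("--runs", type=int, default=8)
    ap.add_argument("--seed-base", type=int, default=5000)
    ap.add_argument("--sigma", type=float, default=0.08)
    ap.add_argument("--maxfev", type=int, default=900)
    ap.add_argument("--rounds", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("scratch/refined_ensemble"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    pm = evolution.default_parameter_map()
    g_seed = np.load(args.seed_genome)
    summary = []
    for r in range(args.runs):
        seed = args.seed_base + r
        rng = np.random.default_rng(seed)
        g = np.clip(g_seed + rng.normal(0.0, args.sigma, g_seed.shape), -1, 1)
        t0 = time.time()
        for rnd in range(args.rounds):
            obj = crn_objective(pm, seed_round=seed * 10 + rnd)
            res = minimize(obj, g, method="Nelder-Mead",
                           options=dict(maxfev=args.maxfev, adaptive=True))
            g = np.clip(res.x, -1, 1)
        params = evolution.decode(g, pm)
        ci_con, rel_con = evolution.retest_ci(
            params, n_assays=25, duration=1000.0,
            gradient_shape="conical", dt=0.01, seed=seed,
        )
        ci_gau, rel_gau = evolution.retest_ci(
            params, n_assays=25, duration=1000.0,
            gradient_shape="gaussian", dt=0.01, seed=seed + 500,
        )
        params = replace(params, provenance={
            **params.provenance,
            "pipeline": "perturbed multi-round Nelder-Mead refinement of a "
                        "common-random-number chemotaxis-index objective",
            "seed": seed,
            "perturbation_sigma": args.sigma,
            "objective": {"dt": 0.02, "duration": 800.0, "pirouette_rate": 0.033,
                          "alphas": list(ALPHAS), "headings": list(HEADS)},
            "retest": {
                "ci_conical": ci_con, "reliability_conical": rel_con,
                "ci_gaussian": ci_gau, "reliability_gaussian": rel_gau,
                "n_assays": 25, "duration": 1000.0, "dt": 0.01,
            },
        })
        fixtures.save_circuit(params, args.out / f"circuit_{seed}.json")
        row = {"seed": seed, "ci_conical": ci_con, "rel_conical": rel_con,
               "ci_gaussian": ci_gau, "rel_gaussian": rel_gau,
               "minutes": (time.time() - t0) / 60.0}
        summary.append(row)
        print(json.dumps(row), flush=True)
        (args.out / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
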