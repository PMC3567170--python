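"""Synthetic data generators, packaged fixtures and circuit serialization.

Packaged data (all plain text, under ``wormtaxis/data/``):

* ``minimal_connectome.csv`` — a hand-written connectivity table whose
  high-contact core is the minimal klinotaxis circuit (ASE sensors, AIY
  and AIZ interneuron pairs with lateral gap junctions, SMB neck motor
  quartet), plus low-contact and long-path decoy neurons that the
  constrained search must prune.
* ``ensemble/*.json`` — circuits evolved with this package's genetic
  algorithm, re-tested and kept at CI >= 0.75; used by the analysis
  battery so results can be reproduced without re-evolving.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .circuit import (
    ChemicalSynapse,
    CircuitParameters,
    GapJunction,
    NeuronParams,
    SensoryParams,
)
from .connectome import ConnectomeGraph, Subnetwork

CIRCUIT_SCHEMA_VERSION = "1"

__all__ = [
    "make_synthetic_connectome",
    "minimal_circuit_topology",
    "minimal_connectome_path",
    "save_circuit",
    "load_circuit",
    "circuit_to_dict",
    "circuit_from_dict",
    "packaged_ensemble",
    "best_fixture_circuit",
]


def make_synthetic_connectome(
    n_sensors: int,
    n_inter: int,
    n_motors: int,
    edge_density: float = 1.0,
    contact_max: int = 5,
    seed: int = 0,
) -> tuple[ConnectomeGraph, dict]:
    """Random layered sensor -> interneuron -> motor connectome.

    Chemical edges run forward between consecutive layers with
    probability ``edge_density``; gap junctions connect interneuron
    pairs with probability ``edge_density / 2``.  Returns the graph and
    a ground-truth record (layer membership and the minimal
    fully-connected depth implied by the construction: 2 when every
    forward edge is present, None when the density is 0).
    """
    if min(n_sensors, n_inter, n_motors) < 1:
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    sensors = [f"S{i}" for i in range(n_sensors)]
    inters = [f"I{i}" for i in range(n_inter)]
    motors = [f"M{i}" for i in range(n_motors)]
    chem: list[tuple[str, str, int]] = []
    gaps: list[tuple[str, str, int]] = []
    for layer_a, layer_b in ((sensors, inters), (inters, motors)):
        for a in layer_a:
            for b in layer_b:
                if rng.random() < edge_density:
                    chem.append((a, b, int(rng.integers(1, contact_max + 1))))
    for i in range(n_inter):
        for j in range(i + 1, n_inter):
            if rng.random() < edge_density / 2.0:
                gaps.append((inters[i], inters[j], int(rng.integers(1, contact_max + 1))))
    graph = ConnectomeGraph(
        neurons=set(sensors + inters + motors),
        chemical_edges=chem,
        gap_edges=gaps,
    )
    truth = {
        "sensors": sensors,
        "interneurons": inters,
        "motors": motors,
        "expected_depth": 2 if edge_density >= 1.0 else None,
        "seed": seed,
    }
    return graph, truth


#: Minimal klinotaxis circuit: neuron list and anatomical edges.
_MINIMAL_CHEM = (
    ("ASEL", "AIYL", 6), ("ASEL", "AIYR", 2),
    ("ASER", "AIYL", 2), ("ASER", "AIYR", 8),
    ("AIYL", "AIZL", 6), ("AIYR", "AIZR", 6),
    ("AIZL", "SMBDL", 2), ("AIZL", "SMBVL", 3),
    ("AIZR", "SMBDR", 2), ("AIZR", "SMBVR", 3),
    ("SMBDL", "SMBDL", 1), ("SMBVL", "SMBVL", 1),
    ("SMBDR", "SMBDR", 1), ("SMBVR", "SMBVR", 1),
)
_MINIMAL_GAPS = (("AIYL", "AIYR", 1), ("AIZL", "AIZR", 2))


def minimal_circuit_topology() -> Subnetwork:
    """The minimal klinotaxis circuit: 10 neurons, two lateral gap
    junctions (AIY with one contact, AIZ with two), feedforward chemical
    paths ASE -> AIY -> AIZ -> SMB and SMB self-connections."""
    neurons = {n for e in _MINIMAL_CHEM for n in e[:2]}
    paths = [
        (s, f"AIY{side}", f"AIZ{side}", m)
        for s in ("ASEL", "ASER")
        for side in ("L", "R")
        for m in (f"SMBD{side}", f"SMBV{side}")
    ]
    return Subnetwork(
        neurons=neurons,
        chemical_edges=list(_MINIMAL_CHEM),
        gap_edges=list(_MINIMAL_GAPS),
        paths=paths,
    )


def minimal_connectome_path() -> Path:
    """Path to the packaged minimal-circuit connectivity table."""
    return Path(str(resources.files("wormtaxis") / "data" / "minimal_connectome.csv"))


def circuit_to_dict(params: CircuitParameters) -> dict:
    return {
        "schema_version": CIRCUIT_SCHEMA_VERSION,
        "sensory": {
            name: {"N": p.N, "M": p.M, "polarity": p.polarity}
            for name, p in params.sensory.items()
        },
        "neurons": {
            name: {"tau": p.tau, "theta": p.theta, "w_self": p.w_self, "w_osc": p.w_osc}
            for name, p in params.neurons.items()
        },
        "chem": [{"pre": s.pre, "post": s.post, "w": s.w} for s in params.chem],
        "gaps": [{"a": g.a, "b": g.b, "g": g.g} for g in params.gaps],
        "w_nmj": params.w_nmj,
        "provenance": params.provenance,
    }


def circuit_from_dict(d: dict) -> CircuitParameters:
    version = d.get("schema_version")
    if version != CIRCUIT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported circuit schema version {version!r}; "
            f"this build reads version {CIRCUIT_SCHEMA_VERSION}"
        )
    missing = [k for k in ("sensory", "neurons", "chem", "gaps", "w_nmj") if k not in d]
    if missing:
        raise ValueError(f"circuit file missing required fields: {missing}")
    return CircuitParameters(
        sensory={
            name: SensoryParams(N=s["N"], M=s["M"], polarity=s["polarity"])
            for name, s in d["sensory"].items()
        },
        neurons={
            name: NeuronParams(
                tau=p["tau"], theta=p["theta"],
                w_self=p.get("w_self", 0.0), w_osc=p.get("w_osc", 0.0),
            )
            for name, p in d["neurons"].items()
        },
        chem=tuple(ChemicalSynapse(s["pre"], s["post"], s["w"]) for s in d["chem"]),
        gaps=tuple(GapJunction(g["a"], g["b"], g["g"]) for g in d["gaps"]),
        w_nmj=float(d["w_nmj"]),
        provenance=d.get("provenance", {}),
    )


def save_circuit(params: CircuitParameters, path: str | Path) -> None:
    """Serialize a circuit to JSON (deterministic layout: a save/load/save
    cycle is byte-identical)."""
    Path(path).write_text(
        json.dumps(circuit_to_dict(params), indent=2, sort_keys=True) + "\n"
    )


def load_circuit(path: str | Path) -> CircuitParameters:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path} is not valid JSON: {exc}") from exc
    return circuit_from_dict(d)


def packaged_ensemble() -> list[CircuitParameters]:
    """All packaged evolved circuits, sorted by filename."""
    root = resources.files("wormtaxis") / "data" / "ensemble"
    circuits = []
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            circuits.append(circuit_from_dict(json.loads(entry.read_text())))
    return circuits


def best_fixture_circuit() -> CircuitParameters:
    """The packaged circuit with the highest re-tested CI."""
    ens = packaged_ensemble()
    if not ens:
        raise FileNotFoundError("no packaged ensemble circuits found")
    return max(ens, key=lambda c: c.provenance.get("retest", {}).get("ci_conical", 0.0))
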