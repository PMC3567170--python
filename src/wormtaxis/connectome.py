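"""Connectome loading and constrained path search.

The wiring diagram of *C. elegans* is available as a table of pairwise
connections: directed chemical synapses and undirected electrical gap
junctions, each annotated with the number of anatomical contacts.  A
candidate sensorimotor circuit for a behavior can be extracted by
enumerating all paths from a *root set* of sensory neurons to a *target
set* of motor neurons, subject to two constraints: a depth limit on path
length (in synaptic hops) and a minimum contact number between
consecutive neurons.  The *contact number* of a neuron pair is the total
count of chemical synapses (both directions) plus gap junctions between
the two cells.

Chemical synapses are traversed pre -> post only; gap junctions carry
current both ways and are traversed in either direction.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeGraph",
    "SearchConstraints",
    "Subnetwork",
    "load_connectome",
    "find_network",
    "is_fully_connected",
    "minimal_fully_connected_depth",
    "network_stats",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ConnectomeGraph:
    """Neurons plus chemical (directed) and gap (undirected) edges.

    ``chemical_edges`` are ``(pre, post, contacts)`` triples;
    ``gap_edges`` are ``(a, b, contacts)`` with ``a <= b`` and each
    unordered pair appearing at most once.
    """

    neurons: set[str] = field(default_factory=set)
    chemical_edges: list[tuple[str, str, int]] = field(default_factory=list)
    gap_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gap_edges = [(*_pair(a, b), c) for a, b, c in self.gap_edges]
        seen_gap: set[tuple[str, str]] = set()
        for a, b, c in self.gap_edges:
            if c < 1:
                raise ValueError(f"gap edge {a}-{b} has contacts {c} < 1")
            if (a, b) in seen_gap:
                raise ValueError(f"duplicate gap pair {a}-{b}")
            seen_gap.add((a, b))
        for pre, post, c in self.chemical_edges:
            if c < 1:
                raise ValueError(f"chemical edge {pre}->{post} has contacts {c} < 1")
        for e in self.chemical_edges:
            self.neurons.update(e[:2])
        for e in self.gap_edges:
            self.neurons.update(e[:2])

    def pair_contacts(self) -> dict[tuple[str, str], int]:
        """Total contact number per unordered neuron pair (chemical both
        directions plus gap junctions)."""
        totals: dict[tuple[str, str], int] = {}
        for pre, post, c in self.chemical_edges:
            p = _pair(pre, post)
            totals[p] = totals.get(p, 0) + c
        for a, b, c in self.gap_edges:
            p = _pair(a, b)
            totals[p] = totals.get(p, 0) + c
        return totals

    def n_chemical(self) -> int:
        return len(self.chemical_edges)

    def n_gap(self) -> int:
        return len(self.gap_edges)


@dataclass(frozen=True)
class SearchConstraints:
    """Constraints for the root-to-target path search.

    ``contact_threshold`` is the minimum contact number a neuron pair
    must have for the connection to be traversable; by default it is
    evaluated per pair (chemical + gap summed).  ``per_edge=True``
    instead requires each individual edge's own contact count to meet
    the threshold.
    """

    root_set: frozenset[str]
    target_set: frozenset[str]
    depth_limit: int
    contact_threshold: int = 0
    per_edge: bool = False

    def __post_init__(self) -> None:
        if not self.root_set or not self.target_set:
            raise ValueError("root_set and target_set must be nonempty")
        if self.depth_limit < 1:
            raise ValueError(f"depth_limit must be >= 1, got {self.depth_limit}")
        if self.contact_threshold < 0:
            raise ValueError("contact_threshold must be non-negative")


@dataclass
class Subnetwork:
    """Union of all surviving root-to-target paths.

    ``paths`` are neuron-name sequences (first element in the root set,
    last in the target set); path length is counted in hops.
    """

    neurons: set[str] = field(default_factory=set)
    chemical_edges: list[tuple[str, str, int]] = field(default_factory=list)
    gap_edges: list[tuple[str, str, int]] = field(default_factory=list)
    paths: list[tuple[str, ...]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "neurons": sorted(self.neurons),
                "chemical_edges": [
                    {"pre": a, "post": b, "contacts": c}
                    for a, b, c in sorted(self.chemical_edges)
                ],
                "gap_edges": [
                    {"a": a, "b": b, "contacts": c}
                    for a, b, c in sorted(self.gap_edges)
                ],
                "paths": [list(p) for p in self.paths],
            },
            indent=2,
        )

    def to_dot(self) -> str:
        """Graphviz DOT export; gap junctions drawn as undirected red edges."""
        out = io.StringIO()
        out.write("digraph klinotaxis {\n")
        for n in sorted(self.neurons):
            out.write(f'  "{n}";\n')
        for a, b, c in sorted(self.chemical_edges):
            out.write(f'  "{a}" -> "{b}" [label="{c}"];\n')
        for a, b, c in sorted(self.gap_edges):
            out.write(f'  "{a}" -> "{b}" [dir=none, color=red, label="{c}"];\n')
        out.write("}\n")
        return out.getvalue()


class ConnectomeParseError(ValueError):
    """Malformed connectivity table row."""


def load_connectome(table_path: str | Path, delimiter: str | None = None) -> ConnectomeGraph:
    """Load a connectivity table with header ``pre,post,kind,contacts``.

    Comma or tab delimiter is auto-detected when ``delimiter`` is None.
    Multiple rows for the same (pair, kind) are summed into a single
    edge's contact count.  Chemical rows are directional; gap rows are
    unordered (``A,B,gap`` and ``B,A,gap`` accumulate the same edge).
    """
    path = Path(table_path)
    text = path.read_text()
    if delimiter is None:
        header = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in header else ","
    chem: dict[tuple[str, str], int] = {}
    gaps: dict[tuple[str, str], int] = {}
    neurons: set[str] = set()
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    for lineno, row in enumerate(reader, start=1):
        if not row or all(not f.strip() for f in row):
            continue
        if lineno == 1 and row[0].strip().lower() == "pre":
            continue
        if len(row) != 4:
            raise ConnectomeParseError(
                f"{path}:{lineno}: expected 4 columns (pre, post, kind, contacts), got {len(row)}"
            )
        pre, post, kind, contacts_s = (f.strip() for f in row)
        if kind not in ("chemical", "gap"):
            raise ConnectomeParseError(
                f"{path}:{lineno}: kind must be 'chemical' or 'gap', got {kind!r}"
            )
        try:
            contacts = int(contacts_s)
        except ValueError as exc:
            raise ConnectomeParseError(
                f"{path}:{lineno}: contacts must be an integer, got {contacts_s!r}"
            ) from exc
        if contacts <= 0:
            raise ConnectomeParseError(
                f"{path}:{lineno}: contacts must be positive, got {contacts}"
            )
        neurons.update((pre, post))
        if kind == "chemical":
            chem[(pre, post)] = chem.get((pre, post), 0) + contacts
        else:
            p = _pair(pre, post)
            gaps[p] = gaps.get(p, 0) + contacts
    if not neurons:
        logger.warning("connectome table %s is empty", path)
    return ConnectomeGraph(
        neurons=neurons,
        chemical_edges=[(a, b, c) for (a, b), c in chem.items()],
        gap_edges=[(a, b, c) for (a, b), c in gaps.items()],
    )


def _traversal_graph(graph: ConnectomeGraph, constraints: SearchConstraints) -> nx.DiGraph:
    """Directed traversal graph honoring the contact threshold.

    Chemical edges go pre->post; gap edges both ways.
    """
    pair_totals = graph.pair_contacts()
    g = nx.DiGraph()
    g.add_nodes_from(graph.neurons)
    thr = constraints.contact_threshold
    for pre, post, c in graph.chemical_edges:
        ok = c >= thr if constraints.per_edge else pair_totals[_pair(pre, post)] >= thr
        if ok and pre != post:
            g.add_edge(pre, post)
    for a, b, c in graph.gap_edges:
        ok = c >= thr if constraints.per_edge else pair_totals[_pair(a, b)] >= thr
        if ok and a != b:
            g.add_edge(a, b)
            g.add_edge(b, a)
    return g


def find_network(
    graph: ConnectomeGraph,
    constraints: SearchConstraints,
    include_induced: bool = False,
) -> Subnetwork:
    """Enumerate all simple root-to-target paths within the constraints.

    Returns the union of surviving paths.  With ``include_induced=True``
    the subnetwork additionally contains every connectome edge between
    retained neurons (regardless of threshold) — lateral gap junctions
    and motor self-connections sit on no simple sensor-to-motor path but
    are part of the anatomical circuit.
    """
    missing = (constraints.root_set | constraints.target_set) - graph.neurons
    if missing:
        raise KeyError(f"neurons not in connectome: {sorted(missing)}")
    tg = _traversal_graph(graph, constraints)
    paths: list[tuple[str, ...]] = []
    for root in sorted(constraints.root_set):
        for target in sorted(constraints.target_set):
            if root == target:
                continue
            for p in nx.all_simple_paths(tg, root, target, cutoff=constraints.depth_limit):
                paths.append(tuple(p))
    nodes: set[str] = set()
    used_pairs: set[tuple[str, str]] = set()  # directed steps actually walked
    for p in paths:
        nodes.update(p)
        used_pairs.update(zip(p, p[1:]))
    chem_edges = []
    gap_edges = []
    for pre, post, c in graph.chemical_edges:
        on_path = (pre, post) in used_pairs
        induced = include_induced and pre in nodes and post in nodes
        if on_path or induced:
            chem_edges.append((pre, post, c))
    for a, b, c in graph.gap_edges:
        on_path = (a, b) in used_pairs or (b, a) in used_pairs
        induced = include_induced and a in nodes and b in nodes
        if on_path or induced:
            gap_edges.append((a, b, c))
    return Subnetwork(neurons=nodes, chemical_edges=chem_edges, gap_edges=gap_edges, paths=paths)


def is_fully_connected(sub: Subnetwork, roots: set[str], targets: set[str]) -> bool:
    """True iff every (root, target) pair is joined by a retained path."""
    covered = {(p[0], p[-1]) for p in sub.paths}
    return all((r, t) in covered for r in roots for t in targets if r != t) and bool(roots) and bool(targets)


def minimal_fully_connected_depth(
    graph: ConnectomeGraph,
    roots: set[str],
    targets: set[str],
    contact_threshold: int = 0,
    per_edge: bool = False,
) -> int | None:
    """Smallest depth limit at which the subnetwork is fully connected.

    Returns None if some pair is unreachable at any depth up to the
    neuron count (the longest possible simple path).
    """
    for depth in range(1, max(len(graph.neurons), 1) + 1):
        sub = find_network(
            graph,
            SearchConstraints(
                root_set=frozenset(roots),
                target_set=frozenset(targets),
                depth_limit=depth,
                contact_threshold=contact_threshold,
                per_edge=per_edge,
            ),
        )
        if is_fully_connected(sub, roots, targets):
            return depth
    return None


def network_stats(sub: Subnetwork, full: ConnectomeGraph) -> dict:
    """Neuron/edge counts and fractions of the full connectome retained."""

    def frac(n: int, d: int) -> float:
        return n / d if d else 0.0

    return {
        "n_neurons": len(sub.neurons),
        "n_chemical": len(sub.chemical_edges),
        "n_gap": len(sub.gap_edges),
        "frac_neurons": frac(len(sub.neurons), len(full.neurons)),
        "frac_chemical": frac(len(sub.chemical_edges), full.n_chemical()),
        "frac_gap": frac(len(sub.gap_edges), full.n_gap()),
        "n_paths": len(sub.paths),
    }
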