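"""Connectome loading and constrained path-search tests.

The search oracle here is an independent recursive enumeration of all
simple paths, written without networkx, against which the production
implementation is compared on random graphs.
"""

import numpy as np
import pytest

from wormtaxis.connectome import (
    ConnectomeGraph,
    ConnectomeParseError,
    SearchConstraints,
    find_network,
    is_fully_connected,
    load_connectome,
    minimal_fully_connected_depth,
    network_stats,
)


def write_table(tmp_path, rows, delimiter=","):
    p = tmp_path / "table.csv"
    lines = [delimiter.join(["pre", "post", "kind", "contacts"])]
    lines += [delimiter.join(str(x) for x in r) for r in rows]
    p.write_text("\n".join(lines) + "\n")
    return p


# --------------------------------------------------------------------------
# loading


def test_load_basic_graph(tmp_path):
    p = write_table(tmp_path, [("A", "B", "chemical", 2),
                               ("A", "B", "gap", 1),
                               ("B", "C", "chemical", 1)])
    g = load_connectome(p)
    assert g.neurons == {"A", "B", "C"}
    assert sorted(g.chemical_edges) == [("A", "B", 2), ("B", "C", 1)]
    assert g.gap_edges == [("A", "B", 1)]


def test_load_sums_duplicate_rows(tmp_path):
    p = write_table(tmp_path, [("A", "B", "chemical", 1), ("A", "B", "chemical", 1)])
    g = load_connectome(p)
    assert g.chemical_edges == [("A", "B", 2)]


def test_load_gap_rows_merge_unordered(tmp_path):
    p = write_table(tmp_path, [("A", "B", "gap", 1), ("B", "A", "gap", 2)])
    g = load_connectome(p)
    assert g.gap_edges == [("A", "B", 3)]


def test_load_empty_table_warns(tmp_path, caplog):
    p = tmp_path / "empty.csv"
    p.write_text("pre,post,kind,contacts\n")
    with caplog.at_level("WARNING"):
        g = load_connectome(p)
    assert g.neurons == set()
    assert any("empty" in r.message for r in caplog.records)


def test_load_tab_delimiter_autodetected(tmp_path):
    p = write_table(tmp_path, [("A", "B", "chemical", 2)], delimiter="\t")
    assert load_connectome(p).chemical_edges == [("A", "B", 2)]


@pytest.mark.parametrize(
    "rows,fragment",
    [
        ([("A", "B", "chemical")], "4 columns"),
        ([("A", "B", "electrical", 1)], "kind"),
        ([("A", "B", "chemical", "x")], "integer"),
        ([("A", "B", "chemical", 0)], "positive"),
    ],
)
def test_load_malformed_rows_name_line(tmp_path, rows, fragment):
    p = write_table(tmp_path, rows)
    with pytest.raises(ConnectomeParseError, match=fragment) as err:
        load_connectome(p)
    assert ":2:" in str(err.value)  # line number after the header


# --------------------------------------------------------------------------
# search


def chain_graph():
    return ConnectomeGraph(
        chemical_edges=[("S", "I", 2), ("I", "M", 2)], gap_edges=[]
    )


def test_find_network_single_chain():
    sub = find_network(
        chain_graph(),
        SearchConstraints(frozenset({"S"}), frozenset({"M"}), depth_limit=2),
    )
    assert sub.neurons == {"S", "I", "M"}
    assert sub.paths == [("S", "I", "M")]


def test_find_network_depth_cutoff():
    sub = find_network(
        chain_graph(),
        SearchConstraints(frozenset({"S"}), frozenset({"M"}), depth_limit=1),
    )
    assert sub.neurons == set() and sub.paths == []


def test_contact_threshold_per_pair():
    g = ConnectomeGraph(chemical_edges=[("S", "I", 1), ("I", "M", 3)], gap_edges=[])
    c2 = SearchConstraints(frozenset({"S"}), frozenset({"M"}), 2, contact_threshold=2)
    c1 = SearchConstraints(frozenset({"S"}), frozenset({"M"}), 2, contact_threshold=1)
    assert find_network(g, c2).paths == []
    assert find_network(g, c1).paths == [("S", "I", "M")]


def test_per_edge_threshold_flag():
    # pair S-I has 1 chemical + 1 gap contact: per-pair total 2 passes a
    # threshold of 2, each individual edge does not.
    g = ConnectomeGraph(
        chemical_edges=[("S", "I", 1), ("I", "M", 2)], gap_edges=[("S", "I", 1)]
    )
    pair = SearchConstraints(frozenset({"S"}), frozenset({"M"}), 2, contact_threshold=2)
    edge = SearchConstraints(
        frozenset({"S"}), frozenset({"M"}), 2, contact_threshold=2, per_edge=True
    )
    assert find_network(g, pair).paths == [("S", "I", "M")]
    assert find_network(g, edge).paths == []


def test_gap_edges_traversed_both_ways():
    g = ConnectomeGraph(chemical_edges=[("I", "M", 2)], gap_edges=[("S", "I", 2)])
    sub = find_network(
        g, SearchConstraints(frozenset({"S"}), frozenset({"M"}), depth_limit=2)
    )
    assert sub.paths == [("S", "I", "M")]


def test_unknown_root_raises_key_error():
    with pytest.raises(KeyError):
        find_network(
            chain_graph(),
            SearchConstraints(frozenset({"X"}), frozenset({"M"}), depth_limit=2),
        )


def test_depth_limit_zero_rejected():
    with pytest.raises(ValueError):
        SearchConstraints(frozenset({"S"}), frozenset({"M"}), depth_limit=0)


def test_is_fully_connected_cases():
    g = ConnectomeGraph(
        chemical_edges=[("S1", "M1", 2), ("S1", "M2", 2), ("S2", "M1", 2),
                        ("S2", "M2", 2)],
        gap_edges=[],
    )
    roots, targets = {"S1", "S2"}, {"M1", "M2"}
    full = find_network(g, SearchConstraints(frozenset(roots), frozenset(targets), 1))
    assert is_fully_connected(full, roots, targets)
    g2 = ConnectomeGraph(chemical_edges=[("S1", "M1", 2), ("S2", "M1", 2),
                                         ("S2", "M2", 2)], gap_edges=[])
    part = find_network(g2, SearchConstraints(frozenset(roots), frozenset(targets), 1))
    assert not is_fully_connected(part, roots, targets)
    empty = find_network(
        chain_graph(), SearchConstraints(frozenset({"S"}), frozenset({"M"}), 1)
    )
    assert not is_fully_connected(empty, {"S"}, {"M"})


def test_minimal_fully_connected_depth():
    # all pairs connect at 3 hops but not 2
    g = ConnectomeGraph(
        chemical_edges=[("S", "A", 2), ("A", "B", 2), ("B", "M", 2)], gap_edges=[]
    )
    assert minimal_fully_connected_depth(g, {"S"}, {"M"}) == 3
    direct = ConnectomeGraph(chemical_edges=[("S", "M", 2)], gap_edges=[])
    assert minimal_fully_connected_depth(direct, {"S"}, {"M"}) == 1
    disconnected = ConnectomeGraph(
        chemical_edges=[("S", "A", 2), ("B", "M", 2)], gap_edges=[]
    )
    assert minimal_fully_connected_depth(disconnected, {"S"}, {"M"}) is None


def test_network_stats_fractions():
    g = ConnectomeGraph(
        chemical_edges=[(f"N{i}", f"N{i+1}", 1) for i in range(9)], gap_edges=[]
    )
    sub = find_network(
        g, SearchConstraints(frozenset({"N0"}), frozenset({"N2"}), depth_limit=2)
    )
    stats = network_stats(sub, g)
    assert stats["n_neurons"] == 3
    assert stats["frac_neurons"] == pytest.approx(0.3)
    empty = find_network(
        g, SearchConstraints(frozenset({"N0"}), frozenset({"N2"}), depth_limit=1)
    )
    s0 = network_stats(empty, g)
    assert s0["n_neurons"] == 0 and s0["frac_chemical"] == 0.0


# --------------------------------------------------------------------------
# oracle equivalence and structural properties


def brute_force_paths(graph, constraints):
    """Independent exhaustive DFS enumeration of simple constrained paths."""
    totals = graph.pair_contacts()

    def allowed(a, b):
        if constraints.per_edge:
            ok_chem = any(
                (p, q) == (a, b) and c >= constraints.contact_threshold
                for p, q, c in graph.chemical_edges
            )
            ok_gap = any(
                {p, q} == {a, b} and c >= constraints.contact_threshold
                for p, q, c in graph.gap_edges
            )
            return ok_chem or ok_gap
        key = (a, b) if a <= b else (b, a)
        return totals.get(key, 0) >= constraints.contact_threshold

    successors = {}
    for n in graph.neurons:
        succ = set()
        for p, q, _ in graph.chemical_edges:
            if p == n and p != q and allowed(p, q):
                succ.add(q)
        for p, q, _ in graph.gap_edges:
            if p == n and allowed(p, q):
                succ.add(q)
            if q == n and allowed(q, p):
                succ.add(p)
        successors[n] = succ

    found = set()

    def dfs(path):
        node = path[-1]
        if len(path) > 1 and node in constraints.target_set:
            found.add(tuple(path))
        if len(path) - 1 >= constraints.depth_limit:
            return
        for nxt in successors[node]:
            if nxt not in path:
                dfs(path + [nxt])

    for root in constraints.root_set:
        dfs([root])
    return found


def random_graph(rng, n_neurons):
    names = [f"N{i}" for i in range(n_neurons)]
    chem, gaps = [], []
    for a in names:
        for b in names:
            if a != b and rng.random() < 0.25:
                chem.append((a, b, int(rng.integers(1, 4))))
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            if rng.random() < 0.1:
                gaps.append((names[i], names[j], int(rng.integers(1, 4))))
    return ConnectomeGraph(neurons=set(names), chemical_edges=chem, gap_edges=gaps)


@pytest.mark.parametrize("trial", range(40))
def test_search_matches_brute_force_enumeration(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(4, 13))
    g = random_graph(rng, n)
    names = sorted(g.neurons)
    roots = frozenset(rng.choice(names, size=2, replace=False))
    targets = frozenset(rng.choice(names, size=2, replace=False))
    constraints = SearchConstraints(
        roots, targets,
        depth_limit=int(rng.integers(1, 5)),
        contact_threshold=int(rng.integers(0, 4)),
        per_edge=bool(rng.random() < 0.3),
    )
    sub = find_network(g, constraints)
    expected = {
        p for p in brute_force_paths(g, constraints) if p[0] != p[-1]
    }
    assert set(sub.paths) == expected


def test_monotonicity_in_depth_and_threshold():
    rng = np.random.default_rng(123)
    g = random_graph(rng, 10)
    roots = frozenset({"N0", "N1"})
    targets = frozenset({"N8", "N9"})
    prev_nodes: set = set()
    for depth in (1, 2, 3, 4):
        sub = find_network(g, SearchConstraints(roots, targets, depth, 1))
        assert prev_nodes <= sub.neurons
        prev_nodes = sub.neurons
    prev_nodes = set()
    for thr in (3, 2, 1, 0):
        sub = find_network(g, SearchConstraints(roots, targets, 3, thr))
        assert prev_nodes <= sub.neurons
        prev_nodes = sub.neurons


def test_gap_traversal_unchanged_by_chemical_reversal():
    rng = np.random.default_rng(5)
    g = random_graph(rng, 8)
    gap_only = ConnectomeGraph(
        neurons=set(g.neurons), chemical_edges=[], gap_edges=list(g.gap_edges)
    )
    reversed_gap_only = ConnectomeGraph(
        neurons=set(g.neurons), chemical_edges=[], gap_edges=list(g.gap_edges)
    )
    roots = frozenset({"N0"})
    targets = frozenset({"N7"})
    c = SearchConstraints(roots, targets, 4, 0)
    assert set(find_network(gap_only, c).paths) == set(
        find_network(reversed_gap_only, c).paths
    )
    # and in a mixed graph, reversing chemical edges preserves pure-gap paths
    rev = ConnectomeGraph(
        neurons=set(g.neurons),
        chemical_edges=[(b, a, c_) for a, b, c_ in g.chemical_edges],
        gap_edges=list(g.gap_edges),
    )
    fwd_paths = find_network(g, c).paths
    rev_paths = find_network(rev, c).paths
    gap_pairs = {frozenset((a, b)) for a, b, _ in g.gap_edges}

    def pure_gap(path):
        return all(frozenset(s) in gap_pairs for s in zip(path, path[1:]))

    assert {p for p in fwd_paths if pure_gap(p)} == {
        p for p in rev_paths if pure_gap(p)
    }


def test_subnetwork_exports(tmp_path):
    sub = find_network(
        chain_graph(),
        SearchConstraints(frozenset({"S"}), frozenset({"M"}), depth_limit=2),
    )
    js = sub.to_json()
    assert '"paths"' in js and "S" in js
    dot = sub.to_dot()
    assert dot.startswith("digraph") and '"S" -> "I"' in dot
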