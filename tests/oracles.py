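"""Independent brute-force oracles used to anchor the implementation.

Everything here is deliberately naive (exhaustive subsets, full
permutation search, pair counting) and shares no code with the package
internals beyond the public graph accessors.
"""

from __future__ import annotations

import itertools

from tnmca.typed_graph import TypedGraph, UNTYPED


def skeleton_adjacency(graph: TypedGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in graph.nodes()}
    for u, v, _ in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def is_connected_subset(graph: TypedGraph, nodes) -> bool:
    nodes = set(nodes)
    adj = skeleton_adjacency(graph)
    start = next(iter(nodes))
    seen, stack = {start}, [start]
    while stack:
        cur = stack.pop()
        for nxt in adj[cur] & nodes:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen == nodes


def brute_connected_ksets(graph: TypedGraph, k: int) -> set[frozenset[str]]:
    """All k-node sets inducing a connected subgraph, by full enumeration."""
    return {
        frozenset(combo)
        for combo in itertools.combinations(sorted(graph.nodes()), k)
        if is_connected_subset(graph, combo)
    }


def brute_valid_tnm(graph: TypedGraph, nodes, min_distinct_types: int = 3) -> bool:
    nodes = set(nodes)
    if len(nodes) < 3 or not is_connected_subset(graph, nodes):
        return False
    if len({graph.node_type(n) for n in nodes}) < min_distinct_types:
        return False
    adj = skeleton_adjacency(graph)
    return all(len(adj[n] & nodes) >= 2 for n in nodes)


def subgraph_parts(graph: TypedGraph, nodes):
    """(types, edges) of the induced subgraph with node-index labels."""
    ids = sorted(nodes)
    index = {n: i for i, n in enumerate(ids)}
    types = tuple(graph.node_type(n) for n in ids)
    edges = [
        (min(index[u], index[v]), max(index[u], index[v]), et)
        for u, v, et in graph.edges()
        if u in index and v in index
    ]
    return types, edges


def brute_canonical_key(types, edges) -> str:
    """Minimal representation over ALL node permutations (not just the
    type-sorted ones the implementation restricts itself to)."""
    k = len(types)
    best = None
    for perm in itertools.permutations(range(k)):
        position = {orig: new for new, orig in enumerate(perm)}
        ptypes = tuple(types[orig] for orig in perm)
        pedges = tuple(
            sorted(
                (min(position[a], position[b]), max(position[a], position[b]), et)
                for a, b, et in edges
            )
        )
        rep = (ptypes, pedges)
        if best is None or rep < best:
            best = rep
    ptypes, pedges = best
    edge_part = ";".join(f"{i}-{j}:{et}" for i, j, et in pedges)
    return f"{k}|{','.join(ptypes)}|{edge_part}"


def brute_isomorphic(types_a, edges_a, types_b, edges_b) -> bool:
    """Type- and edge-type-preserving isomorphism by permutation search."""
    if len(types_a) != len(types_b) or len(edges_a) != len(edges_b):
        return False
    set_b = set(edges_b)
    for perm in itertools.permutations(range(len(types_a))):
        if any(types_a[i] != types_b[perm[i]] for i in range(len(types_a))):
            continue
        mapped = {
            (min(perm[a], perm[b]), max(perm[a], perm[b]), et)
            for a, b, et in edges_a
        }
        if mapped == set_b:
            return True
    return False


def brute_census(graph: TypedGraph, k: int, min_distinct_types: int = 3) -> dict[str, int]:
    """Exhaustive-subset census grouped by permutation-search canonical key."""
    counts: dict[str, int] = {}
    for nodes in brute_connected_ksets(graph, k):
        if not brute_valid_tnm(graph, nodes, min_distinct_types):
            continue
        types, edges = subgraph_parts(graph, nodes)
        key = brute_canonical_key(types, edges)
        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_candidates(
    graph: TypedGraph,
    census_freqs: dict[str, int],
    target: str,
    k: int,
    vocab,
    chemical_type: str = "chemical",
    min_distinct_types: int = 3,
) -> dict[tuple[str, str], set[str]]:
    """Tentative-edge recount: physically add each absent typed edge and
    re-enumerate every valid motif instance through it."""
    out: dict[tuple[str, str], set[str]] = {}
    drugs = [n for n in sorted(graph.nodes()) if graph.node_type(n) == chemical_type]
    for drug in drugs:
        for edge_type in vocab:
            if graph.has_edge(drug, target, edge_type):
                continue
            trial = graph.copy()
            trial.add_edge(drug, target, edge_type)
            referenced: set[str] = set()
            for nodes in brute_connected_ksets(trial, k):
                if drug not in nodes or target not in nodes:
                    continue
                if not brute_valid_tnm(trial, nodes, min_distinct_types):
                    continue
                types, edges = subgraph_parts(trial, nodes)
                key = brute_canonical_key(types, edges)
                if key in census_freqs:
                    referenced.add(key)
            if referenced:
                out[(drug, edge_type)] = referenced
    return out


def brute_pair_auc(labeled) -> float:
    """Mann-Whitney AUC by explicit pair counting (ties count 1/2)."""
    pos = [ls.score for ls in labeled if ls.positive]
    neg = [ls.score for ls in labeled if not ls.positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_typed_graph(
    rng,
    n_nodes: int,
    edge_prob: float = 0.3,
    types=("chemical", "gene", "disease", "pathway"),
    edge_types=("alpha", "beta", UNTYPED),
    parallel_prob: float = 0.15,
) -> TypedGraph:
    """Seeded random typed multigraph for oracle comparisons."""
    g = TypedGraph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for name in names:
        g.add_node(name, types[int(rng.integers(len(types)))])
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            et = edge_types[int(rng.integers(len(edge_types)))]
            g.add_edge(names[i], names[j], et)
            if rng.random() < parallel_prob:
                others = [t for t in edge_types if t != et]
                g.add_edge(names[i], names[j], others[int(rng.integers(len(others)))])
    return g
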