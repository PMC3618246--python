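"""Typed network motif (TNM) extraction and frequency census.

A typed network motif is a connected k-node subgraph pattern that records
node and edge *types* instead of identities.  A k-node induced subgraph
qualifies as a motif instance when

* it is connected (judged on the untyped skeleton),
* every node has distinct-neighbor degree >= 2 within the subgraph
  (one-degree nodes support no inference), and
* it spans at least ``min_distinct_types`` node types (default 3).

Instances are grouped into isomorphism classes by a canonical labeling
that is exact for the small k used here (k <= 5): the representation is
minimized over all node orderings consistent with sorting nodes by type.
The census maps each canonical key to its number of occurrences, counting
node sets (overlapping instances all count, automorphisms do not inflate
the count).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .typed_graph import TypedGraph

MIN_MOTIF_NODES = 3


@dataclass(frozen=True)
class TNMPattern:
    """A canonical typed-motif pattern.

    ``node_types`` is the type label of each pattern node in canonical
    order; ``edges`` holds ``(i, j, edge_type)`` with ``i < j`` indexing
    into ``node_types``.
    """

    node_types: tuple[str, ...]
    edges: frozenset[tuple[int, int, str]]

    @property
    def k(self) -> int:
        return len(self.node_types)

    @property
    def canonical_key(self) -> str:
        edge_part = ";".join(
            f"{i}-{j}:{et}" for i, j, et in sorted(self.edges)
        )
        return f"{self.k}|{','.join(self.node_types)}|{edge_part}"


@dataclass
class TNMCensus:
    """Frequency table of typed-motif patterns at a fixed size k."""

    k: int
    min_distinct_types: int
    frequencies: dict[str, int] = field(default_factory=dict)
    patterns: dict[str, TNMPattern] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.frequencies.values())

    def score(self, key: str) -> float:
        """Relative frequency Freq(TNM_i) / Freq(TNM_total), in (0, 1]."""
        if key not in self.frequencies:
            raise KeyError(f"pattern key not in census: {key!r}")
        return self.frequencies[key] / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "canonical_key": key,
                "k": self.k,
                "frequency": freq,
                "score": freq / self.total,
            }
            for key, freq in self.frequencies.items()
        ]
        frame = pd.DataFrame(
            rows, columns=["canonical_key", "k", "frequency", "score"]
        )
        return frame.sort_values(
            ["frequency", "canonical_key"], ascending=[False, True]
        ).reset_index(drop=True)


def tnm_score(census: TNMCensus, key: str) -> float:
    return census.score(key)


# -- enumeration -------------------------------------------------------


def enumerate_connected_subgraphs(
    graph: TypedGraph, k: int
) -> Iterator[frozenset[str]]:
    """Yield every k-node set inducing a connected subgraph, exactly once.

    ESU-style reverse search: grow from each root node using only
    extension nodes that rank above the root, with the exclusive
    neighborhood rule preventing duplicate discovery.
    """
    if k < MIN_MOTIF_NODES:
        raise ValueError(f"motif size k must be >= {MIN_MOTIF_NODES}, got {k}")
    order = {node: i for i, node in enumerate(sorted(graph.nodes()))}
    adj = {node: graph.neighbors(node) for node in order}

    def extend(sub: set[str], extension: set[str], root_rank: int) -> Iterator[frozenset[str]]:
        if len(sub) == k:
            yield frozenset(sub)
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u
                for u in adj[w]
                if order[u] > root_rank and u not in sub and not (adj[u] & sub)
            }
            sub.add(w)
            yield from extend(sub, new_ext, root_rank)
            sub.remove(w)

    for root in sorted(order, key=order.__getitem__):
        rank = order[root]
        ext = {u for u in adj[root] if order[u] > rank}
        yield from extend({root}, ext, rank)


def is_valid_tnm(
    graph: TypedGraph, node_ids: Iterable[str], min_distinct_types: int = 3
) -> bool:
    """Whether ``node_ids`` induce a typed network motif instance."""
    ids = set(node_ids)
    if len(ids) < MIN_MOTIF_NODES:
        return False
    if len({graph.node_type(n) for n in ids}) < min_distinct_types:
        return False
    for n in ids:
        if len(graph.neighbors(n) & ids) < 2:
            return False
    # min degree 2 on >= 3 nodes implies every node lies on a cycle, but
    # not connectivity of the whole set; check it explicitly.
    seen = {next(iter(ids))}
    stack = list(seen)
    while stack:
        cur = stack.pop()
        for nxt in graph.neighbors(cur) & ids:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen == ids


# -- canonical labeling ------------------------------------------------


def _canonicalize(
    node_types: tuple[str, ...], edges: list[tuple[int, int, str]]
) -> TNMPattern:
    """Exact canonical form by minimizing over type-consistent orderings."""
    k = len(node_types)
    indices = sorted(range(k), key=lambda i: node_types[i])
    sorted_types = tuple(node_types[i] for i in indices)
    # permute only within blocks of equal type: other orderings cannot
    # yield the lexicographically minimal (type-sorted) representation
    blocks: list[list[int]] = []
    start = 0
    for i in range(1, k + 1):
        if i == k or sorted_types[i] != sorted_types[start]:
            blocks.append(indices[start:i])
            start = i
    best: tuple[tuple[int, int, str], ...] | None = None
    for perm_parts in itertools.product(*(itertools.permutations(b) for b in blocks)):
        ordering = [i for part in perm_parts for i in part]
        position = {orig: new for new, orig in enumerate(ordering)}
        relabeled = tuple(
            sorted(
                (min(position[a], position[b]), max(position[a], position[b]), et)
                for a, b, et in edges
            )
        )
        if best is None or relabeled < best:
            best = relabeled
    assert best is not None
    return TNMPattern(node_types=sorted_types, edges=frozenset(best))


def canonical_form(
    graph: TypedGraph, node_ids: Iterable[str], min_distinct_types: int = 3
) -> TNMPattern:
    """Canonical pattern of the induced subgraph on ``node_ids``.

    Raises ``ValueError`` if the node set is not a valid motif instance.
    """
    ids = sorted(set(node_ids))
    if not is_valid_tnm(graph, ids, min_distinct_types):
        raise ValueError(f"node set is not a valid TNM instance: {ids}")
    index = {n: i for i, n in enumerate(ids)}
    types = tuple(graph.node_type(n) for n in ids)
    edges = [
        (min(index[u], index[v]), max(index[u], index[v]), et)
        for u, v, et in graph.induced_subgraph(ids).edges()
    ]
    return _canonicalize(types, edges)


def pattern_from_parts(
    node_types: Iterable[str], edges: Iterable[tuple[int, int, str]]
) -> TNMPattern:
    """Canonical pattern from explicit parts (used by generators and tests)."""
    types = tuple(node_types)
    edge_list = [(min(a, b), max(a, b), et) for a, b, et in edges]
    return _canonicalize(types, edge_list)


# -- census ------------------------------------------------------------


def _triangle_sets(graph: TypedGraph) -> Iterator[frozenset[str]]:
    adj = {n: graph.neighbors(n) for n in graph.nodes()}
    for u, v, _ in set((min(u, v), max(u, v), None) for u, v, _ in graph.edges()):
        for w in adj[u] & adj[v]:
            if w > v:
                yield frozenset((u, v, w))


def _min_degree_two_4sets(graph: TypedGraph) -> Iterator[frozenset[str]]:
    """All 4-node sets with skeleton min degree >= 2 (hence connected).

    Any connected 4-node graph with min degree 2 contains a spanning
    4-cycle, so enumerating 4-cycles by their diagonals (pairs of nodes
    with >= 2 common neighbors) finds every such set.
    """
    adj = {n: graph.neighbors(n) for n in graph.nodes()}
    common: dict[tuple[str, str], list[str]] = {}
    for v, nbrs in adj.items():
        snbrs = sorted(nbrs)
        for i, u in enumerate(snbrs):
            for w in snbrs[i + 1:]:
                common.setdefault((u, w), []).append(v)
    seen: set[frozenset[str]] = set()
    for (u, w), through in common.items():
        if len(through) < 2:
            continue
        for x, y in itertools.combinations(through, 2):
            s = frozenset((u, w, x, y))
            if len(s) == 4 and s not in seen:
                seen.add(s)
                yield s


def iter_motif_instances(
    graph: TypedGraph, k: int, min_distinct_types: int = 3
) -> Iterator[frozenset[str]]:
    """Yield every valid k-node motif instance (node set) exactly once.

    For k in {3, 4} a degree-aware enumerator is used (triangles and
    4-cycle closures); larger k falls back to full connected-subgraph
    enumeration plus filtering.
    """
    if k == 3:
        candidates: Iterator[frozenset[str]] = _triangle_sets(graph)
    elif k == 4:
        candidates = _min_degree_two_4sets(graph)
    else:
        candidates = enumerate_connected_subgraphs(graph, k)
    for node_set in candidates:
        if is_valid_tnm(graph, node_set, min_distinct_types):
            yield node_set


def build_census(
    graph: TypedGraph, k: int, min_distinct_types: int = 3
) -> TNMCensus:
    """Count every valid k-node motif instance, grouped by canonical key."""
    if k < MIN_MOTIF_NODES:
        raise ValueError(f"motif size k must be >= {MIN_MOTIF_NODES}, got {k}")
    census = TNMCensus(k=k, min_distinct_types=min_distinct_types)
    for node_set in iter_motif_instances(graph, k, min_distinct_types):
        pattern = canonical_form(graph, node_set, min_distinct_types)
        key = pattern.canonical_key
        if key not in census.frequencies:
            census.frequencies[key] = 0
            census.patterns[key] = pattern
        census.frequencies[key] += 1
    return census
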