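"""Typed undirected multigraphs of biomedical entities.

The backbone network for indication inference is an undirected multigraph
whose nodes carry an entity type (``chemical``, ``gene``, ``disease``,
``pathway`` in the CTD-style setting) and whose edges carry an optional
interaction type.  Two nodes may be joined by several edges as long as the
edge types differ (e.g. a chemical that is both a ``marker`` and a
``therapeutic`` agent for the same disease); an exact duplicate of an
existing (pair, type) edge is rejected.

Edges without an interaction type carry the :data:`UNTYPED` sentinel, which
behaves as an ordinary edge-type label during pattern matching.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

#: Sentinel edge-type label for edges with no declared interaction type.
#: The empty string is what a blank TSV field parses to, and it round-trips.
UNTYPED = ""

NODES_HEADER = ("node_id", "node_type")
EDGES_HEADER = ("source_id", "target_id", "edge_type")


class GraphIntegrityError(ValueError):
    """A node or edge record violates the graph invariants."""


class TypedGraph:
    """Undirected multigraph with typed nodes and optionally typed edges.

    Thin wrapper around :class:`networkx.MultiGraph`; the multigraph edge
    key is the edge type, which enforces at most one edge per
    (endpoint pair, edge type) combination.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, node_type: str) -> None:
        if not node_id:
            raise GraphIntegrityError("node id must be non-empty")
        if not node_type:
            raise GraphIntegrityError(f"node {node_id!r}: type must be non-empty")
        if node_id in self._g:
            raise GraphIntegrityError(f"duplicate node id {node_id!r}")
        self._g.add_node(node_id, node_type=node_type)

    def add_edge(self, u: str, v: str, edge_type: str = UNTYPED) -> None:
        if u == v:
            raise GraphIntegrityError(f"self-loop on {u!r} rejected")
        for endpoint in (u, v):
            if endpoint not in self._g:
                raise GraphIntegrityError(f"edge references undeclared node {endpoint!r}")
        if self._g.has_edge(u, v, key=edge_type):
            raise GraphIntegrityError(
                f"duplicate edge ({u!r}, {v!r}, type={edge_type!r})"
            )
        self._g.add_edge(u, v, key=edge_type)

    def remove_edge(self, u: str, v: str, edge_type: str = UNTYPED) -> None:
        if not self._g.has_edge(u, v, key=edge_type):
            raise KeyError(f"no edge ({u!r}, {v!r}, type={edge_type!r})")
        self._g.remove_edge(u, v, key=edge_type)

    def remove_node(self, node_id: str) -> None:
        if node_id not in self._g:
            raise KeyError(f"unknown node {node_id!r}")
        self._g.remove_node(node_id)

    # -- queries ------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def node_type(self, node_id: str) -> str:
        try:
            return self._g.nodes[node_id]["node_type"]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self._g.nodes(data="node_type") if t == node_type)

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield ``(u, v, edge_type)`` triples (one per multigraph edge)."""
        for u, v, key in self._g.edges(keys=True):
            yield u, v, key

    def has_edge(self, u: str, v: str, edge_type: str | None = None) -> bool:
        if edge_type is None:
            return self._g.has_edge(u, v)
        return self._g.has_edge(u, v, key=edge_type)

    def edge_types_between(self, u: str, v: str) -> set[str]:
        if not self._g.has_edge(u, v):
            return set()
        return set(self._g[u][v])

    def neighbors(self, node_id: str) -> set[str]:
        """Distinct neighbor nodes (parallel typed edges collapse)."""
        return set(self._g[node_id])

    def degree(self, node_id: str) -> int:
        """Distinct-neighbor degree (skeleton degree)."""
        return len(self._g[node_id])

    def node_items(self) -> list[tuple[str, str]]:
        return sorted((n, t) for n, t in self._g.nodes(data="node_type"))

    def edge_items(self) -> list[tuple[str, str, str]]:
        """Sorted ``(min_id, max_id, edge_type)`` triples."""
        return sorted(
            (min(u, v), max(u, v), key) for u, v, key in self._g.edges(keys=True)
        )

    # -- derived graphs ------------------------------------------------

    def copy(self) -> "TypedGraph":
        out = TypedGraph()
        out._g = self._g.copy()
        return out

    def induced_subgraph(self, node_ids: Iterable[str]) -> "TypedGraph":
        """Subgraph on ``node_ids`` with every parent edge among them."""
        ids = set(node_ids)
        for node_id in ids:
            if node_id not in self._g:
                raise KeyError(f"unknown node {node_id!r}")
        out = TypedGraph()
        out._g = nx.MultiGraph(self._g.subgraph(ids))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return (
            self.node_items() == other.node_items()
            and self.edge_items() == other.edge_items()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TypedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def induced_subgraph(graph: TypedGraph, node_ids: Iterable[str]) -> TypedGraph:
    return graph.induced_subgraph(node_ids)


# -- TSV I/O -----------------------------------------------------------


def _data_rows(path: Path, expected_header: tuple[str, ...]) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        header = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = tuple(fields)
                if header != expected_header:
                    raise GraphIntegrityError(
                        f"{path}: expected header {expected_header}, got {header}"
                    )
                continue
            yield lineno, fields


def read_graph(nodes_path: str | Path, edges_path: str | Path) -> TypedGraph:
    """Read a typed graph from node and edge TSV files.

    The node file has columns ``node_id`` / ``node_type``; the edge file has
    ``source_id`` / ``target_id`` / ``edge_type`` where a blank edge type
    maps to :data:`UNTYPED`.  ``#``-prefixed lines are comments.
    """
    nodes_path, edges_path = Path(nodes_path), Path(edges_path)
    for path in (nodes_path, edges_path):
        if not path.exists():
            raise FileNotFoundError(path)
    graph = TypedGraph()
    for lineno, fields in _data_rows(nodes_path, NODES_HEADER):
        if len(fields) != 2:
            raise GraphIntegrityError(f"{nodes_path}:{lineno}: expected 2 fields")
        try:
            graph.add_node(fields[0], fields[1])
        except GraphIntegrityError as exc:
            raise GraphIntegrityError(f"{nodes_path}:{lineno}: {exc}") from None
    for lineno, fields in _data_rows(edges_path, EDGES_HEADER):
        if len(fields) == 2:  # trailing blank edge_type may be stripped
            fields = fields + [UNTYPED]
        if len(fields) != 3:
            raise GraphIntegrityError(f"{edges_path}:{lineno}: expected 3 fields")
        try:
            graph.add_edge(fields[0], fields[1], fields[2])
        except GraphIntegrityError as exc:
            raise GraphIntegrityError(f"{edges_path}:{lineno}: {exc}") from None
    return graph


def write_graph(graph: TypedGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write TSVs with deterministic row order (repeat writes are byte-identical)."""
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(NODES_HEADER) + "\n")
        for node_id, node_type in graph.node_items():
            handle.write(f"{node_id}\t{node_type}\n")
    with open(edges_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(EDGES_HEADER) + "\n")
        for u, v, edge_type in graph.edge_items():
            handle.write(f"{u}\t{v}\t{edge_type}\n")


def graph_to_tsv_bytes(graph: TypedGraph) -> bytes:
    """Canonical serialized form of a graph (used for determinism checks)."""
    buf = io.StringIO()
    buf.write("\t".join(NODES_HEADER) + "\n")
    for node_id, node_type in graph.node_items():
        buf.write(f"{node_id}\t{node_type}\n")
    buf.write("\t".join(EDGES_HEADER) + "\n")
    for u, v, edge_type in graph.edge_items():
        buf.write(f"{u}\t{v}\t{edge_type}\n")
    return buf.getvalue().encode("utf-8")
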