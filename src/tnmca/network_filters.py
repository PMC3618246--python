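"""Training-network construction: whitelist, hierarchy and hold-out filters.

Three preparation steps turn a raw interaction dump into a training
network for indication inference:

1. ``filter_chemicals`` keeps only chemicals on a drug whitelist
   (non-drug chemicals carry no repositioning signal).
2. ``filter_diseases_by_hierarchy`` restricts diseases to those sharing
   a hierarchy branch (MeSH-style dot-separated tree numbers) with the
   target disease, so motif frequencies are learned from related
   diseases only.
3. ``holdout_answer_set`` removes every chemical-target edge into an
   answer set of known indications, which the inference stage must then
   rediscover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .typed_graph import TypedGraph


@dataclass(frozen=True)
class AnswerSet:
    """Held-out typed chemical-disease edges for one target disease."""

    target_disease_id: str
    edges: frozenset[tuple[str, str, str]]  # (drug_id, disease_id, edge_type)

    def __len__(self) -> int:
        return len(self.edges)

    def drugs(self) -> set[str]:
        return {d for d, _, _ in self.edges}

    def sorted_edges(self) -> list[tuple[str, str, str]]:
        return sorted(self.edges)


def filter_chemicals(
    graph: TypedGraph, whitelist: set[str], chemical_type: str = "chemical"
) -> TypedGraph:
    """Drop chemical nodes not on the whitelist, with their edges."""
    if not whitelist:
        raise ValueError("empty chemical whitelist would delete every chemical")
    out = graph.copy()
    for node in graph.nodes_of_type(chemical_type):
        if node not in whitelist:
            out.remove_node(node)
    return out


def _shares_prefix(trees_a: set[str], trees_b: set[str], depth: int) -> bool:
    """Any-match, segment-wise prefix agreement at the given depth."""
    if depth <= 0:
        return True
    prefixes_b = {tuple(t.split(".")[:depth]) for t in trees_b}
    return any(tuple(t.split(".")[:depth]) in prefixes_b for t in trees_a)


def filter_diseases_by_hierarchy(
    graph: TypedGraph,
    tree_map: dict[str, set[str]],
    target: str,
    depth: int = 1,
    unknown_disease_policy: str = "drop",
    disease_type: str = "disease",
) -> TypedGraph:
    """Keep diseases sharing a >= depth-segment tree-number prefix with the target.

    ``depth=0`` keeps everything (the empty prefix matches).  Diseases
    absent from ``tree_map`` are dropped by default (``"drop"``) or kept
    with ``unknown_disease_policy="keep"``.
    """
    if target not in tree_map:
        raise ValueError(f"target disease {target!r} missing from tree map")
    if unknown_disease_policy not in ("drop", "keep"):
        raise ValueError(f"unknown_disease_policy must be 'drop' or 'keep'")
    target_trees = set(tree_map[target])
    out = graph.copy()
    for node in graph.nodes_of_type(disease_type):
        if node == target:
            continue
        trees = tree_map.get(node)
        if trees is None:
            if unknown_disease_policy == "drop":
                out.remove_node(node)
            continue
        if not _shares_prefix(set(trees), target_trees, depth):
            out.remove_node(node)
    return out


def holdout_answer_set(
    graph: TypedGraph, target: str, chemical_type: str = "chemical"
) -> tuple[TypedGraph, AnswerSet]:
    """Move every chemical-target edge (any type) into an answer set."""
    if target not in graph:
        raise ValueError(f"target disease {target!r} not in graph")
    out = graph.copy()
    held: set[tuple[str, str, str]] = set()
    for nbr in graph.neighbors(target):
        if graph.node_type(nbr) != chemical_type:
            continue
        for edge_type in graph.edge_types_between(nbr, target):
            out.remove_edge(nbr, target, edge_type)
            held.add((nbr, target, edge_type))
    return out, AnswerSet(target_disease_id=target, edges=frozenset(held))


def restore_answers(graph: TypedGraph, answers: AnswerSet) -> TypedGraph:
    """Reinsert held-out edges; inverse of :func:`holdout_answer_set`."""
    out = graph.copy()
    for drug, disease, edge_type in answers.sorted_edges():
        out.add_edge(drug, disease, edge_type)
    return out


# -- file loaders ------------------------------------------------------


def read_whitelist(path: str | Path) -> set[str]:
    """One chemical id per line; ``#`` comments and blank lines ignored."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_answer_set(path: str | Path, target: str) -> AnswerSet:
    """TSV ``drug_id<TAB>disease_id<TAB>edge_type`` of held-out edges."""
    edges: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("drug_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                fields.append("")
            if len(fields) != 3:
                raise ValueError(f"{path}: malformed answer row {line!r}")
            if fields[1] != target:
                raise ValueError(
                    f"{path}: answer edge references disease {fields[1]!r}, "
                    f"expected target {target!r}"
                )
            edges.add((fields[0], fields[1], fields[2]))
    return AnswerSet(target_disease_id=target, edges=frozenset(edges))


def read_tree_map(path: str | Path) -> dict[str, set[str]]:
    """TSV ``disease_id<TAB>tree_number``, one row per tree number."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        header_skipped = False
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_skipped and fields[:2] == ["disease_id", "tree_number"]:
                header_skipped = True
                continue
            if len(fields) != 2 or not fields[1]:
                raise ValueError(f"{path}: malformed tree-map row {line!r}")
            out.setdefault(fields[0], set()).add(fields[1])
    return out
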