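"""Drug-indication inference by single-edge motif completion.

For a target disease ``s`` and every drug ``d`` and candidate interaction
type ``t`` such that the typed edge ``(d, s, t)`` is absent from the
training graph, the tentative edge is added and every valid k-node motif
instance containing it is canonicalized.  Each instance whose canonical
key occurs in the training census contributes that pattern to the
candidate's ``referenced`` set: the observed subgraph matches the pattern
in everything but the one missing relation, so the relation (and its
type) is proposed as new knowledge.

Candidates are scored by noisy-OR aggregation over the relative
frequencies of their distinct referenced patterns::

    Score_Ind = 1 - prod_i (1 - Score_TNM_i)

so that a candidate always scores at least as high as each supporting
pattern, and independent lines of evidence accumulate.  Ties are broken
by the summed raw frequency of the referenced patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motif_census import TNMCensus, _canonicalize
from .typed_graph import UNTYPED, TypedGraph


@dataclass
class InferenceConfig:
    """Settings for candidate generation.

    ``edge_type_vocabulary=None`` means: propose the interaction types
    observed on chemical-disease edges of the training graph, plus
    :data:`UNTYPED`.
    """

    k: int
    target_disease_id: str
    score_threshold: float = 0.0
    edge_type_vocabulary: tuple[str, ...] | None = None
    chemical_type: str = "chemical"
    disease_type: str = "disease"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")


@dataclass
class CandidateIndication:
    drug_id: str
    disease_id: str
    edge_type: str
    referenced: frozenset[str]
    score: float = 0.0
    tiebreak: int = 0


def score_indication(referenced_scores) -> float:
    """Noisy-OR aggregate ``1 - prod(1 - s_i)`` over pattern scores."""
    product = 1.0
    for s in referenced_scores:
        if not 0.0 < s <= 1.0:
            raise ValueError(f"pattern score must lie in (0, 1], got {s}")
        product *= 1.0 - s
    return 1.0 - product


def observed_edge_type_vocabulary(
    graph: TypedGraph, chemical_type: str = "chemical", disease_type: str = "disease"
) -> tuple[str, ...]:
    """Interaction types seen on chemical-disease edges, plus UNTYPED."""
    vocab = {UNTYPED}
    for u, v, et in graph.edges():
        types = {graph.node_type(u), graph.node_type(v)}
        if types == {chemical_type, disease_type}:
            vocab.add(et)
    return tuple(sorted(vocab))


def _completion_node_sets(
    graph: TypedGraph, drug: str, target: str, k: int
) -> list[frozenset[str]]:
    """Valid k-node sets containing drug and target once the tentative
    edge drug-target is present (skeleton min degree >= 2, connected)."""
    adj = {n: graph.neighbors(n) for n in graph.nodes()}
    adj[drug] = adj[drug] | {target}
    adj[target] = adj[target] | {drug}
    found: set[frozenset[str]] = set()
    if k == 3:
        for x in (adj[drug] & adj[target]) - {drug, target}:
            found.add(frozenset((drug, target, x)))
    elif k == 4:
        # drug needs a neighbor besides target inside the set, so at
        # least one extra node lies in N(drug); the other extra node
        # needs two neighbors among the remaining three.
        for x in adj[drug] - {target}:
            pool = (
                (adj[drug] & adj[target])
                | (adj[drug] & adj[x])
                | (adj[target] & adj[x])
            ) - {drug, target, x}
            for y in pool:
                s = frozenset((drug, target, x, y))
                if len(s) == 4 and s not in found:
                    if all(len(adj[n] & s) >= 2 for n in s):
                        found.add(s)
    else:
        # generic fallback: grow connected sets around the pair
        frontier: set[frozenset[str]] = {frozenset((drug, target))}
        for _ in range(k - 2):
            nxt: set[frozenset[str]] = set()
            for s in frontier:
                reachable = set().union(*(adj[n] for n in s)) - s
                for n in reachable:
                    nxt.add(s | {n})
            frontier = nxt
        for s in frontier:
            if all(len(adj[n] & s) >= 2 for n in s):
                found.add(s)
    return sorted(found, key=sorted)


def _tentative_pattern_key(
    graph: TypedGraph,
    node_set: frozenset[str],
    drug: str,
    target: str,
    edge_type: str,
    cache: dict,
) -> str:
    ids = sorted(node_set)
    index = {n: i for i, n in enumerate(ids)}
    types = tuple(graph.node_type(n) for n in ids)
    edges = [
        (min(index[u], index[v]), max(index[u], index[v]), et)
        for u, v, et in graph.induced_subgraph(ids).edges()
    ]
    a, b = index[drug], index[target]
    edges.append((min(a, b), max(a, b), edge_type))
    rep = (types, tuple(sorted(edges)))
    if rep not in cache:
        cache[rep] = _canonicalize(types, edges).canonical_key
    return cache[rep]


def find_candidates(
    graph: TypedGraph, census: TNMCensus, config: InferenceConfig
) -> list[CandidateIndication]:
    """Propose typed drug-target edges supported by census patterns.

    Only edges absent from the training graph are proposed; a candidate
    is emitted only if at least one completed motif instance matches a
    census pattern.
    """
    target = config.target_disease_id
    if target not in graph:
        raise ValueError(f"target disease {target!r} not in graph")
    if graph.node_type(target) != config.disease_type:
        raise ValueError(f"target node {target!r} is not of type {config.disease_type!r}")
    vocab = config.edge_type_vocabulary
    if vocab is None:
        vocab = observed_edge_type_vocabulary(
            graph, config.chemical_type, config.disease_type
        )
    key_cache: dict = {}
    candidates: list[CandidateIndication] = []
    for drug in graph.nodes_of_type(config.chemical_type):
        node_sets = None  # computed lazily, shared across edge types
        for edge_type in vocab:
            if graph.has_edge(drug, target, edge_type):
                continue  # only new knowledge is inferred
            if node_sets is None:
                node_sets = _completion_node_sets(graph, drug, target, config.k)
            referenced: set[str] = set()
            for node_set in node_sets:
                key = _tentative_pattern_key(
                    graph, node_set, drug, target, edge_type, key_cache
                )
                if key in census.frequencies:
                    referenced.add(key)
            if referenced:
                candidates.append(
                    CandidateIndication(
                        drug_id=drug,
                        disease_id=target,
                        edge_type=edge_type,
                        referenced=frozenset(referenced),
                    )
                )
    for cand in candidates:
        cand.score = score_indication(census.score(key) for key in cand.referenced)
        cand.tiebreak = sum(census.frequencies[key] for key in cand.referenced)
    return candidates


def rank_candidates(candidates) -> list[CandidateIndication]:
    """Descending by score, then summed referenced frequency, then id."""
    return sorted(
        candidates,
        key=lambda c: (-c.score, -c.tiebreak, c.drug_id, c.edge_type),
    )


def apply_threshold(ranked, threshold: float) -> list[CandidateIndication]:
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [c for c in ranked if c.score >= threshold]


def candidates_to_frame(ranked) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "drug_id": c.drug_id,
            "disease_id": c.disease_id,
            "edge_type": c.edge_type,
            "score": c.score,
            "tiebreak": c.tiebreak,
            "referenced_keys": ";".join(sorted(c.referenced)),
        }
        for i, c in enumerate(ranked)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "drug_id",
            "disease_id",
            "edge_type",
            "score",
            "tiebreak",
            "referenced_keys",
        ],
    )
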