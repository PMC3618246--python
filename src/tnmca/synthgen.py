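"""Synthetic CTD-like benchmark networks with planted motifs and hold-outs.

The generator emulates the structure of a curated chemical-gene-disease-
pathway interaction network: four node types; interaction types only on
chemical-gene, chemical-disease and gene-disease edges (two-label
vocabularies, echoing e.g. ``marker`` vs ``therapeutic`` disease
associations); untyped edges elsewhere.

A cohort of "indication drugs" is planted around a designated target
disease: each cohort drug participates in motif instances of every
template (by default a chemical-gene-disease triangle and a Fig-6-style
chemical-pathway-gene-disease cycle without a drug-gene edge), reflecting
that a genuine indication is usually supported through both gene- and
pathway-mediated mechanisms.  A fraction of the resulting chemical-target
edges is then moved into the answer set; the remaining intact instances
supply the motif frequencies from which the held-out edges must be
re-inferred.  Sparse uniform noise edges are added per type pair.

Everything is driven by one integer seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network_filters import AnswerSet
from .typed_graph import UNTYPED, TypedGraph, write_graph

CHEMICAL, GENE, DISEASE, PATHWAY = "chemical", "gene", "disease", "pathway"

#: Interaction-type vocabulary per (sorted) node-type pair; pairs absent
#: here only ever carry untyped edges.
DEFAULT_EDGE_TYPE_VOCAB: dict[tuple[str, str], tuple[str, ...]] = {
    ("chemical", "gene"): ("increases", "decreases"),
    ("chemical", "disease"): ("therapeutic", "marker"),
    ("disease", "gene"): ("marker", "therapeutic"),
}

#: Background noise-edge probability per node pair, per type pair.
DEFAULT_NOISE_RATES: dict[tuple[str, str], float] = {
    ("chemical", "gene"): 0.003,
    ("chemical", "disease"): 0.004,
    ("disease", "gene"): 0.003,
    ("chemical", "pathway"): 0.004,
    ("gene", "pathway"): 0.002,
    ("disease", "pathway"): 0.010,
}


@dataclass(frozen=True)
class MotifTemplate:
    """A typed pattern to plant; node index 0 is the cohort drug slot and
    the first disease-typed node is the target-disease slot."""

    name: str
    node_types: tuple[str, ...]
    edges: tuple[tuple[int, int, str], ...]

    @property
    def drug_index(self) -> int:
        return self.node_types.index(CHEMICAL)

    @property
    def target_index(self) -> int:
        return self.node_types.index(DISEASE)


#: Triangle: drug-gene, gene-disease, drug-disease (all typed).
TRIANGLE_TEMPLATE = MotifTemplate(
    name="cgd_triangle",
    node_types=(CHEMICAL, GENE, DISEASE),
    edges=((0, 1, "increases"), (1, 2, "marker"), (0, 2, "therapeutic")),
)

#: 4-cycle with no drug-gene edge: the drug reaches the disease-linked
#: gene through a pathway (shape of the most frequent real-data motif).
PATHWAY_CYCLE_TEMPLATE = MotifTemplate(
    name="cpgd_cycle",
    node_types=(CHEMICAL, PATHWAY, GENE, DISEASE),
    edges=(
        (0, 1, UNTYPED),
        (1, 2, UNTYPED),
        (2, 3, "marker"),
        (0, 3, "therapeutic"),
    ),
)


@dataclass
class GeneratorConfig:
    n_chemicals: int = 200
    n_genes: int = 300
    n_diseases: int = 40
    n_pathways: int = 50
    templates: tuple[tuple[MotifTemplate, int], ...] = (
        (TRIANGLE_TEMPLATE, 100),
        (PATHWAY_CYCLE_TEMPLATE, 100),
    )
    indication_cohort_size: int = 100
    holdout_fraction: float = 0.2
    noise_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_RATES)
    )
    edge_type_vocab: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_TYPE_VOCAB)
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chemicals", "n_genes", "n_diseases", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.holdout_fraction <= 1.0:
            raise ValueError("holdout_fraction must lie in [0, 1]")
        if self.indication_cohort_size > self.n_chemicals:
            raise ValueError("indication cohort larger than chemical pool")
        for template, count in self.templates:
            if count < 0:
                raise ValueError(f"negative instance count for {template.name}")
            if count > 0 and self.indication_cohort_size <= 0:
                raise ValueError("planting requires a non-empty drug cohort")


def _node_pools(config: GeneratorConfig) -> dict[str, list[str]]:
    return {
        CHEMICAL: [f"C{i:04d}" for i in range(1, config.n_chemicals + 1)],
        GENE: [f"G{i:04d}" for i in range(1, config.n_genes + 1)],
        DISEASE: [f"D{i:04d}" for i in range(1, config.n_diseases + 1)],
        PATHWAY: [f"P{i:04d}" for i in range(1, config.n_pathways + 1)],
    }


def generate_network(
    config: GeneratorConfig,
) -> tuple[TypedGraph, AnswerSet, dict]:
    """Build (training graph, answer set, manifest) from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pools = _node_pools(config)
    target = pools[DISEASE][0]

    graph = TypedGraph()
    for node_type in (CHEMICAL, GENE, DISEASE, PATHWAY):
        for node_id in pools[node_type]:
            graph.add_node(node_id, node_type)

    def add_edge_once(u: str, v: str, edge_type: str) -> bool:
        if graph.has_edge(u, v, edge_type):
            return False
        graph.add_edge(u, v, edge_type)
        return True

    # indication-drug cohort shared by all templates
    cohort = sorted(
        rng.choice(pools[CHEMICAL], size=config.indication_cohort_size, replace=False)
    )

    planted_instances: list[dict] = []
    for template, count in config.templates:
        for i in range(count):
            assignment: list[str] = []
            for idx, node_type in enumerate(template.node_types):
                if idx == template.drug_index:
                    assignment.append(cohort[i % len(cohort)])
                elif idx == template.target_index:
                    assignment.append(target)
                else:
                    pool = pools[node_type]
                    if node_type == DISEASE:
                        pool = pool[1:]  # extra disease slots avoid the target
                    assignment.append(pool[int(rng.integers(len(pool)))])
            if len(set(assignment)) < len(assignment):
                continue  # degenerate draw (same node twice); skip
            edges = []
            for a, b, et in template.edges:
                u, v = assignment[a], assignment[b]
                add_edge_once(u, v, et)
                edges.append((min(u, v), max(u, v), et))
            planted_instances.append(
                {"template": template.name, "nodes": assignment, "edges": edges}
            )

    # background noise, never duplicating an existing (pair, type) edge
    noise_edges: list[tuple[str, str, str]] = []
    for pair in sorted(config.noise_rates):
        rate = config.noise_rates[pair]
        type_a, type_b = pair
        pool_a, pool_b = pools[type_a], pools[type_b]
        n_pairs = len(pool_a) * len(pool_b)
        m = int(rng.binomial(n_pairs, rate))
        if m == 0:
            continue
        flat = rng.choice(n_pairs, size=m, replace=False)
        vocab = config.edge_type_vocab.get(pair, (UNTYPED,))
        for index in sorted(int(x) for x in flat):
            u = pool_a[index // len(pool_b)]
            v = pool_b[index % len(pool_b)]
            edge_type = vocab[int(rng.integers(len(vocab)))]
            if add_edge_once(u, v, edge_type):
                noise_edges.append((min(u, v), max(u, v), edge_type))

    # hold out a fraction of chemical-target edges as the answer set
    pool = sorted(
        (nbr, target, et)
        for nbr in graph.neighbors(target)
        if graph.node_type(nbr) == CHEMICAL
        for et in graph.edge_types_between(nbr, target)
    )
    n_hold = int(round(config.holdout_fraction * len(pool)))
    held_idx = sorted(
        int(i) for i in rng.choice(len(pool), size=n_hold, replace=False)
    ) if n_hold else []
    held = [pool[i] for i in held_idx]
    for drug, disease, edge_type in held:
        graph.remove_edge(drug, disease, edge_type)
    answers = AnswerSet(target_disease_id=target, edges=frozenset(held))

    manifest = {
        "seed": config.seed,
        "target_disease_id": target,
        "indication_cohort": list(cohort),
        "planted_instances": planted_instances,
        "held_out_edges": [list(e) for e in sorted(held)],
        "n_noise_edges": len(noise_edges),
    }
    return graph, answers, manifest


# -- canonical small fixtures -----------------------------------------


def triangle_fixture() -> TypedGraph:
    """One drug-gene-disease triangle, all edges typed."""
    g = TypedGraph()
    g.add_node("drug1", CHEMICAL)
    g.add_node("gene1", GENE)
    g.add_node("disease1", DISEASE)
    g.add_edge("drug1", "gene1", "increases")
    g.add_edge("gene1", "disease1", "marker")
    g.add_edge("drug1", "disease1", "therapeutic")
    return g


def four_cycle_fixture() -> TypedGraph:
    """Drug-pathway-gene-disease 4-cycle (no drug-gene edge)."""
    g = TypedGraph()
    g.add_node("drug1", CHEMICAL)
    g.add_node("pathway1", PATHWAY)
    g.add_node("gene1", GENE)
    g.add_node("disease1", DISEASE)
    g.add_edge("drug1", "pathway1", UNTYPED)
    g.add_edge("pathway1", "gene1", UNTYPED)
    g.add_edge("gene1", "disease1", "marker")
    g.add_edge("drug1", "disease1", "therapeutic")
    return g


def near_match_fixture() -> TypedGraph:
    """A complete triangle instance plus a second drug one edge short.

    drug1-gene1-target forms a full typed triangle (establishing the
    pattern); drug2-gene2 and gene2-target carry matching types but the
    drug2-target edge is missing, so inference should propose it.
    """
    g = TypedGraph()
    g.add_node("drug1", CHEMICAL)
    g.add_node("drug2", CHEMICAL)
    g.add_node("gene1", GENE)
    g.add_node("gene2", GENE)
    g.add_node("target", DISEASE)
    g.add_edge("drug1", "gene1", "increases")
    g.add_edge("gene1", "target", "marker")
    g.add_edge("drug1", "target", "therapeutic")
    g.add_edge("drug2", "gene2", "increases")
    g.add_edge("gene2", "target", "marker")
    return g


def abc_fixture() -> TypedGraph:
    """Drug linked to the target through genes g1, g2 and pathway p1
    (ABC score 3), plus a second drug with no shared intermediate."""
    g = TypedGraph()
    g.add_node("drugA", CHEMICAL)
    g.add_node("drugB", CHEMICAL)
    g.add_node("g1", GENE)
    g.add_node("g2", GENE)
    g.add_node("g3", GENE)
    g.add_node("p1", PATHWAY)
    g.add_node("target", DISEASE)
    for mediator in ("g1", "g2", "p1"):
        g.add_edge("drugA", mediator, UNTYPED)
        g.add_edge(mediator, "target", UNTYPED)
    g.add_edge("drugB", "g3", UNTYPED)  # g3 not linked to target
    return g


def make_fixture_suite(out_dir: str | Path) -> list[Path]:
    """Write the canonical small fixtures as TSV pairs; deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, builder in (
        ("triangle", triangle_fixture),
        ("four_cycle", four_cycle_fixture),
        ("near_match", near_match_fixture),
        ("abc", abc_fixture),
    ):
        nodes_path = out_dir / f"{name}.nodes.tsv"
        edges_path = out_dir / f"{name}.edges.tsv"
        write_graph(builder(), nodes_path, edges_path)
        written.extend([nodes_path, edges_path])
    return written


def write_benchmark(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[TypedGraph, AnswerSet, dict]:
    """Generate and write nodes/edges TSVs, answers.tsv and manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph, answers, manifest = generate_network(config)
    write_graph(graph, out_dir / "nodes.tsv", out_dir / "edges.tsv")
    with open(out_dir / "answers.tsv", "w", encoding="utf-8", newline="\n") as handle:
        handle.write("drug_id\tdisease_id\tedge_type\n")
        for drug, disease, edge_type in answers.sorted_edges():
            handle.write(f"{drug}\t{disease}\t{edge_type}\n")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return graph, answers, manifest
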