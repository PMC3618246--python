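"""End-to-end pipeline helpers: census -> inference -> evaluation.

These glue functions run the full indication-inference experiment on a
prepared training graph (motif census at size k, single-edge completion
around the target disease, ROC/AUC against the answer set) and the
synthetic-benchmark loop used for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import evaluation as ev
from .inference_engine import (
    InferenceConfig,
    apply_threshold,
    find_candidates,
    rank_candidates,
)
from .motif_census import TNMCensus, build_census
from .network_filters import AnswerSet
from .synthgen import GeneratorConfig, generate_network
from .typed_graph import TypedGraph


@dataclass
class RunResult:
    model: str
    k: int | None
    auc: float
    positives: int
    universe_size: int


def infer_indications(
    graph: TypedGraph,
    target: str,
    k: int,
    score_threshold: float = 0.0,
    min_distinct_types: int = 3,
    census: TNMCensus | None = None,
):
    """Census + completion + ranking for one target disease; returns the
    ranked candidate list (and builds the census if not supplied)."""
    if census is None:
        census = build_census(graph, k, min_distinct_types)
    config = InferenceConfig(k=k, target_disease_id=target, score_threshold=score_threshold)
    ranked = rank_candidates(find_candidates(graph, census, config))
    return apply_threshold(ranked, score_threshold), census


def evaluate_tnmca(
    graph: TypedGraph, answers: AnswerSet, k: int, min_distinct_types: int = 3
) -> RunResult:
    """Typed-matching evaluation of motif-completion inference."""
    ranked, _ = infer_indications(
        graph, answers.target_disease_id, k, min_distinct_types=min_distinct_types
    )
    predictions = {(c.drug_id, c.edge_type): c.score for c in ranked}
    labeled = ev.build_labeled_universe(predictions, answers, graph, typed_matching=True)
    result = ev.evaluate(labeled)
    return RunResult("tnmca", k, result.auc, result.positives, result.universe_size)


def evaluate_abc(graph: TypedGraph, answers: AnswerSet) -> RunResult:
    """Type-blind evaluation of the transitive ABC baseline."""
    scores = ev.abc_inference(graph, answers.target_disease_id)
    predictions = {(drug,): float(score) for drug, score in scores.items()}
    labeled = ev.build_labeled_universe(predictions, answers, graph, typed_matching=False)
    result = ev.evaluate(labeled)
    return RunResult("abc", None, result.auc, result.positives, result.universe_size)


def run_benchmark(
    config: GeneratorConfig,
    seeds,
    ks: tuple[int, ...] = (3, 4),
) -> dict[str, list[float]]:
    """Generate one network per seed and evaluate every model on it.

    Returns AUC lists keyed by ``"tnmca_k3"``, ``"tnmca_k4"``, ...,
    ``"abc"``.  Seeds with no usable answer set (no positive, or no
    negative) are skipped for every model alike.
    """
    out: dict[str, list[float]] = {f"tnmca_k{k}": [] for k in ks}
    out["abc"] = []
    for seed in seeds:
        graph, answers, _ = generate_network(replace(config, seed=int(seed)))
        if len(answers) == 0:
            continue
        for k in ks:
            out[f"tnmca_k{k}"].append(evaluate_tnmca(graph, answers, k).auc)
        out["abc"].append(evaluate_abc(graph, answers).auc)
    return out


def summarize_benchmark(results: dict[str, list[float]]) -> dict[str, float]:
    return {name: float(np.mean(vals)) for name, vals in results.items() if vals}
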