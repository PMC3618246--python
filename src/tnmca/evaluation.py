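"""ROC/AUC evaluation against held-out indications, plus the ABC baseline.

The ABC (Swanson) baseline scores each drug by the number of distinct
intermediates — genes or pathways adjacent to both the drug and the
target disease — echoing transitive literature-based discovery.  It
predicts only edge existence, so its hits are judged type-blind, whereas
the motif-based model must also match the interaction type.

Both models are evaluated over a fixed universe of items (drug x
interaction-type pairs for typed matching, plain drugs otherwise); items
a model does not emit score 0.  The AUC is the tie-aware Mann-Whitney
statistic (ties contribute 1/2), identical to the trapezoidal area under
the threshold-swept ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skmetrics

from .network_filters import AnswerSet
from .typed_graph import UNTYPED, TypedGraph


@dataclass(frozen=True)
class LabeledScore:
    item: tuple  # (drug_id,) or (drug_id, edge_type)
    score: float
    positive: bool


@dataclass
class EvaluationResult:
    roc_points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float
    positives: int
    universe_size: int


def abc_inference(
    graph: TypedGraph,
    target: str,
    chemical_type: str = "chemical",
    intermediate_types: tuple[str, ...] = ("gene", "pathway"),
) -> dict[str, int]:
    """Score drugs by distinct gene/pathway neighbors shared with the target.

    Returns only drugs with a nonzero score; the evaluation universe
    adds the remaining drugs back at score 0.
    """
    if target not in graph:
        raise ValueError(f"target disease {target!r} not in graph")
    target_mediators = {
        n for n in graph.neighbors(target)
        if graph.node_type(n) in intermediate_types
    }
    scores: dict[str, int] = {}
    for drug in graph.nodes_of_type(chemical_type):
        count = len(graph.neighbors(drug) & target_mediators)
        if count > 0:
            scores[drug] = count
    return scores


def build_labeled_universe(
    predictions: dict[tuple, float],
    answers: AnswerSet,
    graph: TypedGraph,
    typed_matching: bool,
    chemical_type: str = "chemical",
    disease_type: str = "disease",
) -> list[LabeledScore]:
    """Assemble the scored universe for ROC analysis.

    ``predictions`` maps items to scores: ``(drug_id, edge_type)`` keys
    for typed matching, ``(drug_id,)`` keys otherwise.  With typed
    matching an item is positive only for the exact typed answer edge;
    without, any answered drug is positive regardless of type.
    """
    drugs = graph.nodes_of_type(chemical_type)
    if typed_matching:
        vocab = {UNTYPED}
        for u, v, et in graph.edges():
            if {graph.node_type(u), graph.node_type(v)} == {chemical_type, disease_type}:
                vocab.add(et)
        vocab.update(et for _, _, et in answers.edges)
        vocab.update(key[1] for key in predictions)
        positives = {(d, et) for d, _, et in answers.edges}
        items: list[tuple] = [(d, et) for d in drugs for et in sorted(vocab)]
    else:
        positives = {(d,) for d in answers.drugs()}
        items = [(d,) for d in drugs]
    return [
        LabeledScore(
            item=item,
            score=float(predictions.get(item, 0.0)),
            positive=item in positives,
        )
        for item in items
    ]


def _arrays(labeled) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([int(ls.positive) for ls in labeled])
    scores = np.array([ls.score for ls in labeled], dtype=float)
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return labels, scores


def auc(labeled) -> float:
    """Tie-aware rank AUC (probability a positive outranks a negative)."""
    labels, scores = _arrays(labeled)
    return float(_skmetrics.roc_auc_score(labels, scores))


def roc_curve(labeled) -> list[tuple[float, float]]:
    """Threshold-swept (FPR, TPR) staircase from (0, 0) to (1, 1)."""
    labels, scores = _arrays(labeled)
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def evaluate(labeled) -> EvaluationResult:
    return EvaluationResult(
        roc_points=roc_curve(labeled),
        auc=auc(labeled),
        positives=sum(ls.positive for ls in labeled),
        universe_size=len(labeled),
    )
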