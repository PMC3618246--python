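# Methods

## Model

The training data is an undirected multigraph G = (V, E) whose nodes
carry an entity type (chemical, gene, disease, pathway) and whose edges
carry an optional interaction type; parallel edges between the same pair
are allowed when their types differ, and a typeless edge carries the
reserved `UNTYPED` label, which participates in matching as an ordinary
edge type. Self-loops are rejected.

A **typed network motif** (TNM) at size k is the isomorphism class —
under node- and edge-type-preserving permutations — of a k-node induced
subgraph that is connected, has distinct-neighbor degree ≥ 2 at every
node, and spans at least `min_distinct_types` node types (default 3).
The degree floor exists because a pendant node supports no completion
inference; the size floor k ≥ 3 because a two-node subgraph is a single
relation, not a pattern. Subgraphs are *induced*: all parent edges among
the chosen nodes, including parallel typed edges, belong to the
instance. Frequencies count node sets; overlapping instances each count,
automorphisms do not inflate counts.

**Inference** for a target disease s: for every chemical d and every
candidate interaction type t (the types observed on chemical–disease
edges of the training graph, plus `UNTYPED`) such that (d, s, t) is
absent, the tentative edge is added and every valid k-node instance
through it is canonicalized. Keys found in the census form the
candidate's referenced set — the observed subgraph matches each such
pattern in all but the one missing relation. Candidates with empty
referenced sets are not emitted, and an edge already present with the
same type is never re-proposed.

**Scores.** Pattern score = relative census frequency (in (0, 1],
summing to 1 per census; the 3-node and 4-node censuses are normalized
separately, as the two sizes are separate experiments). Candidate score
= noisy-OR over *distinct* referenced patterns, so evidence accumulates
and each candidate dominates every supporting pattern's score; with a
single referenced pattern the two are equal. Ranking is by score, then
summed referenced frequency, then (drug id, edge type) for determinism.
The default score threshold is 0 (rank everything) because evaluation
sweeps the whole ROC curve.

**Evaluation.** The answer set holds the chemical–target edges removed
from the training graph. The typed model is evaluated over the full
drug × edge-type universe with exact typed matching; the ABC baseline
(score = number of distinct gene/pathway nodes adjacent to both drug and
target) predicts only existence and is evaluated type-blind over drugs.
Items a model does not emit score 0. AUC is the tie-aware Mann–Whitney
statistic (ties count ½), identical to the trapezoidal area under the
threshold-swept ROC; it is undefined (an error) when either class is
empty.

## Algorithms and numerics

- *Enumeration.* `enumerate_connected_subgraphs` is an ESU-style
  reverse search yielding each connected k-set once. The census does not
  need all connected sets, only those with skeleton min degree ≥ 2, so
  it uses a direct enumerator: triangles at k = 3; at k = 4 every
  qualifying set contains a spanning 4-cycle, so sets are found as pairs
  of common neighbors of each "diagonal" node pair. This sidesteps the
  combinatorial blowup around hub nodes (a hub of degree ~300 has ~10⁶
  connected 4-sets but only thousands of cycle-closing ones). Both
  enumerators are equivalence-tested against exhaustive subset oracles;
  k ≥ 5 falls back to ESU plus filtering.
- *Canonical labeling.* Exact minimization of the
  (sorted-type-sequence, edge-list) representation over all node
  orderings consistent with sorting nodes by type — at most k! ≤ 120
  permutations for the k ≤ 5 regime this package targets, in practice
  far fewer because only within-type-block permutations vary. Verified
  against full-permutation search on the exhaustive universe of valid
  patterns with ≤ 4 nodes, 3 node types and 2 edge types.
- *Completion search.* Candidate k-sets around the tentative edge
  (d, s) exploit the same degree floor: the drug needs a second
  within-set neighbor, so enumeration starts from N(d) rather than from
  the (possibly huge) neighborhood of the target.
- *Ties and degeneracy.* All orderings (rows in output files, candidate
  ranks, RNG consumption in the generator) are totally ordered by sorted
  keys so that identical inputs give byte-identical outputs.

## Synthetic benchmark

The generator emulates the structure of a curated
chemical–gene–disease–pathway network: four node types; interaction
types only on chemical–gene, chemical–disease and gene–disease pairs
(two-label vocabularies per pair, e.g. `therapeutic`/`marker`); untyped
edges elsewhere. Defaults: 200 chemicals, 300 genes, 40 diseases, 50
pathways; 100 planted 3-node and 100 planted 4-node motif instances
around one target disease; 20% of chemical–target edges held out; sparse
uniform background noise (expected ~350 edges, rates per type pair
chosen so noise is an order of magnitude below planted structure but
still creates occasional spurious completions).

Two default templates are planted: a chemical–gene–disease triangle
(all edges typed) and a chemical–pathway–gene–disease 4-cycle *without*
a drug–gene edge — the shape of the most frequent 4-node pattern in real
curated data, where drugs often act on disease pathways rather than
disease genes. Instances are planted over a shared 100-drug indication
cohort (each cohort drug receives instances of every template),
reflecting that a genuine indication is typically supported through both
gene- and pathway-mediated mechanisms; non-cohort drugs and non-target
diseases receive only noise. The hold-out pool is every chemical–target
edge present after planting and noise, which keeps pure-noise
configurations evaluable (they otherwise have no positives at all).

What the generator does **not** emulate: real degree distributions
(CTD's chemical–gene table alone has ~5 × 10⁵ rows), inferred-vs-curated
evidence tiers, hub chemicals, or hierarchy structure among the decoy
diseases. A green parameter-recovery test therefore establishes that the
pipeline recovers signal it is designed to detect and stays at chance on
noise — not that real-data AUC levels are reproduced; the published
full-scale figures depend on specific database snapshots and are out of
scope here.

## Parameters that matter

| Parameter | Default | Notes |
|---|---|---|
| k (motif size) | 3 or 4 | k ≥ 5 is combinatorially explosive on real data |
| `min_distinct_types` | 3 | formal motif definition; set 2 to relax to node-count-only |
| hierarchy depth | 1 | top-level tree-number category; 0 disables the filter |
| `unknown_disease_policy` | drop | diseases lacking tree numbers leave the training set |
| `score_threshold` | 0 | keep-all; raise to emit a short list |
| `holdout_fraction` | 0.2 | of chemical–target edges, generator benchmarks only |
| noise rates | ~3–10 × 10⁻³ per pair | per type pair, see `synthgen.DEFAULT_NOISE_RATES` |

## Design choices made where the definition was open

- "More than two" in the motif definition is read as: k counts *nodes*
  (minimum 3), with the distinct-*type* minimum exposed separately as
  `min_distinct_types` (default 3). Both readings are thus supported.
- The noisy-OR product runs over distinct canonical keys, not instance
  multiplicities; multiplicity enters through the pattern frequency and
  the tie-break.
- Candidate edges are restricted to (drug, target disease, type)
  triples; the machinery generalizes but other edge categories are not
  evaluated.
- ABC "counts" are distinct intermediates, not paths; the two differ
  only via parallel typed edges.
- The evaluation universe includes zero-scored non-predictions so the
  AUC is defined over the full candidate space.
- Isolated nodes left by filters are retained: they cannot join any
  motif (degree floor) and are harmless.

## Known limitations

- Canonicalization is exhaustive-exact and sized for k ≤ 5; no
  nauty-style refinement for larger patterns.
- Motif frequency is raw count, not a z-score against randomized
  networks; "significant" here means frequent.
- Candidate scores are coarsely tied by construction (every candidate
  referencing the same pattern set scores identically), which is why the
  AUC implementation must be tie-aware.
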