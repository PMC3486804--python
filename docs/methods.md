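# Methods

## Problem and model

The package classifies candidate drug pairs in single sentences: given a
sentence, its dependency parse, and two marked drug mentions, decide
whether the sentence asserts an interaction.  The hypothesis behind the
design is that the relation-bearing signal lives in sentence *structure* —
in particular in the dependency path between the candidates and its
immediate neighborhood — rather than in the identity of the drugs, which is
why candidate mentions are blinded to `DRUG1`/`DRUG2` and bystander drug
mentions to `DRUG` before any feature is computed.

### Sentence graph

Each instance becomes a directed vertex-labeled graph with two
node-disjoint components.  The dependency component has one node per token
(label `lowercase(form)/lowercase(pos)`; blinded tokens carry no POS suffix
so they match regardless of tagging) and one node per dependency, labeled
with the relation string and wired `governor → relation → dependent`.
Materializing relations as nodes keeps the kernel purely vertex-labeled
while preserving edge labels, and the fixed one-in/one-out arity of
relation nodes is a structural invariant checked by `validate_graph`.  The
linear component carries the same tokens with left-to-right successor
edges.  Edges never cross components, so all matrices over the graph are
block-diagonal.

Multi-token mentions collapse onto the span's syntactic head (the unique
token whose head lies outside the span; first token as fallback), and
external dependencies re-attach to the collapsed node.  Dependencies
internal to a span vanish; duplicates arising from re-attachment are
merged.  Non-tree parses (cycles, multiple heads) are accepted verbatim —
nothing downstream assumes a tree.

### Pruning

The dependency component keeps the shortest undirected path between the two
candidate tokens, every token exactly one relation-node hop from a path
token, and the relation nodes both of whose endpoints survive.  The linear
component keeps the candidate span ± 1 token.  Shortest paths are computed
over undirected edges because directed dependency graphs routinely make the
candidates mutually unreachable; ties between equal-length paths break to
the lexicographically smallest node-id sequence for determinism.  "One hop
from *any* path token" (rather than from the candidates only) is the
adopted reading of the neighborhood rule.  When the candidates are
disconnected the dependency component is kept whole and the instance is
flagged (`prune_fallback` in provenance) instead of being dropped.  Pruning
is idempotent and never removes a candidate.

### Hashing

Labels are encoded as D-bit codes assigned sequentially from 1 in
first-seen order (0 is reserved as null, 2^D − 1 as the unknown-label code
used when a frozen vocabulary meets an unseen label at inference).
Sequential assignment makes encodings reproducible where random draws would
not be, at the cost that the code of a label depends on the order in which
the corpus is traversed — all invariance properties therefore hold *given*
a shared vocabulary.  The neighborhood hash update rotates the node's own
label by `rot_center` and XORs in the in-/out-neighbor labels rotated by
`rot_in`/`rot_out`; the three offsets (defaults 1, 2, 3) need only be
pairwise distinct, which is what makes edge direction observable.  Level k
of the hierarchy (k ≤ R) then characterizes the labeled radius-k
neighborhood: nodes with isomorphic, identically-labeled radius-k
neighborhoods receive equal level-k values exactly, and unequal
neighborhoods collide only with probability ≈ 2^−D.  D = 24 keeps that
negligible at corpus scale (vocabularies of 10^4–10^5 labels); any D ≤ 62
is accepted.

### Kernel

Walk weights come from the Neumann series W = (I − γA)⁻¹ = Σ γⁿAⁿ,
computed by one dense matrix inversion per graph.  Convergence requires
γ·ρ(A) < 1 and is checked per graph (the spectral radius is reported in
the raised error on divergence).  By default A is the *symmetrized*
adjacency: on directed dependency structures most ordered node pairs have
no directed walk at all, which would empty the pairwise feature space; the
directed structure still enters through the hash update.  The n = 0
identity term is included, so the diagonal contributes plain
single-subgraph (bag-of-hash-labels) features.

Per level k, a graph maps to a sparse vector indexed by ordered hash-label
pairs (a, b) with value Σ W_ij over node pairs labeled (a, b); labels are
tagged with their component by default so dependency and linear features
never collide.  The kernel is K = Σ_k βᵏ⟨φ_k(g), φ_k(g′)⟩ — an explicit
inner product, hence positive semidefinite by construction — optionally
cosine-normalized so K(g, g) = 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| D | 24 | hash bit width; 2^D must exceed the vocabulary size |
| R | 2 | hierarchy bound; level k sees radius k (larger R risks over-fitting via over-specific subgraphs) |
| β | 0.6 | per-level decay βᵏ, balancing small vs. large subgraph pairs |
| γ | 0.25 | walk-length decay; must keep γ·ρ(A) < 1 |
| w | 1.0 | uniform edge weight |
| rot offsets | (1, 2, 3) | center/in/out rotations; only distinctness matters |
| normalize | on | cosine normalization of K |
| symmetrize_walks | on | walk matrix over undirected edges |
| tag_components | on | disjoint dependency/linear feature spaces |
| C | 1.0 | SVM regularization (sweep externally when tuning) |

β = 0.6 and D = 24 are the operating points reported for the DDI task this
kernel was designed for; R defaults to 2 as a small radius that already
captures path-plus-neighbor structure without exploding feature
specificity.

## Evaluation

Metrics are computed from pooled confusion counts: precision, recall, F,
accuracy, and Matthews correlation, with all zero-denominator cases defined
as 0.  AUC is the Mann–Whitney rank statistic on raw SVM decision values
with ties counted ½.  Cross-validation splits at the *document* level
(documents shuffled by seed, dealt round-robin) so sentences of one
document never straddle a fold boundary; each fold refits the vocabulary
and classifier on its training portion only.  Reports carry both the pooled
(micro) metrics and the per-fold (macro) means with standard deviations;
micro is the default headline.

## Synthetic data

The toy-corpus generator emulates a DDI corpus structurally: documents of
10 sentences, each sentence one of ten hand-parsed template frames with two
drug entities and one labeled candidate pair, drug names drawn from a
20-name pool and open slots (trigger verbs, effect nouns, adverbs) from
small pools for lexical variety.  The planted signal is the design's own
hypothesis made literal: positive frames place an interaction trigger verb
on the dependency path between the candidates; negative frames never do.
Two frames carry a prunable leading clause in the style of a case-report
preamble, and one negative frame buries a trigger verb inside a relative
clause two hops off the path — pruning removes it, an unpruned graph sees a
misleading trigger.  Defaults (200 instances, positive rate 0.3, documents
of 10) are the study conditions used by the acceptance checks.

What passing on this corpus shows: the full pipeline — XML/parse reading,
blinding, graph construction, pruning, hashing, kernel, SVM, document-level
CV — preserves and recovers a structural signal.  What it does not show:
robustness to parser noise, lexical ambiguity, negation, coordination, or
the heavy class imbalance of real corpora (≈10 % positives with far more
varied negatives); real-corpus F-scores are far below the toy corpus's.
Reproducing published corpus-level results would require the external
DDI-2011 corpus and its parses, which are deliberately out of scope.

## Numerical choices

* Walk matrices use dense `inv(I − γA)`; graphs are sentence-sized
  (tens of nodes), so cubic inversion is negligible and exact to ~1e-15
  against the truncated series.
* Gram computation extracts features exactly once per graph (contract
  tested), then forms pairwise inner products; normalization divides by
  unnormalized self-kernels, with a 0/0 guard returning 0.
* Node ordering for all matrices is ascending node id; ids are assigned in
  construction order (dependency tokens, relation nodes, linear tokens).
* Isomorphism invariance of kernel values holds to ~1 ulp, not bitwise:
  permuting a matrix changes LAPACK summation order.
* Degenerate inputs: empty graphs yield W = I and bag features; a
  single-token sentence has an edgeless linear component; equal-length
  shortest paths and label ties are broken deterministically.

## Known limitations

* Vocabulary codes are corpus-order dependent; models must persist their
  vocabulary (the CLI does) and freeze it at inference, mapping unseen
  labels to one UNK code.
* No collision resolution beyond the D-bit birthday argument; collision
  monitoring only.
* The γ convergence bound depends on the densest graph in a batch; one
  divergent graph aborts the Gram computation by design rather than being
  silently skipped.
* Only binary, sentence-internal, unordered pairs are modeled; cross-
  sentence relations and interaction *types* are out of scope.
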