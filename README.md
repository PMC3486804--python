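# hspkernel

A hash subgraph pairwise (HSP) graph kernel for extracting drug–drug
interactions (DDIs) from dependency-parsed biomedical text.

When one drug changes the level or activity of another, database curators
need to find the sentence that says so.  Cast as machine learning, each
candidate drug pair in a sentence is a binary classification instance:
does this sentence assert an interaction between these two drugs?  This
package implements a single graph kernel over sentence structure that is
competitive with multi-kernel systems, together with everything needed to
run it end to end: corpus readers, entity blinding, graph construction,
shortest-path pruning, the kernel itself, and a precomputed-kernel SVM with
cross-validated evaluation.

## The method

Each sentence with a marked candidate pair becomes a directed
vertex-labeled graph with two disjoint components:

* a **dependency subgraph**: one node per token labeled `form/pos`
  (candidates blinded to `DRUG1` / `DRUG2`, other drug mentions to `DRUG`),
  with each dependency materialized as an intermediate relation node,
  `head → relation → dependent`;
* a **linear subgraph**: the same tokens with successor edges in sentence
  order.

The graph is **pruned** to the syntactic neighborhood of the candidates:
the dependency component keeps the shortest path between `DRUG1` and
`DRUG2` plus tokens one dependency hop away; the linear component keeps the
candidate span ± 1 token.

Every node label gets a unique D-bit code (D = 24 by default).  The
**neighborhood hash** is iterated R times,

    h_{k+1}(v) = ROT_c h_k(v)  ⊕  ⊕_{u→v} ROT_i h_k(u)  ⊕  ⊕_{v→u} ROT_o h_k(u),

with distinct cyclic-rotation offsets for the node itself and its in- and
out-neighbors, so level k encodes the labeled neighborhood of radius k.
Walk weights come from the Neumann series

    W = (I − γA)⁻¹ = Σ_n γⁿ Aⁿ,

and each graph maps, per level, to a sparse vector over ordered **subgraph
pairs** (a, b) of hash labels, weighted by the total walk weight between
nodes carrying them.  The kernel is the level-decayed inner product

    K(g, g′) = Σ_{k=0}^{R} βᵏ ⟨φ_k(g), φ_k(g′)⟩,

cosine-normalized by default, and fed to an SVM through its
precomputed-kernel interface.  Defaults: D = 24, R = 2, β = 0.6, γ = 0.25,
uniform edge weight w = 1.

## Worked example

The package ships a seeded generator for a planted-signal toy corpus
(positive pairs have an interaction verb on the candidates' dependency
path), so the whole pipeline runs without any external data:

```python
from pathlib import Path
from hspkernel import toy_corpus, load_instances, graph_from_instance, cross_validate

toy_corpus(seed=7, n_sentences=60, positive_rate=0.3, out_dir="demo")
instances = load_instances(Path("demo/corpus.xml"), Path("demo/parses.conll"))
graphs = [graph_from_instance(inst) for inst in instances]   # blind + build + prune
report = cross_validate(
    graphs,
    [inst.label for inst in instances],
    [inst.document_id for inst in instances],
    n_folds=5,
    seed=7,
)
print(report.table())
```

prints

```
TP	FP	FN	TN	P	R	F	Acc	MCC	AUC
17	0	0	43	100.0	100.0	100.0	100.0	100.0	100.0
```

i.e. the 5-fold document-level cross-validation recovers the planted signal
perfectly on these 60 instances: 17 true interactions found, no false
positives or negatives, so precision, recall, F-score, accuracy, Matthews
correlation and AUC (all in percent) are 100.  On real corpora the same
numbers are the ones to report; the evaluator reproduces published
confusion-matrix rows to one decimal (e.g. TP=508, FP=297, FN=248, TN=5973
→ P=63.1, R=67.2, F=65.1, Acc=92.2, MCC=60.8).

The same pipeline from a shell:

```bash
hspk make-fixtures --out demo --n-sentences 60 --positive-rate 0.3 --seed 7
hspk cv --corpus demo/corpus.xml --parses demo/parses.conll --folds 5 --seed 7 --out report.json
```

Estimator classes compose with scikit-learn: `HSPKernel` is a transformer
whose `fit_transform` yields the training Gram matrix, and `HSPClassifier`
is a full graph-in/label-out classifier with `get_params`/`set_params` for
grid search.

## Input formats

* **Corpus XML**: `<corpus><document id><sentence id text><entity id
  charOffset="s-e" text/><pair e1 e2 interaction="true|false"/>...`.
  `charOffset` is inclusive at both ends, as DDI corpora print it.
* **Parses**: blank-line-separated blocks, first line `# <sentence id>`,
  then tab-separated rows `index form POS head relation` (1-based indices,
  head 0 = root).

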