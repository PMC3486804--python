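import numpy as np
import pytest

from hspkernel.corpus_io import load_instances
from hspkernel.graph_model import Component, LabeledNode, NodeKind, SentenceGraph
from hspkernel.synthetic import toy_corpus


def make_graph(token_labels, relations=(), drug1=None, drug2=None, linear=False, w=1.0):
    """Compact dependency-component graph builder for tests.

    ``token_labels`` -> token nodes 0..n-1; ``relations`` is a list of
    (head_token, dependent_token, relation_label) materialized as relation
    nodes n, n+1, ... with edges head -> rel -> dependent.  With ``linear``
    a mirrored linear component (ids offset past the relation nodes) is
    added with successor edges.
    """
    n = len(token_labels)
    nodes = [
        LabeledNode(i, lab, NodeKind.TOKEN, Component.DEPENDENCY, token_index=i)
        for i, lab in enumerate(token_labels)
    ]
    edges = set()
    next_id = n
    for (h, d, rel) in relations:
        nodes.append(LabeledNode(next_id, rel, NodeKind.DEPENDENCY_RELATION, Component.DEPENDENCY))
        edges.add((h, next_id))
        edges.add((next_id, d))
        next_id += 1
    drug1_ids = () if drug1 is None else (drug1,)
    drug2_ids = () if drug2 is None else (drug2,)
    if linear:
        base = next_id
        for i, lab in enumerate(token_labels):
            nodes.append(LabeledNode(base + i, lab, NodeKind.TOKEN, Component.LINEAR, token_index=i))
            if i > 0:
                edges.add((base + i - 1, base + i))
        if drug1 is not None:
            drug1_ids = (drug1, base + drug1)
        if drug2 is not None:
            drug2_ids = (drug2, base + drug2)
    return SentenceGraph(
        nodes=tuple(nodes),
        edges=frozenset(edges),
        edge_weight=w,
        drug1_ids=drug1_ids,
        drug2_ids=drug2_ids,
    )


def permute_graph(g: SentenceGraph, seed: int) -> tuple[SentenceGraph, dict]:
    """Isomorphic copy of ``g`` under a random node-id permutation."""
    rng = np.random.default_rng(seed)
    ids = sorted(g.node_ids)
    new_ids = [int(x) for x in rng.permutation(len(ids))]
    mapping = dict(zip(ids, new_ids))
    nodes = tuple(
        LabeledNode(mapping[n.node_id], n.label, n.kind, n.component, n.token_index)
        for n in g.nodes
    )
    edges = frozenset((mapping[u], mapping[v]) for (u, v) in g.edges)
    return (
        SentenceGraph(
            nodes=nodes,
            edges=edges,
            edge_weight=g.edge_weight,
            drug1_ids=tuple(mapping[i] for i in g.drug1_ids),
            drug2_ids=tuple(mapping[i] for i in g.drug2_ids),
        ),
        mapping,
    )


@pytest.fixture(scope="session")
def toy_corpus_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("toycorpus")
    toy_corpus(seed=7, n_sentences=40, positive_rate=0.4, out_dir=d)
    return d


@pytest.fixture(scope="session")
def toy_instances(toy_corpus_dir):
    return load_instances(toy_corpus_dir / "corpus.xml", toy_corpus_dir / "parses.conll")
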