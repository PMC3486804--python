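"""Construction of the two-component sentence graph.

The dependency component materializes each dependency as a labeled relation
node: head token -> relation node -> dependent token, so the relation node
has exactly one in-edge and one out-edge and edge direction encodes the
governor/dependent distinction.  The linear component carries one node per
token with a directed edge to its successor in sentence order.

Token nodes are labeled ``lowercase(form)/lowercase(pos)`` (e.g.
``"treated/vbn"``); blinded candidate tokens are labeled exactly ``DRUG1``,
``DRUG2`` or ``DRUG`` with no POS suffix, so a candidate matches regardless
of how its surface form was tagged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import BlindingPlan, CandidateInstance, blind_entities
from .errors import GraphValidationError
from .graph_model import Component, LabeledNode, NodeKind, SentenceGraph

__all__ = ["build_graph", "graph_from_instance"]

_BLIND_LABELS = {"DRUG1", "DRUG2", "DRUG"}


@dataclass(frozen=True)
class _MergedToken:
    label: str
    blinded: bool


def _merge_tokens(instance: CandidateInstance, plan: BlindingPlan):
    """Apply the blinding plan: collapse mention spans, remap dependencies."""
    parse = instance.parse
    n = len(parse.tokens)
    replacement: dict[int, str] = {}  # original index -> blinded label (kept token only)
    redirect: dict[int, int] = {}  # original index -> surviving original index
    removed: set[int] = set()
    for (kept, members, label) in plan.groups:
        replacement[kept] = label
        for m in members:
            redirect[m] = kept
            if m != kept:
                removed.add(m)

    surviving = [i for i in range(n) if i not in removed]
    new_index = {orig: j for j, orig in enumerate(surviving)}

    tokens: list[_MergedToken] = []
    for orig in surviving:
        if orig in replacement:
            tokens.append(_MergedToken(replacement[orig], blinded=True))
        else:
            tok = parse.tokens[orig]
            tokens.append(_MergedToken(f"{tok.form.lower()}/{tok.pos.lower()}", blinded=False))

    deps: list[tuple[int, int, str]] = []
    seen: set[tuple[int, int, str]] = set()
    for (h, d, rel) in parse.dependencies:
        h2 = new_index[redirect.get(h, h)]
        d2 = new_index[redirect.get(d, d)]
        if h2 == d2:  # dependency internal to a collapsed mention
            continue
        key = (h2, d2, rel)
        if key in seen:
            continue
        seen.add(key)
        deps.append(key)

    def _position(kept_orig: int) -> int:
        return new_index[kept_orig]

    drug1_pos = drug2_pos = None
    for (kept, _members, label) in plan.groups:
        if label == "DRUG1":
            drug1_pos = _position(kept)
        elif label == "DRUG2":
            drug2_pos = _position(kept)
    if drug1_pos is None or drug2_pos is None:
        raise GraphValidationError(
            f"sentence {instance.sentence_id}: candidate token absent after blinding"
        )
    return tokens, deps, drug1_pos, drug2_pos


def build_graph(
    instance: CandidateInstance, plan: BlindingPlan | None = None, edge_weight: float = 1.0
) -> SentenceGraph:
    """Two-component sentence graph for one blinded candidate instance.

    Node ids are assigned in construction order: dependency-component token
    nodes (by sentence position), then relation nodes (in parse order), then
    linear-component token nodes.  The resulting graph always satisfies the
    structural invariants by construction: 2*T + D nodes and 2*D + (T - 1)
    edges for T tokens and D dependencies.
    """
    if plan is None:
        plan = blind_entities(instance)
    tokens, deps, drug1_pos, drug2_pos = _merge_tokens(instance, plan)
    T = len(tokens)

    nodes: list[LabeledNode] = []
    edges: set[tuple[int, int]] = set()
    for i, tok in enumerate(tokens):
        nodes.append(
            LabeledNode(i, tok.label, NodeKind.TOKEN, Component.DEPENDENCY, token_index=i)
        )
    next_id = T
    for (h, d, rel) in deps:
        rel_id = next_id
        next_id += 1
        nodes.append(LabeledNode(rel_id, rel, NodeKind.DEPENDENCY_RELATION, Component.DEPENDENCY))
        edges.add((h, rel_id))
        edges.add((rel_id, d))
    linear_base = next_id
    for i, tok in enumerate(tokens):
        nodes.append(
            LabeledNode(linear_base + i, tok.label, NodeKind.TOKEN, Component.LINEAR, token_index=i)
        )
        if i > 0:
            edges.add((linear_base + i - 1, linear_base + i))

    return SentenceGraph(
        nodes=tuple(nodes),
        edges=frozenset(edges),
        edge_weight=edge_weight,
        drug1_ids=(drug1_pos, linear_base + drug1_pos),
        drug2_ids=(drug2_pos, linear_base + drug2_pos),
        provenance={
            "sentence_id": instance.sentence_id,
            "document_id": instance.document_id,
            "label": instance.label,
            "blinding_warnings": list(plan.warnings),
        },
    )


def graph_from_instance(
    instance: CandidateInstance, prune: bool = True, edge_weight: float = 1.0
) -> SentenceGraph:
    """Blind, build and (optionally) prune in one step."""
    g = build_graph(instance, edge_weight=edge_weight)
    if prune:
        from .pruning import prune as _prune

        g = _prune(g)
    return g
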