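"""Shortest-path-centered pruning of the sentence graph.

The syntactic neighborhood of the candidate pair carries most of the
relation-bearing structure; the rest of the sentence is noise for the
kernel.  Pruning therefore keeps

* in the dependency component: the token nodes on the shortest path between
  the two candidates (over undirected edges), every token one
  dependency-relation hop away from a shortest-path token, and the relation
  nodes whose both endpoint tokens survive;
* in the linear component: the tokens between the candidates plus one
  adjacent token on each side.

If the candidates are disconnected in the dependency component the
component is kept unpruned (flagged in the result) rather than dropping the
instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .errors import GraphValidationError
from .graph_model import Component, NodeKind, SentenceGraph, require_valid

__all__ = ["shortest_path_tokens", "prune", "prune_info", "PruneResult"]


@dataclass(frozen=True)
class PruneResult:
    graph: SentenceGraph
    fallback: bool  # dependency component kept unpruned (candidates disconnected)
    kept: int
    dropped: int


def _dependency_graph(g: SentenceGraph) -> nx.Graph:
    und = nx.Graph()
    dep_ids = {n.node_id for n in g.component_nodes(Component.DEPENDENCY)}
    und.add_nodes_from(sorted(dep_ids))
    for (u, v) in g.edges:
        if u in dep_ids and v in dep_ids:
            und.add_edge(u, v)
    return und


def shortest_path_tokens(g: SentenceGraph) -> list[int]:
    """A shortest undirected path between the candidates in the dependency component.

    Returns the full node-id sequence including intervening relation nodes,
    or an empty list when the candidates are disconnected.  Among
    equal-length paths the lexicographically smallest node-id sequence is
    chosen, so the result is deterministic.
    """
    require_valid(g)
    d1 = g.drug_id(1, Component.DEPENDENCY)
    d2 = g.drug_id(2, Component.DEPENDENCY)
    if d1 is None or d2 is None:
        raise GraphValidationError("graph has no candidate markers in the dependency component")
    und = _dependency_graph(g)
    if not nx.has_path(und, d1, d2):
        return []
    return min(nx.all_shortest_paths(und, d1, d2), key=lambda p: tuple(p))


def prune_info(g: SentenceGraph) -> PruneResult:
    """Prune ``g`` and report provenance (fallback flag, kept/dropped counts)."""
    require_valid(g)
    path = shortest_path_tokens(g)
    dep_nodes = g.component_nodes(Component.DEPENDENCY)
    fallback = not path

    if fallback:
        kept_dep = {n.node_id for n in dep_nodes}
    else:
        path_tokens = {i for i in path if g.node(i).kind == NodeKind.TOKEN}
        # direct-neighbor tokens: one relation-node hop from any path token
        neighbor_tokens: set[int] = set()
        for rel in dep_nodes:
            if rel.kind != NodeKind.DEPENDENCY_RELATION:
                continue
            ends = set(g.undirected_neighbors(rel.node_id))
            if ends & path_tokens:
                neighbor_tokens |= ends - path_tokens
        kept_tokens = path_tokens | neighbor_tokens
        kept_dep = set(kept_tokens)
        for rel in dep_nodes:
            if rel.kind != NodeKind.DEPENDENCY_RELATION:
                continue
            ends = g.undirected_neighbors(rel.node_id)
            if all(e in kept_tokens for e in ends):
                kept_dep.add(rel.node_id)

    # linear window: candidate span plus one token on each side
    lin_nodes = g.component_nodes(Component.LINEAR)
    l1 = g.drug_id(1, Component.LINEAR)
    l2 = g.drug_id(2, Component.LINEAR)
    kept_lin: set[int] = set()
    if l1 is not None and l2 is not None:
        p1, p2 = g.node(l1).token_index, g.node(l2).token_index
        lo, hi = min(p1, p2) - 1, max(p1, p2) + 1
        kept_lin = {n.node_id for n in lin_nodes if lo <= n.token_index <= hi}
    else:
        kept_lin = {n.node_id for n in lin_nodes}

    keep = kept_dep | kept_lin
    pruned = g.subgraph(keep)
    pruned = replace(
        pruned,
        provenance={**dict(g.provenance), "pruned": True, "prune_fallback": fallback},
    )
    return PruneResult(
        graph=pruned,
        fallback=fallback,
        kept=len(keep),
        dropped=len(g.nodes) - len(keep),
    )


def prune(g: SentenceGraph) -> SentenceGraph:
    """Pruned copy of ``g``; idempotent."""
    return prune_info(g).graph
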