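"""Directed vertex-labeled sentence graphs.

A sentence is represented as a graph with two node-disjoint components:

* the **dependency** component encodes grammatical structure, with
  dependency relations materialized as intermediate labeled nodes
  (head token -> relation node -> dependent token);
* the **linear** component encodes left-to-right token order.

The two blinded candidate entity tokens (DRUG1, DRUG2) are marked so that
downstream pruning and feature extraction can locate them.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import GraphValidationError

__all__ = [
    "NodeKind",
    "Component",
    "LabeledNode",
    "SentenceGraph",
    "KernelConfig",
    "validate_graph",
    "adjacency",
    "write_graphs_jsonl",
    "read_graphs_jsonl",
]


class NodeKind(str, enum.Enum):
    TOKEN = "token"
    DEPENDENCY_RELATION = "dependency_relation"


class Component(str, enum.Enum):
    DEPENDENCY = "dependency"
    LINEAR = "linear"


@dataclass(frozen=True)
class LabeledNode:
    """A labeled graph node.

    ``token_index`` is the 0-based sentence position and is present exactly
    for token nodes; relation nodes carry the dependency relation string as
    their label and live in the dependency component only.
    """

    node_id: int
    label: str
    kind: NodeKind = NodeKind.TOKEN
    component: Component = Component.DEPENDENCY
    token_index: int | None = None


@dataclass(frozen=True)
class SentenceGraph:
    """Immutable directed vertex-labeled graph over two components.

    ``drug1_ids`` / ``drug2_ids`` hold the node ids of the blinded candidate
    tokens, at most one per component.  They may be empty for graphs that are
    not candidate instances (e.g. random graphs used for kernel testing).
    """

    nodes: tuple[LabeledNode, ...]
    edges: frozenset[tuple[int, int]]
    edge_weight: float = 1.0
    drug1_ids: tuple[int, ...] = ()
    drug2_ids: tuple[int, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes, key=lambda n: n.node_id)))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        object.__setattr__(self, "drug1_ids", tuple(self.drug1_ids))
        object.__setattr__(self, "drug2_ids", tuple(self.drug2_ids))

    # -- lookups ---------------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]

    def node(self, node_id: int) -> LabeledNode:
        return self._by_id[node_id]

    @property
    def _by_id(self) -> dict[int, LabeledNode]:
        d = self.__dict__.get("_by_id_cache")
        if d is None:
            d = {n.node_id: n for n in self.nodes}
            self.__dict__["_by_id_cache"] = d
        return d

    def component_nodes(self, component: Component) -> list[LabeledNode]:
        return [n for n in self.nodes if n.component == component]

    def in_neighbors(self, node_id: int) -> list[int]:
        return sorted(u for (u, v) in self.edges if v == node_id)

    def out_neighbors(self, node_id: int) -> list[int]:
        return sorted(v for (u, v) in self.edges if u == node_id)

    def undirected_neighbors(self, node_id: int) -> list[int]:
        return sorted(set(self.in_neighbors(node_id)) | set(self.out_neighbors(node_id)))

    def drug_id(self, which: int, component: Component) -> int | None:
        """Node id of the blinded candidate ``which`` (1 or 2) in ``component``."""
        ids = self.drug1_ids if which == 1 else self.drug2_ids
        for i in ids:
            if self.node(i).component == component:
                return i
        return None

    def subgraph(self, keep: Iterable[int]) -> "SentenceGraph":
        """Induced subgraph on ``keep``; candidate markers are filtered, ids kept."""
        keep = set(keep)
        return replace(
            self,
            nodes=tuple(n for n in self.nodes if n.node_id in keep),
            edges=frozenset((u, v) for (u, v) in self.edges if u in keep and v in keep),
            drug1_ids=tuple(i for i in self.drug1_ids if i in keep),
            drug2_ids=tuple(i for i in self.drug2_ids if i in keep),
        )


@dataclass
class KernelConfig:
    """All tunables of the HSP kernel.

    Parameters
    ----------
    D : int
        Bit width of the hash labels; 2**D must strictly exceed the label
        vocabulary size.  24 bits keeps collisions negligible at corpus scale.
    R : int
        Upper bound of the hash-label hierarchy: level k summarizes the
        labeled neighborhood of radius k around each node.
    beta : float
        Per-level decay: level k contributes with weight beta**k, scaling
        the impact of subgraph pairs of different sizes.
    gamma : float
        Walk-length decay of the Neumann series sum_n gamma^n A^n; must keep
        gamma * spectral_radius(A) < 1.
    w : float
        Uniform edge weight of the adjacency matrix.
    rot_center, rot_in, rot_out : int
        Cyclic-rotation offsets applied to a node's own label and the labels
        of its in-/out-neighbors in the hash update; distinct offsets make
        edge direction observable in the hash.
    normalize : bool
        Cosine-normalize kernel values: K(g,g) == 1.
    symmetrize_walks : bool
        Build the walk matrix from the symmetrized adjacency so every node
        pair in a connected component receives walk weight.
    tag_components : bool
        Keep dependency- and linear-component feature spaces disjoint.
    """

    D: int = 24
    R: int = 2
    beta: float = 0.6
    gamma: float = 0.25
    w: float = 1.0
    rot_center: int = 1
    rot_in: int = 2
    rot_out: int = 3
    normalize: bool = True
    symmetrize_walks: bool = True
    tag_components: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.D <= 62):
            raise GraphValidationError(f"D must be in [1, 62], got {self.D}")
        if self.R < 0:
            raise GraphValidationError(f"R must be non-negative, got {self.R}")
        if self.beta <= 0:
            raise GraphValidationError(f"beta must be > 0, got {self.beta}")
        if self.gamma < 0:
            raise GraphValidationError(f"gamma must be >= 0, got {self.gamma}")
        if self.w <= 0:
            raise GraphValidationError(f"edge weight must be > 0, got {self.w}")
        offsets = (self.rot_center, self.rot_in, self.rot_out)
        for o in offsets:
            if not (0 <= o < self.D):
                raise GraphValidationError(f"rotation offset {o} outside [0, {self.D})")
        if len(set(offsets)) != 3:
            raise GraphValidationError(f"rotation offsets must be pairwise distinct: {offsets}")


# ---------------------------------------------------------------------------


def validate_graph(g: SentenceGraph) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the graph is valid.  Violations name the offending
    node/edge ids so builder bugs are traceable.
    """
    violations: list[str] = []
    ids = set()
    for n in g.nodes:
        if n.node_id in ids:
            violations.append(f"duplicate node id {n.node_id}")
        ids.add(n.node_id)
        if not n.label:
            violations.append(f"node {n.node_id} has empty label")
        if n.kind == NodeKind.DEPENDENCY_RELATION:
            if n.component != Component.DEPENDENCY:
                violations.append(f"relation node {n.node_id} outside dependency component")
            if n.token_index is not None:
                violations.append(f"relation node {n.node_id} carries a token_index")
        elif n.token_index is None:
            violations.append(f"token node {n.node_id} missing token_index")

    # token positions unique within a component
    for comp in Component:
        seen: dict[int, int] = {}
        for n in g.component_nodes(comp):
            if n.token_index is None:
                continue
            if n.token_index in seen:
                violations.append(
                    f"duplicate token_index {n.token_index} in {comp.value} component "
                    f"(nodes {seen[n.token_index]}, {n.node_id})"
                )
            seen[n.token_index] = n.node_id

    if g.edge_weight <= 0:
        violations.append(f"edge weight must be positive, got {g.edge_weight}")

    for (u, v) in sorted(g.edges):
        if u not in ids or v not in ids:
            violations.append(f"edge ({u}, {v}) references missing node")
            continue
        if u == v:
            violations.append(f"self-loop at node {u}")
            continue
        if g.node(u).component != g.node(v).component:
            violations.append(f"edge ({u}, {v}) crosses components")

    for n in g.nodes:
        if n.kind != NodeKind.DEPENDENCY_RELATION:
            continue
        ins = [u for u in g.in_neighbors(n.node_id) if u in ids]
        outs = [v for v in g.out_neighbors(n.node_id) if v in ids]
        if len(ins) != 1 or len(outs) != 1:
            violations.append(
                f"relation node {n.node_id} has {len(ins)} in-edges and "
                f"{len(outs)} out-edges (expected 1 and 1)"
            )
        for m in ins + outs:
            if g.node(m).kind != NodeKind.TOKEN:
                violations.append(f"relation node {n.node_id} adjacent to non-token node {m}")

    for name, drug_ids in (("drug1", g.drug1_ids), ("drug2", g.drug2_ids)):
        comps = set()
        for i in drug_ids:
            if i not in ids:
                violations.append(f"{name} id {i} references missing node")
                continue
            node = g.node(i)
            if node.kind != NodeKind.TOKEN:
                violations.append(f"{name} id {i} is not a token node")
            if node.component in comps:
                violations.append(f"{name} has multiple nodes in {node.component.value} component")
            comps.add(node.component)
    overlap = set(g.drug1_ids) & set(g.drug2_ids)
    if overlap:
        violations.append(f"drug1 and drug2 ids overlap: {sorted(overlap)}")

    return violations


def require_valid(g: SentenceGraph) -> None:
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError("; ".join(violations))


def adjacency(g: SentenceGraph, symmetrize: bool = False) -> tuple[np.ndarray, list[int]]:
    """Weighted adjacency matrix over the deterministic node ordering.

    Returns ``(A, order)`` where ``order`` is the ascending node-id list and
    ``A[i, j] == w`` iff the edge ``order[i] -> order[j]`` exists (plus the
    reverse direction when ``symmetrize``).  The matrix is block-diagonal
    with respect to the two components because edges never cross them.
    """
    require_valid(g)
    order = sorted(g.node_ids)
    index = {nid: i for i, nid in enumerate(order)}
    A = np.zeros((len(order), len(order)))
    for (u, v) in g.edges:
        A[index[u], index[v]] = g.edge_weight
        if symmetrize:
            A[index[v], index[u]] = g.edge_weight
    return A, order


# -- serialization ----------------------------------------------------------


def _graph_to_dict(g: SentenceGraph) -> dict:
    return {
        "nodes": [
            {
                "id": n.node_id,
                "label": n.label,
                "kind": n.kind.value,
                "component": n.component.value,
                **({"token_index": n.token_index} if n.token_index is not None else {}),
            }
            for n in g.nodes
        ],
        "edges": sorted([list(e) for e in g.edges]),
        "edge_weight": g.edge_weight,
        "drug1_ids": list(g.drug1_ids),
        "drug2_ids": list(g.drug2_ids),
        "provenance": dict(g.provenance),
    }


def _graph_from_dict(d: dict) -> SentenceGraph:
    nodes = tuple(
        LabeledNode(
            node_id=nd["id"],
            label=nd["label"],
            kind=NodeKind(nd["kind"]),
            component=Component(nd["component"]),
            token_index=nd.get("token_index"),
        )
        for nd in d["nodes"]
    )
    return SentenceGraph(
        nodes=nodes,
        edges=frozenset((u, v) for u, v in d["edges"]),
        edge_weight=d.get("edge_weight", 1.0),
        drug1_ids=tuple(d.get("drug1_ids", ())),
        drug2_ids=tuple(d.get("drug2_ids", ())),
        provenance=d.get("provenance", {}),
    )


def write_graphs_jsonl(graphs: Sequence[SentenceGraph], path) -> None:
    """One JSON document per line, one line per graph."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps(_graph_to_dict(g), sort_keys=True) + "\n")


def read_graphs_jsonl(path) -> list[SentenceGraph]:
    graphs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                graphs.append(_graph_from_dict(json.loads(line)))
    return graphs
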