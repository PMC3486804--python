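"""The hash subgraph pairwise (HSP) kernel.

Each graph is mapped, per hierarchy level k, into a sparse feature vector
indexed by ordered pairs of hash labels: entry (a, b) accumulates the total
discounted walk weight W_ij over node pairs with level-k labels a and b,
where

    W = (I - gamma * A)^{-1} = sum_{n >= 0} gamma^n A^n

is the Neumann walk matrix (convergent while gamma * spectral_radius(A) < 1).
The n = 0 identity term contributes the diagonal, i.e. plain single-subgraph
(bag-of-labels) features.  The kernel between two graphs is

    K(g1, g2) = sum_{k=0}^{R} beta^k * <phi_k(g1), phi_k(g2)>

with the inner product summing products of matching (a, b) entries — an
explicit feature-space inner product, hence positive semidefinite.  With
component tagging, labels are disambiguated per component so dependency and
linear subgraph pairs never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DivergenceError, NumericalError
from .graph_model import KernelConfig, SentenceGraph, adjacency
from .hashing import HashLabeling, LabelVocabulary, hierarchical_labels

__all__ = [
    "WalkMatrix",
    "walk_matrix",
    "feature_map",
    "graph_features",
    "hsp_kernel",
    "gram_matrix",
    "HSPKernel",
]

FeatureKey = tuple
FeatureMap = dict


@dataclass
class WalkMatrix:
    """Neumann walk-weight matrix over a fixed node ordering."""

    matrix: np.ndarray
    order: list[int]
    gamma: float
    spectral_radius: float


@dataclass
class GraphFeatures:
    """Per-level sparse subgraph-pair feature maps of one graph, plus its self-kernel."""

    levels: list[FeatureMap]
    self_kernel: float


def walk_matrix(g: SentenceGraph, config: KernelConfig) -> WalkMatrix:
    """W = (I - gamma A)^{-1}, the discounted all-lengths walk count matrix."""
    A, order = adjacency(g, symmetrize=config.symmetrize_walks)
    if A.size:
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    else:
        rho = 0.0
    if config.gamma * rho >= 1.0:
        raise DivergenceError(radius=rho, gamma=config.gamma)
    M = np.eye(len(order)) - config.gamma * A
    try:
        W = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"near-singular walk-matrix inversion: {exc}") from exc
    return WalkMatrix(matrix=W, order=order, gamma=config.gamma, spectral_radius=rho)


def feature_map(
    level_labels: Mapping[int, int],
    walk: WalkMatrix,
    components: Mapping[int, str] | None = None,
    tag_components: bool = True,
) -> FeatureMap:
    """Subgraph-pair features for one hierarchy level.

    Entry (a, b) sums W_ij over all ordered node pairs (i, j) — the diagonal
    included — whose labels are a and b.  With ``tag_components`` each label
    is keyed together with its node's component so features from different
    components never merge.  Zero-weight entries are dropped.
    """
    keys = []
    for nid in walk.order:
        label = level_labels[nid]
        if tag_components and components is not None:
            keys.append((components[nid], label))
        else:
            keys.append(label)
    W = walk.matrix
    fm: FeatureMap = {}
    n = len(keys)
    for i in range(n):
        for j in range(n):
            wij = W[i, j]
            if wij == 0.0:
                continue
            key = (keys[i], keys[j])
            fm[key] = fm.get(key, 0.0) + wij
    return {k: v for k, v in fm.items() if v != 0.0}


def _inner(fm1: FeatureMap, fm2: FeatureMap) -> float:
    if len(fm2) < len(fm1):
        fm1, fm2 = fm2, fm1
    return sum(v * fm2[k] for k, v in fm1.items() if k in fm2)


def _unnormalized(levels1: list[FeatureMap], levels2: list[FeatureMap], beta: float) -> float:
    return sum(beta**k * _inner(f1, f2) for k, (f1, f2) in enumerate(zip(levels1, levels2)))


def graph_features(g: SentenceGraph, vocab: LabelVocabulary, config: KernelConfig) -> GraphFeatures:
    """All per-level feature maps of ``g``; the walk matrix is computed once."""
    walk = walk_matrix(g, config)
    labeling: HashLabeling = hierarchical_labels(g, vocab, config)
    components = {n.node_id: n.component.value for n in g.nodes}
    levels = [
        feature_map(labeling.levels[k], walk, components, config.tag_components)
        for k in range(config.R + 1)
    ]
    return GraphFeatures(levels=levels, self_kernel=_unnormalized(levels, levels, config.beta))


def hsp_kernel(
    g1: SentenceGraph, g2: SentenceGraph, vocab: LabelVocabulary, config: KernelConfig
) -> float:
    """Kernel value between two graphs under a shared vocabulary."""
    f1 = graph_features(g1, vocab, config)
    f2 = graph_features(g2, vocab, config)
    return _pair_value(f1, f2, config)


def _pair_value(f1: GraphFeatures, f2: GraphFeatures, config: KernelConfig) -> float:
    k = _unnormalized(f1.levels, f2.levels, config.beta)
    if not config.normalize:
        return k
    denom = np.sqrt(f1.self_kernel * f2.self_kernel)
    return k / denom if denom > 0 else 0.0


def gram_matrix(
    graphs: Sequence[SentenceGraph], vocab: LabelVocabulary, config: KernelConfig
) -> np.ndarray:
    """Symmetric kernel matrix; exactly one feature extraction per graph."""
    feats = []
    for idx, g in enumerate(graphs):
        try:
            feats.append(graph_features(g, vocab, config))
        except Exception as exc:
            exc.add_note(f"while extracting features for graph {idx}")
            raise
    n = len(graphs)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = _pair_value(feats[i], feats[j], config)
    return K


def cross_gram(
    test_feats: Sequence[GraphFeatures], train_feats: Sequence[GraphFeatures], config: KernelConfig
) -> np.ndarray:
    K = np.zeros((len(test_feats), len(train_feats)))
    for i, fi in enumerate(test_feats):
        for j, fj in enumerate(train_feats):
            K[i, j] = _pair_value(fi, fj, config)
    return K


class HSPKernel(BaseEstimator, TransformerMixin):
    """Precomputed-kernel transformer over sentence graphs.

    ``fit`` learns the label vocabulary from the training graphs and caches
    their feature maps; ``transform`` returns the kernel matrix between its
    argument and the training graphs (so ``fit_transform(X)`` is the square
    training Gram matrix, directly consumable by a precomputed-kernel SVM).
    Labels unseen at ``fit`` time map to the reserved unknown code.

    Parameters mirror :class:`~hspkernel.graph_model.KernelConfig`.
    """

    def __init__(
        self,
        D: int = 24,
        R: int = 2,
        beta: float = 0.6,
        gamma: float = 0.25,
        w: float = 1.0,
        rot_center: int = 1,
        rot_in: int = 2,
        rot_out: int = 3,
        normalize: bool = True,
        symmetrize_walks: bool = True,
        tag_components: bool = True,
    ):
        self.D = D
        self.R = R
        self.beta = beta
        self.gamma = gamma
        self.w = w
        self.rot_center = rot_center
        self.rot_in = rot_in
        self.rot_out = rot_out
        self.normalize = normalize
        self.symmetrize_walks = symmetrize_walks
        self.tag_components = tag_components

    def _config(self) -> KernelConfig:
        return KernelConfig(
            D=self.D,
            R=self.R,
            beta=self.beta,
            gamma=self.gamma,
            w=self.w,
            rot_center=self.rot_center,
            rot_in=self.rot_in,
            rot_out=self.rot_out,
            normalize=self.normalize,
            symmetrize_walks=self.symmetrize_walks,
            tag_components=self.tag_components,
        )

    def fit(self, X: Sequence[SentenceGraph], y=None) -> "HSPKernel":
        config = self._config()
        self.vocabulary_ = LabelVocabulary(D=self.D)
        self.train_features_ = [graph_features(g, self.vocabulary_, config) for g in X]
        self.n_features_in_ = len(X)
        self.vocabulary_.frozen = True
        return self

    def transform(self, X: Sequence[SentenceGraph]) -> np.ndarray:
        if not hasattr(self, "train_features_"):
            raise NumericalError("HSPKernel.transform called before fit")
        config = self._config()
        feats = [graph_features(g, self.vocabulary_, config) for g in X]
        return cross_gram(feats, self.train_features_, config)

    def fit_transform(self, X: Sequence[SentenceGraph], y=None) -> np.ndarray:
        self.fit(X)
        config = self._config()
        n = len(self.train_features_)
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = _pair_value(
                    self.train_features_[i], self.train_features_[j], config
                )
        return K
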