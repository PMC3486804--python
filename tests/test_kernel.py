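import dataclasses
from collections import Counter

import numpy as np
import pytest

from hspkernel.errors import DivergenceError
from hspkernel.graph_model import KernelConfig, SentenceGraph, adjacency
from hspkernel.hashing import LabelVocabulary, hierarchical_labels
from hspkernel.kernel import (
    HSPKernel,
    feature_map,
    graph_features,
    gram_matrix,
    hsp_kernel,
    walk_matrix,
)
from hspkernel.synthetic import random_graph

from conftest import make_graph, permute_graph


def truncated_series(A: np.ndarray, gamma: float, terms: int = 51) -> np.ndarray:
    """Independent oracle: explicit partial sum of the walk series."""
    W = np.zeros_like(A)
    P = np.eye(len(A))
    for n in range(terms):
        W += gamma**n * P
        P = P @ A
    return W


def dense_kernel(g1, g2, vocab, config) -> float:
    """Independent oracle: brute-force enumeration over all ordered node
    pairs and hierarchy levels, no sparse feature maps."""
    total = 0.0
    parts = []
    for g in (g1, g2):
        W = walk_matrix(g, config)
        lab = hierarchical_labels(g, vocab, config)
        comp = {n.node_id: n.component.value for n in g.nodes}
        parts.append((W, lab, comp))
    (W1, lab1, comp1), (W2, lab2, comp2) = parts
    for k in range(config.R + 1):
        level = 0.0
        for a, i in enumerate(W1.order):
            for b, j in enumerate(W1.order):
                for c, p in enumerate(W2.order):
                    for d, q in enumerate(W2.order):
                        same_ip = lab1.levels[k][i] == lab2.levels[k][p]
                        same_jq = lab1.levels[k][j] == lab2.levels[k][q]
                        if config.tag_components:
                            same_ip = same_ip and comp1[i] == comp2[p]
                            same_jq = same_jq and comp1[j] == comp2[q]
                        if same_ip and same_jq:
                            level += W1.matrix[a, b] * W2.matrix[c, d]
        total += config.beta**k * level
    if config.normalize:
        d1 = dense_kernel(g1, g1, vocab, dataclasses.replace(config, normalize=False))
        d2 = dense_kernel(g2, g2, vocab, dataclasses.replace(config, normalize=False))
        return total / np.sqrt(d1 * d2)
    return total


def safe_gamma(g, symmetrize=True, target=0.4):
    A, _ = adjacency(g, symmetrize=symmetrize)
    rho = max(np.max(np.abs(np.linalg.eigvals(A))), 1e-9) if A.size else 1.0
    return min(target / rho, 0.4)


class TestWalkMatrix:
    def test_edgeless_graph_gives_identity(self):
        g = make_graph(["a", "b", "c"])
        W = walk_matrix(g, KernelConfig())
        assert np.array_equal(W.matrix, np.eye(3))

    def test_single_symmetric_edge_closed_form(self):
        g = make_graph(["a", "b"])
        g = dataclasses.replace(g, edges=frozenset({(0, 1)}))
        W = walk_matrix(g, KernelConfig(gamma=0.5, symmetrize_walks=True))
        expected = np.array([[4 / 3, 2 / 3], [2 / 3, 4 / 3]])
        assert np.allclose(W.matrix, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_truncated_series(self, seed):
        g = random_graph(seed=seed, n_nodes=7, edge_prob=0.25)
        gamma = safe_gamma(g)
        cfg = KernelConfig(gamma=gamma)
        W = walk_matrix(g, cfg)
        A, _ = adjacency(g, symmetrize=True)
        assert np.max(np.abs(W.matrix - truncated_series(A, gamma))) < 1e-10

    def test_divergence_raises_with_radius(self):
        g = make_graph(["a", "b"])
        g = dataclasses.replace(g, edges=frozenset({(0, 1)}))
        with pytest.raises(DivergenceError) as err:
            walk_matrix(g, KernelConfig(gamma=1.5))
        assert err.value.radius == pytest.approx(1.0)

    def test_diagonal_at_least_one(self):
        for seed in range(5):
            g = random_graph(seed=seed, n_nodes=6, edge_prob=0.2)
            W = walk_matrix(g, KernelConfig(gamma=safe_gamma(g)))
            assert np.all(np.diag(W.matrix) >= 1 - 1e-12)


class TestFeatureMap:
    def test_edgeless_distinct_labels(self):
        g = make_graph(["a", "b"])
        vocab = LabelVocabulary()
        cfg = KernelConfig()
        W = walk_matrix(g, cfg)
        labels = hierarchical_labels(g, vocab, cfg).levels[0]
        fm = feature_map(labels, W, tag_components=False)
        a, b = vocab.code("a"), vocab.code("b")
        assert fm == {(a, a): 1.0, (b, b): 1.0}

    def test_edgeless_repeated_label_accumulates(self):
        g = make_graph(["a", "a"])
        vocab = LabelVocabulary()
        cfg = KernelConfig()
        W = walk_matrix(g, cfg)
        labels = hierarchical_labels(g, vocab, cfg).levels[0]
        fm = feature_map(labels, W, tag_components=False)
        a = vocab.code("a")
        assert fm == {(a, a): 2.0}

    def test_two_node_walk_weights(self):
        g = make_graph(["a", "b"])
        g = dataclasses.replace(g, edges=frozenset({(0, 1)}))
        vocab = LabelVocabulary()
        cfg = KernelConfig(gamma=0.5, symmetrize_walks=True)
        W = walk_matrix(g, cfg)
        labels = hierarchical_labels(g, vocab, cfg).levels[0]
        fm = feature_map(labels, W, tag_components=False)
        a, b = vocab.code("a"), vocab.code("b")
        assert fm[(a, a)] == pytest.approx(4 / 3)
        assert fm[(b, b)] == pytest.approx(4 / 3)
        assert fm[(a, b)] == pytest.approx(2 / 3)
        assert fm[(b, a)] == pytest.approx(2 / 3)


class TestHSPKernel:
    def test_self_kernel_positive(self):
        g = make_graph(["a", "b"], relations=[(0, 1, "r")])
        vocab = LabelVocabulary()
        assert hsp_kernel(g, g, vocab, KernelConfig(normalize=False)) > 0

    def test_disjoint_label_sets_give_zero(self):
        g1 = make_graph(["a", "b"])
        g2 = make_graph(["c", "d"])
        vocab = LabelVocabulary()
        assert hsp_kernel(g1, g2, vocab, KernelConfig(normalize=False)) == 0.0

    def test_bag_of_labels_closed_form(self):
        # gamma=0, R=0, beta=1: K = sum_a count1(a) * count2(a)
        cfg = KernelConfig(gamma=0.0, R=0, beta=1.0, normalize=False, tag_components=False)
        for seed in range(20):
            g1 = random_graph(seed=seed, n_nodes=6, edge_prob=0.3, alphabet_size=3)
            g2 = random_graph(seed=seed + 500, n_nodes=5, edge_prob=0.3, alphabet_size=3)
            vocab = LabelVocabulary()
            k = hsp_kernel(g1, g2, vocab, cfg)
            c1 = Counter(n.label for n in g1.nodes)
            c2 = Counter(n.label for n in g2.nodes)
            expected = sum(c1[lab] * c2[lab] for lab in c1)
            assert k == pytest.approx(expected)

    def test_symmetry_exact(self):
        vocab = LabelVocabulary()
        cfg = KernelConfig(gamma=0.1)
        g1 = random_graph(seed=1, n_nodes=6, edge_prob=0.25)
        g2 = random_graph(seed=2, n_nodes=7, edge_prob=0.25)
        assert hsp_kernel(g1, g2, vocab, cfg) == hsp_kernel(g2, g1, vocab, cfg)

    def test_isomorphism_invariance(self):
        vocab = LabelVocabulary()
        cfg = KernelConfig(gamma=0.1)
        g1 = random_graph(seed=3, n_nodes=6, edge_prob=0.3)
        g2 = random_graph(seed=4, n_nodes=6, edge_prob=0.3)
        g2p, _ = permute_graph(g2, seed=42)
        assert hsp_kernel(g1, g2, vocab, cfg) == pytest.approx(
            hsp_kernel(g1, g2p, vocab, cfg), abs=1e-12
        )

    def test_monotone_in_beta_and_r(self):
        vocab = LabelVocabulary()
        g1 = random_graph(seed=5, n_nodes=6, edge_prob=0.3, alphabet_size=2)
        g2 = random_graph(seed=6, n_nodes=6, edge_prob=0.3, alphabet_size=2)
        base = dict(gamma=0.05, normalize=False)
        ks_beta = [
            hsp_kernel(g1, g2, vocab, KernelConfig(beta=b, **base)) for b in (0.2, 0.6, 1.0)
        ]
        # overlaps are sums of nonnegative products here, so K grows with beta
        assert ks_beta == sorted(ks_beta)
        ks_r = [hsp_kernel(g1, g2, vocab, KernelConfig(R=r, **base)) for r in (0, 1, 2)]
        assert ks_r == sorted(ks_r)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        g1 = random_graph(seed=seed * 2 + 1, n_nodes=n1, edge_prob=0.3, alphabet_size=3)
        g2 = random_graph(seed=seed * 2 + 2, n_nodes=n2, edge_prob=0.3, alphabet_size=3)
        gamma = min(safe_gamma(g1), safe_gamma(g2))
        cfg = KernelConfig(gamma=gamma, R=2)
        vocab = LabelVocabulary()
        assert hsp_kernel(g1, g2, vocab, cfg) == pytest.approx(
            dense_kernel(g1, g2, vocab, cfg), abs=1e-9
        )

    def test_normalized_self_kernel_is_one(self):
        vocab = LabelVocabulary()
        cfg = KernelConfig(gamma=0.1, normalize=True)
        for seed in range(5):
            g = random_graph(seed=seed, n_nodes=6, edge_prob=0.25)
            assert hsp_kernel(g, g, vocab, cfg) == pytest.approx(1.0)


class TestGram:
    def graphs(self, n=10):
        return [random_graph(seed=s, n_nodes=6, edge_prob=0.2) for s in range(n)]

    def test_single_graph(self):
        g = self.graphs(1)
        K = gram_matrix(g, LabelVocabulary(), KernelConfig(gamma=0.1))
        assert K.shape == (1, 1) and K[0, 0] == pytest.approx(1.0)

    def test_duplicated_graphs_give_equal_rows(self):
        g = self.graphs(1)[0]
        K = gram_matrix([g, g, g], LabelVocabulary(), KernelConfig(gamma=0.1))
        assert np.allclose(K, 1.0)
        assert np.linalg.matrix_rank(K) == 1

    @pytest.mark.parametrize("normalize", [True, False])
    def test_positive_semidefinite(self, normalize):
        graphs = [random_graph(seed=s, n_nodes=7, edge_prob=0.15) for s in range(30)]
        cfg = KernelConfig(gamma=0.1, normalize=normalize)
        K = gram_matrix(graphs, LabelVocabulary(), cfg)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_feature_extraction_once_per_graph(self, monkeypatch):
        import hspkernel.kernel as kmod

        calls = []
        original = kmod.graph_features

        def counting(g, vocab, config):
            calls.append(id(g))
            return original(g, vocab, config)

        monkeypatch.setattr(kmod, "graph_features", counting)
        graphs = self.graphs(6)
        kmod.gram_matrix(graphs, LabelVocabulary(), KernelConfig(gamma=0.1))
        assert len(calls) == 6


class TestEstimator:
    def test_fit_transform_equals_gram(self):
        graphs = [random_graph(seed=s, n_nodes=6, edge_prob=0.2) for s in range(8)]
        est = HSPKernel(gamma=0.1)
        K1 = est.fit_transform(graphs)
        K2 = gram_matrix(graphs, LabelVocabulary(), KernelConfig(gamma=0.1))
        assert np.allclose(K1, K2)

    def test_transform_unseen_labels_use_unk(self):
        train = [make_graph(["a", "b"], relations=[(0, 1, "r")])]
        test = [make_graph(["zzz", "qqq"], relations=[(0, 1, "s")])]
        est = HSPKernel(gamma=0.1).fit(train)
        K = est.transform(test)
        assert K.shape == (1, 1)
        assert est.vocabulary_.frozen

    def test_get_set_params_round_trip(self):
        est = HSPKernel(beta=0.8)
        params = est.get_params()
        assert params["beta"] == 0.8
        est.set_params(R=3)
        assert est.R == 3
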