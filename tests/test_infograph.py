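"""GIN encoding and the contrastive mutual-information objective."""

import math

import numpy as np
import pytest

from fragdta import (
    EncoderConfig,
    GINEncoder,
    ResidueFragment,
    build_fragment_graph,
    gin_forward,
    jsd_mi_loss,
    load_checkpoint,
    pretrain,
    save_checkpoint,
)
from fragdta.autograd import Tensor
from fragdta.graphs import MolecularGraph
from fragdta.infograph import batch_graphs
from fragdta.layers import Bilinear

from conftest import random_chain_graphs


def softplus_scalar(x: float) -> float:
    return math.log1p(math.exp(-abs(x))) + max(x, 0.0)


class TestGINForward:
    def test_single_node_graph_embedding_is_activated_node_embedding(
        self, target_encoder_small
    ):
        g = build_fragment_graph(ResidueFragment("A", "t", 0, 1))
        node_emb, graph_emb = gin_forward(g, target_encoder_small)
        assert node_emb.shape == (1, 8)
        assert np.allclose(graph_emb, np.maximum(node_emb[0], 0.0), atol=1e-7)

    def test_permutation_invariance(self, target_encoder_small, rng):
        for g in random_chain_graphs(20, 25, seed=5):
            _, emb = gin_forward(g, target_encoder_small)
            perm = rng.permutation(g.n_nodes)
            inv = np.argsort(perm)
            permuted = MolecularGraph(
                g.node_tokens[perm],
                np.sort(np.stack([inv[g.edges[:, 0]], inv[g.edges[:, 1]]], axis=1), axis=1),
                origin=g.origin,
            )
            _, emb_p = gin_forward(permuted, target_encoder_small)
            assert np.abs(emb - emb_p).max() < 1e-6

    def test_isomorphic_labeled_graphs_agree(self, target_encoder_small):
        # same labeled 4-node path written with two different node orderings
        a = MolecularGraph([3, 1, 4, 1], [[0, 1], [1, 2], [2, 3]], "target_fragment")
        b = MolecularGraph([1, 4, 1, 3], [[0, 1], [0, 3], [1, 2]], "target_fragment")
        _, ea = gin_forward(a, target_encoder_small)
        _, eb = gin_forward(b, target_encoder_small)
        assert np.abs(ea - eb).max() < 1e-6

    def test_empty_graph_rejected(self, target_encoder_small):
        g = MolecularGraph(np.zeros(0, dtype=np.int64), np.zeros((0, 2)), "drug")
        with pytest.raises(ValueError):
            gin_forward(g, target_encoder_small)


class TestJSDLoss:
    def test_zero_discriminator_gives_two_ln_two(
        self, target_encoder_small, fragment_graphs
    ):
        x, src, dst, gid = batch_graphs(fragment_graphs, 25)
        h, g = target_encoder_small.forward_batch(
            Tensor(x), src, dst, gid, len(fragment_graphs)
        )
        disc = Bilinear(8, 8, np.random.default_rng(0))
        disc.W.data[:] = 0.0
        loss = jsd_mi_loss(h, g, gid, disc)
        assert abs(loss.item() - 2 * math.log(2)) < 1e-6

    def test_matches_scalar_hand_evaluation(self):
        # two single-node "graphs" with fixed 2-d embeddings and a fixed
        # bilinear discriminator, evaluated independently in pure python
        H = np.array([[1.0, -0.5], [0.25, 2.0]], dtype=np.float32)
        G = np.array([[0.5, 1.0], [-1.0, 0.5]], dtype=np.float32)
        W = np.array([[0.3, -0.2], [0.1, 0.4]], dtype=np.float32)
        disc = Bilinear(2, 2, np.random.default_rng(0))
        disc.W.data = W.copy()
        loss = jsd_mi_loss(Tensor(H), Tensor(G), np.array([0, 1]), disc)

        scores = [[float(H[i] @ W @ G[j]) for j in range(2)] for i in range(2)]
        expected = 0.5 * (
            softplus_scalar(-scores[0][0]) + softplus_scalar(-scores[1][1])
        ) + 0.5 * (softplus_scalar(scores[0][1]) + softplus_scalar(scores[1][0]))
        assert abs(loss.item() - expected) < 1e-6

    def test_perfect_discrimination_drives_loss_to_zero(self):
        H = np.array([[1.0], [-1.0]], dtype=np.float32)
        G = np.array([[1.0], [-1.0]], dtype=np.float32)
        disc = Bilinear(1, 1, np.random.default_rng(0))
        disc.W.data = np.array([[30.0]], dtype=np.float32)  # T -> +/- 30
        loss = jsd_mi_loss(Tensor(H), Tensor(G), np.array([0, 1]), disc)
        assert loss.item() < 1e-6

    def test_single_graph_batch_rejected(self, target_encoder_small, fragment_graphs):
        x, src, dst, gid = batch_graphs(fragment_graphs[:1], 25)
        h, g = target_encoder_small.forward_batch(Tensor(x), src, dst, gid, 1)
        with pytest.raises(ValueError):
            jsd_mi_loss(h, g, gid, Bilinear(8, 8, np.random.default_rng(0)))


class TestPretrain:
    def test_seeded_determinism(self, fragment_graphs):
        cfg = EncoderConfig(n_layers=2, hidden_size=8)
        a = pretrain(fragment_graphs * 5, cfg, 25, epochs=3, batch_size=8, seed=42)
        b = pretrain(fragment_graphs * 5, cfg, 25, epochs=3, batch_size=8, seed=42)
        assert a.loss_history == b.loss_history
        for pa, pb in zip(a.encoder.params(), b.encoder.params()):
            assert np.array_equal(pa.data, pb.data)

    def test_loss_decreases_on_small_corpus(self):
        graphs = random_chain_graphs(24, 25, seed=9)
        cfg = EncoderConfig(n_layers=2, hidden_size=12)
        state = pretrain(graphs, cfg, 25, epochs=10, batch_size=12, seed=0)
        assert state.loss_history[-1] < state.loss_history[0]
        assert len(state.loss_history) == 10

    def test_corpus_of_one_rejected(self, fragment_graphs):
        with pytest.raises(ValueError):
            pretrain(fragment_graphs[:1], EncoderConfig(), 25)

    def test_checkpoint_roundtrip(self, fragment_graphs, tmp_path):
        cfg = EncoderConfig(n_layers=2, hidden_size=8)
        state = pretrain(fragment_graphs * 3, cfg, 25, epochs=2, batch_size=6, seed=5)
        path = tmp_path / "enc.ckpt"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        assert loaded.loss_history == state.loss_history
        g = fragment_graphs[0]
        _, a = gin_forward(g, state.encoder)
        _, b = gin_forward(g, loaded.encoder)
        assert np.array_equal(a, b)


class TestEncoderConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EncoderConfig(n_layers=0)
        with pytest.raises(ValueError):
            EncoderConfig(readout_layers="sum")

    def test_layer_concat_readout_dimension(self):
        cfg = EncoderConfig(n_layers=3, hidden_size=6, readout_layers="concat")
        enc = GINEncoder(cfg, 25, np.random.default_rng(0))
        assert enc.out_dim == 18
        g = build_fragment_graph(ResidueFragment("ACD", "t", 0, 3))
        _, emb = gin_forward(g, enc)
        assert emb.shape == (18,)
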