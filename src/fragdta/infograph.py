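"""Contrastive graph pretraining: GIN encoder + Jensen-Shannon MI objective.

A GIN encoder maps a tokenized molecular graph to per-node embeddings; the
graph embedding is an activation of the node-embedding mean.  Pretraining
maximizes Jensen-Shannon mutual information between node ("patch")
representations and graph representations: a bilinear discriminator scores
every (node, graph) pair in a minibatch, nodes paired with their own graph
are positives and nodes paired with every other graph in the batch are
negatives, and the loss is

    mean_pos softplus(-T)  +  mean_neg softplus(T)

which equals ``2 ln 2`` for an uninformative (identically zero) discriminator
and approaches 0 as the discriminator separates positives from negatives.

Two encoders are pretrained independently and never share parameters: one on
drug atom graphs, one on target residue-fragment graphs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat, scatter_sum, softplus
from .graphs import MolecularGraph
from .layers import Adam, Bilinear, GINLayer, Module, get_activation


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one GIN encoder.

    ``hidden_size`` is both the per-layer width and the embedding dimension.
    ``readout_layers`` selects whether the graph embedding summarizes the
    final layer only ("final") or the concatenation of all layer readouts
    ("concat", in which case the graph embedding has n_layers * hidden_size
    entries).
    """

    n_layers: int = 5
    hidden_size: int = 60
    readout: str = "mean"
    activation: str = "relu"
    epsilon: float = 0.0
    readout_layers: str = "final"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.readout != "mean":
            raise ValueError("only mean readout is supported")
        if self.readout_layers not in ("final", "concat"):
            raise ValueError("readout_layers must be 'final' or 'concat'")


class GINEncoder(Module):
    """Stack of GIN layers over one-hot token features, with mean readout."""

    def __init__(self, cfg: EncoderConfig, vocab_size: int, rng: np.random.Generator):
        self.cfg = cfg
        self.vocab_size = int(vocab_size)
        d = cfg.hidden_size
        sizes = [vocab_size] + [d] * cfg.n_layers
        self.layers = [
            GINLayer(sizes[i], sizes[i + 1], rng, epsilon=cfg.epsilon)
            for i in range(cfg.n_layers)
        ]
        self.act = get_activation(cfg.activation)

    @property
    def out_dim(self) -> int:
        d = self.cfg.hidden_size
        return d * self.cfg.n_layers if self.cfg.readout_layers == "concat" else d

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward_batch(
        self,
        x: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        graph_id: np.ndarray,
        n_graphs: int,
    ) -> tuple[Tensor, Tensor]:
        """Encode a batch of graphs given stacked one-hot node features.

        Returns (node embeddings (N, d), graph embeddings (n_graphs, d_out)).
        """
        counts = np.bincount(graph_id, minlength=n_graphs).astype(np.float32)
        inv = Tensor((1.0 / np.maximum(counts, 1.0))[:, None])
        h = x
        per_layer = []
        for i, layer in enumerate(self.layers):
            h = layer(h, src, dst)
            if i < len(self.layers) - 1:
                h = self.act(h)
            per_layer.append(h)
        if self.cfg.readout_layers == "concat":
            node_out = concat(per_layer, axis=1)
        else:
            node_out = h
        graph_mean = scatter_sum(node_out, graph_id, n_graphs) * inv
        graph_emb = self.act(graph_mean)
        return h, graph_emb


def batch_graphs(
    graphs: list[MolecularGraph], vocab_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack graphs into (one-hot X, src, dst, graph_id) arrays with node
    indices offset per graph."""
    xs, srcs, dsts, gids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.one_hot(vocab_size))
        s, d = g.directed_edges()
        srcs.append(s + offset)
        dsts.append(d + offset)
        gids.append(np.full(g.n_nodes, gi, dtype=np.int64))
        offset += g.n_nodes
    return (
        np.concatenate(xs, axis=0),
        np.concatenate(srcs),
        np.concatenate(dsts),
        np.concatenate(gids),
    )


def gin_forward(
    graph: MolecularGraph, encoder: GINEncoder
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a single graph; returns (node embeddings, graph embedding) as
    plain arrays."""
    if graph.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    x, src, dst, gid = batch_graphs([graph], encoder.vocab_size)
    h, g = encoder.forward_batch(Tensor(x), src, dst, gid, 1)
    return h.data, g.data[0]


def jsd_mi_loss(
    node_emb: Tensor,
    graph_emb: Tensor,
    graph_id: np.ndarray,
    discriminator: Bilinear,
) -> Tensor:
    """Jensen-Shannon MI estimator loss over a batch of >= 2 graphs.

    ``node_emb`` is (N, d) over all nodes of the batch, ``graph_emb`` is
    (B, d_g), ``graph_id`` assigns each node to its graph.
    """
    n_graphs = graph_emb.shape[0]
    if n_graphs < 2:
        raise ValueError("JSD MI loss needs at least 2 graphs for negatives")
    n_nodes = node_emb.shape[0]
    scores = discriminator(node_emb, graph_emb)          # (N, B)
    pos_mask = np.zeros((n_nodes, n_graphs), dtype=np.float32)
    pos_mask[np.arange(n_nodes), graph_id] = 1.0
    neg_mask = 1.0 - pos_mask
    pos_term = (softplus(-scores) * Tensor(pos_mask)).sum() * (1.0 / n_nodes)
    neg_term = (softplus(scores) * Tensor(neg_mask)).sum() * (
        1.0 / (n_nodes * (n_graphs - 1))
    )
    return pos_term + neg_term


@dataclass
class PretrainState:
    """Pretrained encoder (and discriminator) plus the per-epoch loss trace."""

    encoder: GINEncoder
    discriminator: Bilinear
    epoch: int
    loss_history: list[float]
    config: EncoderConfig


def pretrain(
    graphs: list[MolecularGraph],
    cfg: EncoderConfig,
    vocab_size: int,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> PretrainState:
    """InfoGraph pretraining of a GIN encoder on an unlabeled graph corpus.

    Fully seeded: parameter init, batch shuffling and therefore the loss
    history are reproducible bit-for-bit from ``seed``.
    """
    if len(graphs) < 2:
        raise ValueError("pretraining needs at least 2 graphs")
    rng = np.random.default_rng(seed)
    encoder = GINEncoder(cfg, vocab_size, rng)
    disc = Bilinear(cfg.hidden_size, encoder.out_dim, rng)
    opt = Adam(encoder.params() + disc.params(), lr=lr)
    history: list[float] = []
    n = len(graphs)
    for _ in range(epochs):
        order = rng.permutation(n)
        batches = [order[i:i + batch_size] for i in range(0, n, batch_size)]
        # fold a trailing single-graph batch into its predecessor: the loss
        # needs in-batch negatives
        if len(batches) > 1 and len(batches[-1]) == 1:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches = batches[:-1]
        epoch_losses = []
        for idx in batches:
            batch = [graphs[i] for i in idx]
            x, src, dst, gid = batch_graphs(batch, vocab_size)
            h, g = encoder.forward_batch(Tensor(x), src, dst, gid, len(batch))
            loss = jsd_mi_loss(h, g, gid, disc)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return PretrainState(encoder, disc, epochs, history, cfg)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(state: PretrainState, path) -> None:
    """Encoder + discriminator parameters with a config snapshot (.npz)."""
    path = Path(path)
    meta = {
        "format": "fragdta-encoder-v1",
        "config": asdict(state.config),
        "vocab_size": state.encoder.vocab_size,
        "epoch": state.epoch,
        "loss_history": state.loss_history,
    }
    arrays = {f"enc_{i}": a for i, a in enumerate(state.encoder.state_arrays())}
    arrays |= {f"disc_{i}": a for i, a in enumerate(state.discriminator.state_arrays())}
    with open(path, "wb") as fh:  # write via handle so numpy keeps the exact name
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PretrainState:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "fragdta-encoder-v1":
            raise ValueError(f"{path}: not a fragdta encoder checkpoint")
        cfg = EncoderConfig(**meta["config"])
        rng = np.random.default_rng(0)
        encoder = GINEncoder(cfg, meta["vocab_size"], rng)
        disc = Bilinear(cfg.hidden_size, encoder.out_dim, rng)
        enc_arrays = [data[f"enc_{i}"] for i in range(len(encoder.params()))]
        disc_arrays = [data[f"disc_{i}"] for i in range(len(disc.params()))]
    encoder.load_arrays(enc_arrays)
    disc.load_arrays(disc_arrays)
    return PretrainState(encoder, disc, meta["epoch"], list(meta["loss_history"]), cfg)
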