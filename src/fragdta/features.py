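"""Fixed-size low-level feature matrices from pretrained encoders.

Targets: the sequence is cut into exactly K overlapping windows; each real
window's fragment graph is encoded to one graph-embedding row, padding
windows contribute all-zero rows -> a K x d matrix per target.

Drugs: the molecule's per-atom node embeddings, in canonical atom order,
zero-padded or truncated to a fixed row count (64 by default) -> a 64 x d
matrix per drug.  Fixing both row counts makes the drug and target feature
tensors the same shape, so the downstream CNNs see a regular 2D "image".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .graphs import build_drug_graph, build_fragment_graph
from .infograph import GINEncoder, batch_graphs
from .segmentation import WindowConfig, segment_overlapping

logger = logging.getLogger(__name__)

DEFAULT_DRUG_ROWS = 64


@dataclass
class LowLevelTargetFeatures:
    matrix: np.ndarray          # (K, d) float32
    parent_id: str
    padding_mask: np.ndarray    # (K,) bool, True where the row is padding

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LowLevelDrugFeatures:
    matrix: np.ndarray          # (rows, d) float32
    drug_id: str
    n_real: int                 # rows < n_real hold atom embeddings

    @property
    def rows(self) -> int:
        return self.matrix.shape[0]


def extract_target_features(
    sequence: str,
    encoder: GINEncoder,
    cfg: WindowConfig,
    parent_id: str = "",
) -> LowLevelTargetFeatures:
    """K overlapping windows -> fragment graphs -> one graph embedding per
    window, stacked in window order; padding windows are zero rows."""
    if not sequence:
        raise ValueError("cannot extract features from an empty sequence")
    frag_set = segment_overlapping(sequence, cfg, parent_id=parent_id)
    real = [(i, f) for i, f in enumerate(frag_set) if not f.padding]
    graphs = [build_fragment_graph(f) for _, f in real]
    x, src, dst, gid = batch_graphs(graphs, encoder.vocab_size)
    _, g = encoder.forward_batch(Tensor(x), src, dst, gid, len(graphs))
    out = np.zeros((cfg.k, encoder.out_dim), dtype=np.float32)
    mask = np.ones(cfg.k, dtype=bool)
    for row, (i, _) in enumerate(real):
        out[i] = g.data[row]
        mask[i] = False
    return LowLevelTargetFeatures(out, parent_id, mask)


def extract_drug_features(
    smiles: str,
    encoder: GINEncoder,
    drug_id: str = "",
    rows: int = DEFAULT_DRUG_ROWS,
) -> LowLevelDrugFeatures:
    """Per-atom node embeddings in canonical atom order, zero-padded or
    truncated to a fixed number of rows (truncation keeps the first atoms in
    canonical order)."""
    graph = build_drug_graph(smiles)
    x, src, dst, gid = batch_graphs([graph], encoder.vocab_size)
    h, _ = encoder.forward_batch(Tensor(x), src, dst, gid, 1)
    node_emb = h.data
    n = graph.n_nodes
    if n > rows:
        logger.debug("drug %s: %d atoms truncated to %d rows", drug_id or smiles, n, rows)
        node_emb = node_emb[:rows]
        n = rows
    out = np.zeros((rows, node_emb.shape[1]), dtype=np.float32)
    out[:n] = node_emb
    return LowLevelDrugFeatures(out, drug_id, n)
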