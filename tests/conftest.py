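import numpy as np
import pytest

from fragdta import EncoderConfig, GINEncoder, ResidueFragment, build_fragment_graph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_encoder_cfg():
    return EncoderConfig(n_layers=2, hidden_size=8)


@pytest.fixture
def target_encoder_small(small_encoder_cfg):
    return GINEncoder(small_encoder_cfg, 25, np.random.default_rng(1))


@pytest.fixture
def fragment_graphs():
    seqs = ["ACDEFGHIK", "MKVWYQNP", "GGSTAL", "WWCCHH"]
    return [
        build_fragment_graph(ResidueFragment(s, f"t{i}", 0, len(s)))
        for i, s in enumerate(seqs)
    ]


def random_chain_graphs(n_graphs: int, vocab_size: int, seed: int):
    """Random residue-chain-like graphs plus a few random extra edges."""
    from fragdta.graphs import MolecularGraph

    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(3, 20))
        tokens = rng.integers(0, vocab_size, size=n)
        edges = [(i, i + 1) for i in range(n - 1)]
        for _ in range(int(rng.integers(0, 3))):
            u, v = sorted(rng.choice(n, size=2, replace=False))
            if (u, v) not in edges:
                edges.append((u, v))
        graphs.append(
            MolecularGraph(tokens, np.array(sorted(edges)), origin="target_fragment")
        )
    return graphs
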