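"""Graph construction for drugs (SMILES, via RDKit) and target fragments.

Drugs become heavy-atom graphs in canonical SMILES atom order; target
fragments become residue-level chain graphs by default (one node per amino
acid, edges between sequence neighbours).  An atom-level peptide graph built
by RDKit from the fragment sequence is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .vocab import TokenVocabulary, atom_token, drug_vocabulary, target_vocabulary

RDLogger.DisableLog("rdApp.*")  # surface parse failures as exceptions, not stderr spam

logger = logging.getLogger(__name__)


class InvalidSMILESError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"could not parse SMILES: {smiles!r}")


@dataclass(frozen=True)
class ResidueFragment:
    """A window cut from a target sequence; 0-based half-open offsets.

    Padding fragments (empty sequence, ``padding=True``) exist only to pad an
    overlapping fragment set out to exactly K windows.
    """

    sequence: str
    parent_id: str
    start: int
    end: int
    padding: bool = False

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("end - start must equal sequence length")
        if not self.padding and len(self.sequence) < 1:
            raise ValueError("non-padding fragment must be nonempty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MolecularGraph:
    """Tokenized undirected graph for a drug or a residue fragment.

    ``edges`` stores each undirected edge once as (u, v) with u < v;
    :meth:`directed_edges` expands to both orientations for message passing.
    """

    node_tokens: np.ndarray          # (n,) int token indices
    edges: np.ndarray                # (m, 2) int, u < v, no self-loops
    origin: str                      # "drug" | "target_fragment"
    source_id: str = ""

    def __post_init__(self):
        self.node_tokens = np.asarray(self.node_tokens, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = self.n_nodes
        if self.edges.size:
            if self.edges.max() >= n or self.edges.min() < 0:
                raise ValueError("edge endpoint out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return int(self.node_tokens.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) with every undirected edge in both orientations."""
        if not self.edges.size:
            empty = np.zeros(0, dtype=np.int64)
            return empty, empty
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return src, dst

    def one_hot(self, vocab_size: int) -> np.ndarray:
        x = np.zeros((self.n_nodes, vocab_size), dtype=np.float32)
        x[np.arange(self.n_nodes), self.node_tokens] = 1.0
        return x


def _canonical_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(smiles)
    # Round-trip through canonical SMILES so atom order is the canonical
    # output order, independent of how the input was spelled.
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical output always reparses
        raise InvalidSMILESError(canonical)
    return mol


def build_drug_graph(smiles: str, vocab: TokenVocabulary | None = None) -> MolecularGraph:
    """Heavy-atom graph of a molecule: one node per atom (hydrogens implicit),
    one undirected edge per bond, nodes in canonical SMILES atom order."""
    vocab = vocab or drug_vocabulary()
    mol = _canonical_mol(smiles)
    tokens = np.array(
        [vocab.encode(atom_token(a)) for a in mol.GetAtoms()], dtype=np.int64
    )
    edges = np.array(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        ),
        dtype=np.int64,
    ).reshape(-1, 2)
    return MolecularGraph(tokens, edges, origin="drug", source_id=smiles)


def build_fragment_graph(
    fragment: ResidueFragment, vocab: TokenVocabulary | None = None
) -> MolecularGraph:
    """Residue-level chain graph: node per residue, edge per peptide adjacency."""
    if len(fragment) == 0:
        raise ValueError("cannot build a graph from an empty fragment")
    vocab = vocab or target_vocabulary()
    tokens = np.array([vocab.encode(c) for c in fragment.sequence], dtype=np.int64)
    n = len(tokens)
    edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    return MolecularGraph(
        tokens, edges, origin="target_fragment",
        source_id=f"{fragment.parent_id}[{fragment.start}:{fragment.end}]",
    )


def build_peptide_graph(
    fragment: ResidueFragment, vocab: TokenVocabulary | None = None
) -> MolecularGraph:
    """Atom-level alternative: build the fragment as a peptide molecule with
    RDKit and tokenize its atoms over the drug vocabulary."""
    if len(fragment) == 0:
        raise ValueError("cannot build a graph from an empty fragment")
    mol = Chem.MolFromSequence(fragment.sequence)
    if mol is None:
        raise ValueError(f"RDKit cannot build a peptide from {fragment.sequence!r}")
    vocab = vocab or drug_vocabulary()
    tokens = np.array(
        [vocab.encode(atom_token(a)) for a in mol.GetAtoms()], dtype=np.int64
    )
    edges = np.array(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        ),
        dtype=np.int64,
    ).reshape(-1, 2)
    return MolecularGraph(
        tokens, edges, origin="target_fragment",
        source_id=f"{fragment.parent_id}[{fragment.start}:{fragment.end}]",
    )
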