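"""Token vocabularies for drug atoms and target residues.

The drug vocabulary has exactly 62 tokens and the target vocabulary exactly
25.  The drug side tokenizes heavy atoms by element, with dedicated tokens for
the aromatic forms of the elements that occur aromatically in organic
chemistry and for the common charge states of C/N/O/S/P; everything else maps
to a reserved UNK token.  The target side is the 20 standard amino acids plus
U (selenocysteine), O (pyrrolysine) and the ambiguity codes B and Z, with X
doubling as the UNK token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from types import MappingProxyType
from typing import Mapping

logger = logging.getLogger(__name__)

DRUG_UNK = "<UNK>"
TARGET_UNK = "X"

# 45 aliphatic element tokens: organic subset first, then halogens/metalloids/
# metals seen in drug-like molecules and salts.
_ALIPHATIC_ELEMENTS = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
    "Si", "Se", "As", "Te", "Al", "Zn", "Fe", "Cu", "Mn", "Mg",
    "Ca", "Na", "K", "Li", "Co", "Ni", "Hg", "Sn", "Sb", "Bi",
    "Pt", "Au", "Ag", "Cr", "V", "Ti", "Mo", "W", "Pd", "Ru",
    "Rh", "Pb", "Ge", "Ga", "Cd",
)
# 7 aromatic tokens (elements that participate in aromatic rings).
_AROMATIC_ELEMENTS = ("C", "N", "O", "S", "P", "Se", "B")
# 9 charge-state tokens; charge takes precedence over aromaticity.
_CHARGED = (
    ("C", 1), ("C", -1), ("N", 1), ("N", -1), ("O", 1),
    ("O", -1), ("S", 1), ("S", -1), ("P", 1),
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues
_EXTRA_RESIDUES = "UOBZ"               # Sec, Pyl, Asx, Glx


@dataclass(frozen=True)
class TokenVocabulary:
    """Immutable token -> contiguous index map with a reserved UNK token."""

    kind: str  # "drug" | "target"
    index: Mapping[str, int]
    unk_token: str
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self):
        if self.unk_token not in self.index:
            raise ValueError("UNK token must be in the vocabulary")
        idx = sorted(self.index.values())
        if idx != list(range(len(idx))):
            raise ValueError("vocabulary indices must be contiguous from 0")

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def unk_index(self) -> int:
        return self.index[self.unk_token]

    def encode(self, token: str) -> int:
        """Map a token to its index; unknown tokens fall back to UNK (logged
        once per distinct token)."""
        try:
            return self.index[token]
        except KeyError:
            if token not in self._warned:
                self._warned.add(token)
                logger.warning(
                    "%s vocabulary: token %r not in vocabulary, mapped to UNK",
                    self.kind, token,
                )
            return self.unk_index


def _charge_token(symbol: str, charge: int) -> str:
    return f"{symbol}{'+' if charge > 0 else '-'}"


@lru_cache(maxsize=None)
def drug_vocabulary() -> TokenVocabulary:
    """The 62-token heavy-atom vocabulary."""
    tokens: list[str] = list(_ALIPHATIC_ELEMENTS)
    tokens += [f"{el}:ar" for el in _AROMATIC_ELEMENTS]
    tokens += [_charge_token(s, c) for s, c in _CHARGED]
    tokens.append(DRUG_UNK)
    assert len(tokens) == 62, len(tokens)
    return TokenVocabulary(
        kind="drug",
        index=MappingProxyType({t: i for i, t in enumerate(tokens)}),
        unk_token=DRUG_UNK,
    )


@lru_cache(maxsize=None)
def target_vocabulary() -> TokenVocabulary:
    """The 25-token residue vocabulary (X doubles as UNK)."""
    tokens = list(_AMINO_ACIDS) + list(_EXTRA_RESIDUES) + [TARGET_UNK]
    assert len(tokens) == 25, len(tokens)
    return TokenVocabulary(
        kind="target",
        index=MappingProxyType({t: i for i, t in enumerate(tokens)}),
        unk_token=TARGET_UNK,
    )


def atom_token(atom) -> str:
    """Tokenize an RDKit atom: charge state first, then aromatic form, then
    plain element; out-of-vocabulary combinations become UNK downstream."""
    symbol = atom.GetSymbol()
    charge = atom.GetFormalCharge()
    if charge != 0 and (symbol, 1 if charge > 0 else -1) in _CHARGED:
        return _charge_token(symbol, charge)
    if atom.GetIsAromatic() and symbol in _AROMATIC_ELEMENTS:
        return f"{symbol}:ar"
    return symbol
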