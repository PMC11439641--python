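"""Sliding-window segmentation of target sequences.

Two regimes:

* **non-overlapping** windows for the pretraining corpus, so no residue leaks
  into two training fragments;
* **overlapping** windows for feature extraction, always exactly ``K``
  windows per sequence so every target yields a fixed-size fragment set.

For a sequence of length ``L``, window length ``l`` and ``K`` windows, the
overlapping stride is ``s = max(1, ceil((L - l) / (K - 1)))`` and window ``i``
starts at ``min(i * s, L - l)``; sequences with ``L <= l`` produce one real
window (the full sequence) followed by ``K - 1`` padding fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .graphs import ResidueFragment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Window length (residues), fragment count K, and the minimum length a
    trailing partial pretraining window must have to be kept."""

    window_length: int = 64
    k: int = 64
    min_fragment_length: int = 8

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.min_fragment_length <= self.window_length:
            raise ValueError("min_fragment_length must be in [1, window_length]")


@dataclass
class FragmentSet:
    parent_id: str
    fragments: list[ResidueFragment]
    mode: str  # "non_overlapping" | "overlapping"

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parent_id\tindex\tstart\tend\tpadding\n")
            for i, f in enumerate(self.fragments):
                fh.write(f"{f.parent_id}\t{i}\t{f.start}\t{f.end}\t{int(f.padding)}\n")


def segment_nonoverlapping(
    sequence: str, cfg: WindowConfig, parent_id: str = ""
) -> FragmentSet:
    """Consecutive disjoint windows from position 0; a trailing partial window
    shorter than ``min_fragment_length`` is dropped."""
    if not sequence:
        raise ValueError("cannot segment an empty sequence")
    l = cfg.window_length
    frags: list[ResidueFragment] = []
    for start in range(0, len(sequence), l):
        end = min(start + l, len(sequence))
        if end - start < l and end - start < cfg.min_fragment_length:
            logger.debug(
                "dropping length-%d tail of %s (< min_fragment_length=%d)",
                end - start, parent_id or "<sequence>", cfg.min_fragment_length,
            )
            break
        frags.append(ResidueFragment(sequence[start:end], parent_id, start, end))
    return FragmentSet(parent_id, frags, mode="non_overlapping")


def segment_overlapping(
    sequence: str, cfg: WindowConfig, parent_id: str = ""
) -> FragmentSet:
    """Exactly ``K`` windows of length ``window_length`` spanning the sequence;
    short sequences are padded with empty padding fragments."""
    if not sequence:
        raise ValueError("cannot segment an empty sequence")
    L, l, k = len(sequence), cfg.window_length, cfg.k
    frags: list[ResidueFragment] = []
    if L <= l:
        frags.append(ResidueFragment(sequence, parent_id, 0, L))
        frags += [
            ResidueFragment("", parent_id, L, L, padding=True) for _ in range(k - 1)
        ]
    else:
        stride = 1 if k == 1 else max(1, math.ceil((L - l) / (k - 1)))
        for i in range(k):
            start = min(i * stride, L - l)
            frags.append(ResidueFragment(sequence[start:start + l], parent_id, start, start + l))
    return FragmentSet(parent_id, frags, mode="overlapping")
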