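"""Readers and writers for the standard input formats.

Drugs arrive as .smi files (one SMILES per line, optional whitespace-separated
id) or CSVs with ``id,smiles`` columns; targets as FASTA; labeled data as CSVs
with ``drug_id,target_id,affinity`` columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file; returns (id, smiles) pairs.  Lines are
    ``SMILES [id]``; missing ids become D<line index>."""
    out: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        ident = parts[1] if len(parts) > 1 else f"D{i}"
        out.append((ident, smiles))
    return out


def read_drugs_csv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(df["id"], df["smiles"]))


def read_drugs(path) -> list[tuple[str, str]]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_drugs_csv(path)
    return read_smiles_file(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA; record id is the header up to the first whitespace."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_smiles_file(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for ident, smiles in records:
            fh.write(f"{smiles}\t{ident}\n")


def read_affinities_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"drug_id", "target_id", "affinity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["drug_id"] = df["drug_id"].astype(str)
    df["target_id"] = df["target_id"].astype(str)
    df["affinity"] = df["affinity"].astype(float)
    return df
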