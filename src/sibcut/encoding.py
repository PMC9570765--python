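"""Encode siRNA antisense sequences as concatenated BCUT descriptor vectors.

Each nucleotide token of a length-L sequence is replaced by its 12 BCUT
descriptors, giving a 12*L feature vector (252 features for the usual
21-mer guide strand with its two 3' overhang positions nt20-nt21).
Columns are labelled ``nt{p}_{descriptor}`` with 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bcut import BCUT_COLUMNS, DescriptorTable

TOKEN_SEPARATOR = ","


@dataclass(frozen=True)
class SiRNARecord:
    """One siRNA: identifier, tokenised guide-strand sequence, potency.

    Potency lives on whatever scale the source dataset uses (normalized
    knockdown where higher is better, or residual reporter level where
    lower is better); the package models it as-is and never flips signs.
    """

    id: str
    sequence: tuple[str, ...]
    potency: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class EncodedDataset:
    """Design matrix (N x 12L), potency vector and sample ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0] or len(self.ids) != self.X.shape[0]:
            raise ValueError("X, y and ids must agree on sample count")
        if not self.columns:
            self.columns = column_labels(self.X.shape[1] // 12) if self.X.shape[1] else []
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column labels must match X width")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def sequence_length(self) -> int:
        return self.X.shape[1] // 12

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx, dtype=int)
        return EncodedDataset(
            self.X[idx], self.y[idx], [self.ids[i] for i in idx], list(self.columns)
        )

    def with_potencies(self, y) -> "EncodedDataset":
        return EncodedDataset(self.X, np.asarray(y, dtype=float), list(self.ids), list(self.columns))


def column_labels(length: int) -> list[str]:
    """Labels ``nt{p}_{descriptor}`` for a length-``length`` sequence."""
    return [f"nt{p}_{d}" for p in range(1, length + 1) for d in BCUT_COLUMNS]


def parse_column_label(label: str) -> tuple[int, str]:
    """Invert :func:`column_labels`: ``nt7_BCUT_SMR_2`` -> ``(7, "BCUT_SMR_2")``."""
    pos_part, _, descriptor = label.partition("_")
    if not pos_part.startswith("nt") or not pos_part[2:].isdigit() or descriptor not in BCUT_COLUMNS:
        raise ValueError(f"malformed column label {label!r}")
    return int(pos_part[2:]), descriptor


def tokenize_sequence(raw: str) -> tuple[str, ...]:
    """Split a raw sequence string into nucleotide tokens.

    Strings containing a comma are treated as comma-separated token
    lists (the dialect for chemically modified alphabets, e.g.
    ``"mA,fU,LG"``); otherwise one token per character.
    """
    if not raw:
        raise ValueError("empty sequence string")
    if TOKEN_SEPARATOR in raw:
        tokens = tuple(t.strip() for t in raw.split(TOKEN_SEPARATOR))
        if any(not t for t in tokens):
            raise ValueError(f"empty token in sequence {raw!r}")
        return tokens
    return tuple(raw)


def format_sequence(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize_sequence` (round-trips both dialects)."""
    if all(len(t) == 1 for t in tokens):
        return "".join(tokens)
    return TOKEN_SEPARATOR.join(tokens)


def encode_sirna(sequence: Sequence[str], table: DescriptorTable) -> np.ndarray:
    """Concatenated BCUT vector for one tokenised sequence."""
    parts = []
    for position, token in enumerate(sequence, start=1):
        if token not in table:
            raise KeyError(
                f"unknown nucleotide token {token!r} at position nt{position}"
            )
        parts.append(table.row(token))
    return np.concatenate(parts)


def encode_dataset(records: Sequence[SiRNARecord], table: DescriptorTable) -> EncodedDataset:
    """Encode a homogeneous-length record list into a design matrix."""
    records = list(records)
    if not records:
        return EncodedDataset(np.empty((0, 0)), np.empty(0), [], [])
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        common = max(lengths, key=lambda n: sum(len(r.sequence) == n for r in records))
        offenders = [r.id for r in records if len(r.sequence) != common]
        raise ValueError(f"mixed sequence lengths; offending ids: {offenders}")
    L = lengths.pop()
    X = np.vstack([encode_sirna(r.sequence, table) for r in records])
    y = np.array([r.potency for r in records], dtype=float)
    return EncodedDataset(X, y, [r.id for r in records], column_labels(L))


def read_dataset_csv(path) -> list[SiRNARecord]:
    """Read a dataset CSV with required columns id, sequence, potency."""
    frame = pd.read_csv(path, dtype={"id": str, "sequence": str})
    missing = [c for c in ("id", "sequence", "potency") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        SiRNARecord(row.id, tokenize_sequence(row.sequence), float(row.potency))
        for row in frame.itertuples(index=False)
    ]


def write_dataset_csv(records: Iterable[SiRNARecord], path) -> None:
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [format_sequence(r.sequence) for r in records],
            "potency": [r.potency for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_fasta_sequences(path) -> list[SiRNARecord]:
    """FASTA ingestion for sequence-only encoding (potency left NaN)."""
    records: list[SiRNARecord] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SiRNARecord(name, tokenize_sequence("".join(chunks))))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        records.append(SiRNARecord(name, tokenize_sequence("".join(chunks))))
    return records
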