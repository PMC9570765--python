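"""Synthetic siRNA-shaped datasets with known ground truth.

Every pipeline stage is testable without external data: sequences are
drawn i.i.d. uniform over a token alphabet, encoded with a descriptor
table, and potencies are generated as a linear function of the
standardized descriptors plus Gaussian noise.  Two preconfigured
benchmarks mirror the shapes of the public datasets the method was
designed around: a large natural-nucleotide set (2431 21-mers) with a
sparse planted signal, and a small chemically-modified-style set (48
21-mers) whose signal lives in four latent descriptor-space
directions.

The generators emulate dataset geometry (sample count, sequence
length, alphabet size, signal-to-noise), not RNAi biology: real
potencies are not linear in BCUT space and real sequences are not
uniform, so passing recovery tests demonstrates correctness of the
machinery, not biological validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bcut import BCUT_COLUMNS, DescriptorTable, natural_descriptor_table
from .encoding import EncodedDataset, SiRNARecord, column_labels, encode_dataset

NATURAL_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U", "T")

#: Default noise standard deviation, as a fraction of unit signal
#: standard deviation (the planted signal is scaled to variance 1).
DEFAULT_NOISE_SD = 0.3


@dataclass(frozen=True)
class BenchmarkSpec:
    """Recipe for a synthetic dataset: shape, planted signal, noise."""

    n: int
    L: int = 21
    alphabet: tuple[str, ...] = NATURAL_ALPHABET
    beta: dict = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        valid = set(column_labels(self.L))
        bad = [k for k in self.beta if k not in valid]
        if bad:
            raise ValueError(f"beta key(s) not valid for L={self.L}: {bad}")


def generate_sequences(spec: BenchmarkSpec) -> list[SiRNARecord]:
    """Seeded i.i.d. uniform token sequences; potency left unset."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n))
    records = []
    for i in range(spec.n):
        tokens = tuple(rng.choice(spec.alphabet, size=spec.L))
        records.append(SiRNARecord(f"synth{i + 1:0{width}d}", tokens))
    return records


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    keep = sd > 0
    out[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return out


def generate_potencies(
    records: list[SiRNARecord], table: DescriptorTable, spec: BenchmarkSpec
) -> list[SiRNARecord]:
    """Set potencies as (standardized X) @ beta + Gaussian noise.

    The signal is rescaled to unit standard deviation (when it varies)
    so ``noise_sd`` reads as noise-to-signal ratio.
    """
    encoded = encode_dataset(records, table)
    Z = _standardize(encoded.X)
    beta = np.zeros(Z.shape[1])
    col_index = {c: i for i, c in enumerate(encoded.columns)}
    for key, value in spec.beta.items():
        if key not in col_index:
            raise ValueError(f"beta key {key!r} not among encoded columns")
        beta[col_index[key]] = value
    signal = Z @ beta
    sd = signal.std()
    if sd > 0:
        signal = signal / sd
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    y = signal + rng.normal(0.0, spec.noise_sd, size=len(signal))
    return [
        SiRNARecord(r.id, r.sequence, float(val)) for r, val in zip(records, y)
    ]


def generate_benchmark(spec: BenchmarkSpec, table: DescriptorTable | None = None) -> EncodedDataset:
    """Sequences + potencies + encoding in one call."""
    table = table if table is not None else natural_descriptor_table()
    records = generate_potencies(generate_sequences(spec), table, spec)
    return encode_dataset(records, table)


def sparse_beta(L: int, n_nonzero: int, seed: int, positions=None) -> dict:
    """A seeded sparse coefficient map over valid column labels.

    ``positions`` restricts the support to given 1-based nucleotide
    positions (e.g. ``(1, 2)`` plants all signal on nt1/nt2).
    """
    labels = column_labels(L)
    if positions is not None:
        allowed = {f"nt{p}_" for p in positions}
        labels = [lab for lab in labels if any(lab.startswith(a) for a in allowed)]
    rng = np.random.default_rng(seed)
    n_nonzero = min(n_nonzero, len(labels))
    chosen = rng.choice(len(labels), size=n_nonzero, replace=False)
    coefs = rng.normal(1.0, 0.3, size=n_nonzero) * rng.choice([-1.0, 1.0], size=n_nonzero)
    return {labels[i]: float(c) for i, c in zip(chosen, coefs)}


def huesken_shaped_benchmark(
    seed: int = 0,
    *,
    n: int = 2431,
    L: int = 21,
    n_nonzero: int = 24,
    noise_sd: float = DEFAULT_NOISE_SD,
    positions=None,
) -> EncodedDataset:
    """Large natural-alphabet benchmark with a sparse planted signal."""
    spec = BenchmarkSpec(
        n=n,
        L=L,
        beta=sparse_beta(L, n_nonzero, seed, positions),
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_benchmark(spec)


def latent_benchmark(
    seed: int = 0,
    *,
    n: int = 48,
    L: int = 21,
    n_directions: int = 4,
    weights: tuple[float, ...] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> EncodedDataset:
    """Small benchmark whose signal spans a few latent directions.

    Potency is a weighted sum of the dataset's leading principal score
    directions (unit-variance each) plus noise, so a PLS model needs
    about ``n_directions`` components to capture it — the small-data,
    many-descriptor regime of chemically modified siRNA sets.
    """
    table = natural_descriptor_table()
    spec = BenchmarkSpec(n=n, L=L, seed=seed, noise_sd=noise_sd)
    records = generate_sequences(spec)
    encoded = encode_dataset(records, table)
    Z = _standardize(encoded.X)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    if weights is None:
        weights = tuple(1.0 - 0.2 * k for k in range(n_directions))
    if len(weights) != n_directions:
        raise ValueError("weights length must equal n_directions")
    scores = Z @ vt[:n_directions].T
    scores = scores / scores.std(axis=0)
    signal = scores @ np.asarray(weights, dtype=float)
    signal = signal / signal.std()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    y = signal + rng.normal(0.0, noise_sd, size=n)
    return encoded.with_potencies(y)


def synth_modified_alphabet(k: int, seed: int = 0, *, scale: float = 0.1) -> DescriptorTable:
    """A synthetic table of ``k`` chemically-modified-style tokens.

    Each token's 12 descriptors are a seeded Gaussian perturbation of a
    natural nucleotide's row, re-sorted within each property block so
    the eigen-summary ordering invariant still holds.  With
    ``scale=0`` a token duplicates its parent natural row.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    natural = natural_descriptor_table()
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(k):
        parent = natural.symbols[i % len(natural.symbols)]
        base = natural.row(parent).copy()
        perturbed = base + rng.normal(0.0, scale, size=12)
        for block in range(3):
            sl = slice(4 * block, 4 * block + 4)
            perturbed[sl] = np.sort(perturbed[sl])
        rows[f"m{i + 1}{parent}"] = perturbed
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(BCUT_COLUMNS))
    frame.index.name = "NT"
    return DescriptorTable(frame)
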