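"""Rational train/test design from an ART-2a clustering.

Test molecules are drawn so that every (multimember) cluster is
represented, which guarantees each test siRNA has structurally similar
neighbours in the training set; the most and least potent siRNAs are
always kept in training so the model never extrapolates beyond the
observed potency range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .art2a import ART2aConfig, Clustering, art2a_cluster
from .encoding import EncodedDataset


@dataclass(frozen=True)
class SplitDesign:
    """Disjoint train/test index sets covering a dataset."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test indices overlap")

    @property
    def n_total(self) -> int:
        return len(self.train_idx) + len(self.test_idx)

    def to_frame(self, ids: list[str]) -> pd.DataFrame:
        rows = [(ids[i], "train") for i in self.train_idx]
        rows += [(ids[i], "test") for i in self.test_idx]
        return pd.DataFrame(rows, columns=["id", "role"]).sort_values("id", kind="stable")


def potency_extremes(y: np.ndarray) -> tuple[int, int]:
    """Indices of the most and least potent samples (first occurrence)."""
    y = np.asarray(y, dtype=float)
    return int(np.argmax(y)), int(np.argmin(y))


def design_split(
    encoded: EncodedDataset,
    clustering: Clustering,
    test_size: int,
    seed: int = 0,
    *,
    multimember_only: bool = True,
) -> SplitDesign:
    """One rational train/test partition.

    Cycles over the multimember clusters in seeded random order,
    drawing one eligible member per cluster per pass, until
    ``test_size`` test samples are collected.  The potency extremes are
    never eligible.  ``multimember_only=False`` additionally cycles
    over singleton clusters (used by the training-size scan, where the
    requested test set can exceed the multimember population).
    """
    n = encoded.n_samples
    if not 0 <= test_size <= max(0, n - 2):
        raise ValueError(f"test_size must lie in [0, {n - 2}]")
    if len(clustering.assignment) != n:
        raise ValueError("clustering does not match dataset size")
    if test_size == 0:
        return SplitDesign(tuple(range(n)), ())
    excluded = set(potency_extremes(encoded.y))
    labels = clustering.multimember_labels()
    if not multimember_only:
        labels = np.unique(clustering.assignment)
    rng = np.random.default_rng(seed)
    pools = {
        int(lab): [int(i) for i in clustering.members(lab) if i not in excluded]
        for lab in labels
    }
    n_eligible = sum(len(p) for p in pools.values())
    if test_size > n_eligible:
        raise ValueError(
            f"test_size {test_size} exceeds the {n_eligible} eligible samples "
            "(members of covered clusters, potency extremes excluded)"
        )
    order = rng.permutation(np.array(sorted(pools), dtype=int))
    test: list[int] = []
    while len(test) < test_size:
        progressed = False
        for lab in order:
            pool = pools[int(lab)]
            if not pool:
                continue
            pick = pool.pop(int(rng.integers(len(pool))))
            test.append(pick)
            progressed = True
            if len(test) == test_size:
                break
        if not progressed:  # pragma: no cover - guarded by n_eligible check
            break
    test_set = set(test)
    train = tuple(i for i in range(n) if i not in test_set)
    return SplitDesign(train, tuple(sorted(test)))


def generate_splits(
    encoded: EncodedDataset,
    n_splits: int,
    test_size: int,
    cfg: ART2aConfig | None = None,
    *,
    clustering: Clustering | None = None,
    seed: int = 0,
) -> list[SplitDesign]:
    """``n_splits`` rational designs from one clustering, distinct seeds."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if clustering is None:
        clustering = art2a_cluster(encoded.X, cfg or ART2aConfig())
    child_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    return [
        design_split(encoded, clustering, test_size, int(s)) for s in child_seeds
    ]


def read_split_csv(path, ids: list[str]) -> SplitDesign:
    """Read a two-column (id, role) split file back into index form."""
    frame = pd.read_csv(path)
    lookup = {sid: i for i, sid in enumerate(ids)}
    train, test = [], []
    for row in frame.itertuples(index=False):
        if row.id not in lookup:
            raise ValueError(f"split file references unknown id {row.id!r}")
        (train if row.role == "train" else test).append(lookup[row.id])
    return SplitDesign(tuple(sorted(train)), tuple(sorted(test)))
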