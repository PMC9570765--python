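"""ART-2a adaptive resonance clustering of descriptor vectors.

Sequential, similarity-gated clustering of unit-normalised vectors: a
sample joins the existing cluster whose centroid it matches best when
the cosine similarity clears the vigilance threshold, and the centroid
moves toward the sample; otherwise the sample founds a new cluster.
Because centroids keep adapting, each one remains a faithful prototype
of its members — the property the rational train/test design relies on.

Descriptors are column-standardised (zero-variance columns dropped)
before L2 row normalisation, so that no BCUT property dominates the
cosine geometry merely through its numeric scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ART2aConfig:
    """Knobs of the sequential ART-2a pass.

    vigilance: cosine-similarity threshold in (0, 1) for joining a
        cluster; higher values give more, tighter clusters.
    learning_rate: centroid update step in (0, 1].
    max_epochs: upper bound on full passes over the data; iteration
        stops earlier once assignments stabilise.
    seed: governs presentation order.
    """

    vigilance: float = 0.9
    learning_rate: float = 0.1
    max_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.vigilance < 1.0:
            raise ValueError("vigilance must lie in (0, 1)")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")


@dataclass
class Clustering:
    """Cluster labels plus unit-norm centroids in preprocessed space."""

    assignment: np.ndarray
    centroids: np.ndarray
    n_epochs: int = 0
    config: ART2aConfig | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)

    def multimember_labels(self) -> np.ndarray:
        labels, counts = np.unique(self.assignment, return_counts=True)
        return labels[counts >= 2]

    @property
    def n_multimember(self) -> int:
        return len(self.multimember_labels())


def preprocess(X: np.ndarray) -> np.ndarray:
    """Column-standardise, drop zero-variance columns, L2-normalise rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all descriptor columns are constant; nothing to cluster")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    norms = np.linalg.norm(Z, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm row(s) after standardisation: {zero.tolist()}")
    return Z / norms[:, None]


def art2a_cluster(X: np.ndarray, cfg: ART2aConfig, *, preprocessed: bool = False) -> Clustering:
    """Cluster the rows of ``X`` with sequential ART-2a.

    With ``preprocessed=True`` the rows are taken as already
    unit-normalised (used to amortise standardisation across repeated
    clustering runs during vigilance tuning).
    """
    V = np.asarray(X, dtype=float) if preprocessed else preprocess(X)
    n, p = V.shape
    rng = np.random.default_rng(cfg.seed)
    centroids = np.empty((0, p))
    assignment = np.full(n, -1, dtype=int)
    n_epochs = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        previous = assignment.copy()
        for i in order:
            x = V[i]
            if centroids.shape[0]:
                sims = centroids @ x
                best = int(np.argmax(sims))
            else:
                best, sims = -1, None
            if best >= 0 and sims[best] >= cfg.vigilance:
                c = (1.0 - cfg.learning_rate) * centroids[best] + cfg.learning_rate * x
                centroids[best] = c / np.linalg.norm(c)
                assignment[i] = best
            else:
                centroids = np.vstack([centroids, x[None, :]])
                assignment[i] = centroids.shape[0] - 1
        n_epochs = epoch + 1
        if np.array_equal(previous, assignment):
            break
    # drop clusters that lost all members to later, better-matching prototypes
    labels, inverse = np.unique(assignment, return_inverse=True)
    return Clustering(inverse, centroids[labels], n_epochs, cfg)


@dataclass
class VigilanceResult:
    """Outcome of vigilance tuning toward a multimember-cluster target."""

    vigilance: float
    achieved: int
    target: int
    clustering: Clustering
    exact: bool = field(default=False)

    def __float__(self) -> float:
        return self.vigilance


_TUNING_GRID = (0.01, 0.02, 0.04, 0.06, 0.08, 0.12, 0.16, 0.24, 0.32, 0.45, 0.6, 0.75, 0.9)


def tune_vigilance(
    X: np.ndarray,
    target_multimember: int,
    cfg: ART2aConfig | None = None,
    *,
    tol: float = 1e-4,
) -> VigilanceResult:
    """Search the vigilance parameter toward a multimember-cluster count.

    The multimember count grows (stepwise, roughly monotonically) with
    vigilance until clusters shatter into singletons, so the count is
    first probed on a coarse vigilance grid; the leftmost grid interval
    that brackets the target is then bisected to a tolerance of
    ``tol``.  Ties resolve to the smaller vigilance.  If the target is
    unreachable the best-effort result is returned with a warning.
    """
    cfg = cfg or ART2aConfig()
    n = np.asarray(X).shape[0]
    if not 1 <= target_multimember <= max(1, n // 2):
        raise ValueError("target must lie in [1, N/2]")
    V = preprocess(X)
    best: VigilanceResult | None = None

    def probe(vigilance: float) -> VigilanceResult:
        nonlocal best
        clustering = art2a_cluster(V, replace(cfg, vigilance=vigilance), preprocessed=True)
        count = clustering.n_multimember
        result = VigilanceResult(
            vigilance, count, target_multimember, clustering, count == target_multimember
        )
        gap = abs(count - target_multimember)
        if (
            best is None
            or gap < abs(best.achieved - target_multimember)
            or (gap == abs(best.achieved - target_multimember) and vigilance < best.vigilance)
        ):
            best = result
        return result

    coarse = [probe(v) for v in _TUNING_GRID]
    for result in coarse:
        if result.exact:
            return result
    bracket = None
    for left, right in zip(coarse, coarse[1:]):
        lo_c, hi_c = sorted((left.achieved, right.achieved))
        if lo_c <= target_multimember <= hi_c:
            bracket = (left, right)
            break
    if bracket is not None:
        lo, hi = bracket[0].vigilance, bracket[1].vigilance
        ascending = bracket[0].achieved <= bracket[1].achieved
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            result = probe(mid)
            if result.exact:
                return result
            below = result.achieved < target_multimember
            if below == ascending:
                lo = mid
            else:
                hi = mid
    assert best is not None
    if not best.exact:
        logger.warning(
            "vigilance tuning: target %d multimember clusters unreachable; "
            "achieved %d at vigilance %.5f",
            target_multimember,
            best.achieved,
            best.vigilance,
        )
    return best
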