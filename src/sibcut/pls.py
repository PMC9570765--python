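"""Partial least squares regression (NIPALS) and evaluation statistics.

PLS projects the descriptor matrix onto a small set of orthogonal
latent components chosen to covary maximally with potency, which keeps
regression stable when descriptors are many and collinear (252 columns
from five distinct nucleotide rows per position).  Components are
extracted sequentially with the NIPALS algorithm; the sentinel
``"all"`` extracts the maximal non-degenerate set, min(N-1, rank(X)).

Model quality is reported as the Pearson correlation r between actual
and predicted potency, the predictive r^2 (one minus residual over
total sum of squares, computable on held-out data and possibly
negative), and the root-mean-square error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PLSConfig:
    """n_components: positive integer or ``"all"``; scale: autoscale vs center-only."""

    n_components: int | str = "all"
    scale: bool = True

    def __post_init__(self) -> None:
        if self.n_components != "all":
            if not isinstance(self.n_components, (int, np.integer)) or self.n_components < 1:
                raise ValueError('n_components must be a positive integer or "all"')


@dataclass
class PLSModel:
    """Fitted latent-variable regression model.

    ``coefficients`` live in autoscaled descriptor space (the space the
    relative-importance analysis reads); prediction applies the stored
    centering/scaling so that
    ``yhat = y_mean + y_scale * ((X - x_mean)/x_scale) @ coefficients``.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray      # p x A
    loadings: np.ndarray     # p x A
    y_loadings: np.ndarray   # A
    coefficients: np.ndarray  # p
    n_components_used: int
    column_labels: list[str] = field(default_factory=list)
    config: PLSConfig = field(default_factory=PLSConfig)

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was trained on {self.n_features}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Latent scores of new data (deflation path)."""
        Xs = (self._check_width(X) - self.x_mean) / self.x_scale
        E = Xs.copy()
        T = np.empty((E.shape[0], self.n_components_used))
        for a in range(self.n_components_used):
            T[:, a] = E @ self.weights[:, a]
            E -= np.outer(T[:, a], self.loadings[:, a])
        return T

    def predict(self, X) -> np.ndarray:
        Xs = (self._check_width(X) - self.x_mean) / self.x_scale
        return self.y_mean + self.y_scale * (Xs @ self.coefficients)

    def predict_via_scores(self, X) -> np.ndarray:
        """Score-path prediction; equals :meth:`predict` to ~1e-8 (sanity route)."""
        return self.y_mean + self.y_scale * (self.transform(X) @ self.y_loadings)

    def to_json(self, path) -> None:
        payload = {
            "schema": 1,
            "config": {"n_components": self.config.n_components, "scale": self.config.scale},
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "n_components_used": self.n_components_used,
            "column_labels": self.column_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != 1:
            raise ValueError(f"unsupported model schema: {payload.get('schema')}")
        cfg = PLSConfig(**payload["config"])
        return cls(
            x_mean=np.array(payload["x_mean"]),
            x_scale=np.array(payload["x_scale"]),
            y_mean=float(payload["y_mean"]),
            y_scale=float(payload["y_scale"]),
            weights=np.array(payload["weights"]),
            loadings=np.array(payload["loadings"]),
            y_loadings=np.array(payload["y_loadings"]),
            coefficients=np.array(payload["coefficients"]),
            n_components_used=int(payload["n_components_used"]),
            column_labels=list(payload["column_labels"]),
            config=cfg,
        )


def fit_pls(X, y, cfg: PLSConfig | None = None, column_labels: Sequence[str] | None = None) -> PLSModel:
    """Fit a PLS regression by sequential NIPALS extraction.

    Zero-variance columns are dropped from the extraction (their
    coefficients are fixed at zero) with a warning.  ``"all"``
    components resolves to min(N-1, rank of the centered X).
    """
    cfg = cfg or PLSConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    keep = (np.ptp(X, axis=0) != 0) & (x_sd > 0)
    if not keep.all():
        logger.warning("dropping %d zero-variance column(s) from PLS fit", int((~keep).sum()))
    x_scale = np.where(keep, x_sd, 1.0) if cfg.scale else np.ones(p)
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=1)) if cfg.scale else 1.0

    E = ((X - x_mean) / x_scale)[:, keep]
    f = (y - y_mean) / y_scale
    rank = np.linalg.matrix_rank(E)
    max_components = min(n - 1, rank)
    if cfg.n_components == "all":
        A = max_components
    else:
        A = int(cfg.n_components)
        if A > min(n - 1, E.shape[1]):
            raise ValueError(
                f"n_components={A} exceeds min(N-1, n_features)={min(n - 1, E.shape[1])}"
            )
        A = min(A, max_components)

    pk = E.shape[1]
    W = np.zeros((pk, A))
    P = np.zeros((pk, A))
    q = np.zeros(A)
    used = 0
    for a in range(A):
        # NIPALS weight direction; with a single response the inner
        # power iteration converges in one step, so w is exact here
        w = E.T @ f
        wnorm = np.linalg.norm(w)
        if wnorm < 1e-14 or np.linalg.norm(f) < 1e-14:
            break
        w /= wnorm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - t * q_a
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        used = a + 1

    W, P, q = W[:, :used], P[:, :used], q[:used]
    # back-transform latent regression to descriptor space: B = W (P'W)^-1 q
    if used:
        coef_kept = W @ np.linalg.solve(P.T @ W, q)
    else:  # pragma: no cover - degenerate, kept for safety
        coef_kept = np.zeros(pk)
    coefficients = np.zeros(p)
    coefficients[keep] = coef_kept
    weights = np.zeros((p, used))
    loadings = np.zeros((p, used))
    weights[keep] = W
    loadings[keep] = P
    labels = list(column_labels) if column_labels is not None else [f"x{i}" for i in range(p)]
    return PLSModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=weights,
        loadings=loadings,
        y_loadings=q,
        coefficients=coefficients,
        n_components_used=used,
        column_labels=labels,
        config=cfg,
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(X)


def pearson_r(y, p) -> float:
    """Pearson correlation between actual and predicted potencies."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("y and p must be equal-length vectors with N >= 2")
    yd, pd_ = y - y.mean(), p - p.mean()
    denom = np.sqrt((yd**2).sum() * (pd_**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((yd * pd_).sum() / denom)


def predictive_r2(y, p) -> float:
    """1 - SS_res/SS_tot; may be negative on held-out data."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("y and p must be equal-length vectors with N >= 2")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("predictive r2 undefined for constant y")
    return float(1.0 - ((y - p) ** 2).sum() / ss_tot)


def rmse(y, p) -> float:
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.size < 1:
        raise ValueError("y and p must be equal-length non-empty vectors")
    return float(np.sqrt(((y - p) ** 2).mean()))


@dataclass(frozen=True)
class EvaluationReport:
    """Pearson r, predictive r^2 and RMSE for one (actual, predicted) pair."""

    r: float
    r2: float
    rmse: float
    n: int

    @classmethod
    def from_predictions(cls, y, p) -> "EvaluationReport":
        return cls(pearson_r(y, p), predictive_r2(y, p), rmse(y, p), len(np.asarray(y)))
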