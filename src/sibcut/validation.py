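"""Validation analyses over many rational splits.

Five analyses establish that a fitted potency model is real rather
than an artifact of one lucky partition: (1) train/test correlation
statistics aggregated over repeated rational splits, (2) a scan over
the number of PLS components, (3) the effect of the train/test
partition itself, (4) the effect of training-set size, and (5)
y-scrambling, where potencies are permuted across the dataset and the
whole protocol is re-run — a genuine model must collapse.  A sixth
analysis reads the autoscaled regression coefficients as relative
importances of nucleotide positions and of the 12 BCUT descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .art2a import ART2aConfig, Clustering, art2a_cluster
from .encoding import EncodedDataset, parse_column_label
from .pls import EvaluationReport, PLSConfig, PLSModel, fit_pls
from .split import SplitDesign, design_split, generate_splits, potency_extremes

logger = logging.getLogger(__name__)

DEFAULT_COMPONENT_GRID: tuple = ("all", *range(1, 15))


@dataclass
class SplitStats:
    """Per-split evaluation reports plus Mean/Std/Max/Min aggregates."""

    per_split: pd.DataFrame  # columns: split, set, r, r2, rmse, n

    def aggregate(self, metric: str = "r") -> pd.DataFrame:
        """Table with Training/Test rows and Mean, Standard Deviation, Maximum, Minimum."""
        rows = {}
        for subset, name in (("train", "Training"), ("test", "Test")):
            vals = self.per_split.loc[self.per_split["set"] == subset, metric]
            if not len(vals):
                continue
            rows[name] = {
                "Mean": vals.mean(),
                "Standard Deviation": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "Maximum": vals.max(),
                "Minimum": vals.min(),
            }
        return pd.DataFrame(rows).T

    def mean(self, metric: str = "r", subset: str = "test") -> float:
        vals = self.per_split.loc[self.per_split["set"] == subset, metric]
        return float(vals.mean())


def _check_design(encoded: EncodedDataset, split: SplitDesign, index: int) -> None:
    n = encoded.n_samples
    union = sorted(split.train_idx) + sorted(split.test_idx)
    if sorted(union) != list(range(n)):
        raise ValueError(f"split {index}: indices do not partition the dataset")
    if split.test_idx:
        hi, lo = potency_extremes(encoded.y)
        if hi not in split.train_idx or lo not in split.train_idx:
            raise ValueError(f"split {index}: potency extremes missing from training set")


def _fit_split(
    encoded: EncodedDataset, split: SplitDesign, cfg: PLSConfig
) -> tuple[PLSModel, EvaluationReport, EvaluationReport | None]:
    train = encoded.subset(list(split.train_idx))
    model = fit_pls(train.X, train.y, cfg, column_labels=encoded.columns)
    train_rep = EvaluationReport.from_predictions(train.y, model.predict(train.X))
    test_rep = None
    if split.test_idx:
        test = encoded.subset(list(split.test_idx))
        test_rep = EvaluationReport.from_predictions(test.y, model.predict(test.X))
    return model, train_rep, test_rep


def multi_split_evaluation(
    encoded: EncodedDataset,
    splits: list[SplitDesign],
    cfg: PLSConfig | None = None,
    *,
    return_models: bool = False,
):
    """Fit one PLS model per rational split and aggregate the statistics."""
    if not splits:
        raise ValueError("need at least one split")
    cfg = cfg or PLSConfig()
    rows, models = [], []
    for k, split in enumerate(splits):
        _check_design(encoded, split, k)
        model, train_rep, test_rep = _fit_split(encoded, split, cfg)
        models.append(model)
        rows.append((k, "train", train_rep.r, train_rep.r2, train_rep.rmse, train_rep.n))
        if test_rep is not None:
            rows.append((k, "test", test_rep.r, test_rep.r2, test_rep.rmse, test_rep.n))
    stats = SplitStats(pd.DataFrame(rows, columns=["split", "set", "r", "r2", "rmse", "n"]))
    return (stats, models) if return_models else stats


def pc_scan(
    encoded: EncodedDataset,
    split: SplitDesign,
    component_grid=DEFAULT_COMPONENT_GRID,
    *,
    scale: bool = True,
) -> pd.DataFrame:
    """Train/test statistics as a function of the number of PLS components."""
    grid = list(component_grid)
    if not grid:
        raise ValueError("component grid must be non-empty")
    _check_design(encoded, split, 0)
    rows = []
    for n_components in grid:
        cfg = PLSConfig(n_components=n_components, scale=scale)
        model, train_rep, test_rep = _fit_split(encoded, split, cfg)
        row = {
            "n_components": n_components,
            "components_used": model.n_components_used,
            "train_r": train_rep.r,
            "train_r2": train_rep.r2,
            "train_rmse": train_rep.rmse,
        }
        if test_rep is not None:
            row.update(test_r=test_rep.r, test_r2=test_rep.r2, test_rmse=test_rep.rmse)
        rows.append(row)
    return pd.DataFrame(rows)


def training_size_scan(
    encoded: EncodedDataset,
    fractions,
    art_cfg: ART2aConfig | None = None,
    *,
    scale: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Model quality versus training-set size.

    For each fraction a fresh clustering-based rational split of that
    training size is drawn (singleton clusters become eligible too, so
    small training fractions remain constructible) and a PLS model with
    ``"all"`` components is evaluated on the complement.
    """
    art_cfg = art_cfg or ART2aConfig()
    n = encoded.n_samples
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(list(fractions)), 1)) % (2**31)
    for k, fraction in enumerate(fractions):
        if not 0.0 < fraction < 1.0:
            raise ValueError(f"fraction {fraction} outside (0, 1)")
        n_train = int(round(fraction * n))
        if n_train < 2:
            logger.warning("fraction %.3f leaves %d training samples; skipped", fraction, n_train)
            continue
        clustering = art2a_cluster(encoded.X, art_cfg)
        split = design_split(
            encoded, clustering, n - n_train, int(child_seeds[k]), multimember_only=False
        )
        _, train_rep, test_rep = _fit_split(encoded, split, PLSConfig("all", scale))
        rows.append(
            {
                "fraction": fraction,
                "n_train": len(split.train_idx),
                "n_test": len(split.test_idx),
                "train_r": train_rep.r,
                "test_r": test_rep.r if test_rep else np.nan,
                "test_r2": test_rep.r2 if test_rep else np.nan,
                "test_rmse": test_rep.rmse if test_rep else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScrambleReport:
    """Original-vs-scrambled statistics and the percent collapse."""

    original: SplitStats
    scrambled: SplitStats
    reduction_pct_test: float
    reduction_pct_train: float


def _reduction_pct(original: float, scrambled: float) -> float:
    if original <= 0:
        return float("nan")
    return 100.0 * (1.0 - scrambled / original)


def y_scramble_test(
    encoded: EncodedDataset,
    clustering: Clustering,
    n_splits: int,
    test_size: int,
    cfg: PLSConfig | None = None,
    *,
    seed: int = 0,
) -> ScrambleReport:
    """Permute potencies across the whole dataset, redo splits and models.

    The permutation severs any real descriptor-potency relationship, so
    a sound protocol must lose most of its test correlation; the report
    carries the percent reduction of mean r (NaN-flagged when the
    original mean r is non-positive, where a ratio is meaningless).
    """
    cfg = cfg or PLSConfig()
    rng = np.random.default_rng(seed)
    original_splits = generate_splits(
        encoded, n_splits, test_size, clustering=clustering, seed=seed
    )
    original = multi_split_evaluation(encoded, original_splits, cfg)
    scrambled_data = encoded.with_potencies(rng.permutation(encoded.y))
    scrambled_splits = generate_splits(
        scrambled_data, n_splits, test_size, clustering=clustering, seed=seed + 1
    )
    scrambled = multi_split_evaluation(scrambled_data, scrambled_splits, cfg)
    return ScrambleReport(
        original,
        scrambled,
        _reduction_pct(original.mean("r", "test"), scrambled.mean("r", "test")),
        _reduction_pct(original.mean("r", "train"), scrambled.mean("r", "train")),
    )


@dataclass
class ImportanceReport:
    """Relative importance of descriptor columns and their marginals.

    ``per_column`` sums to 1; the per-position marginal (length L) and
    per-descriptor marginal (length 12) are averages over the
    corresponding column groups, renormalised to sum to 1.
    """

    per_column: pd.Series
    per_position: pd.Series
    per_descriptor: pd.Series

    def top_positions(self, k: int = 2) -> list[str]:
        return list(self.per_position.nlargest(k).index)


def relative_importance(models: list[PLSModel], L: int | None = None) -> ImportanceReport:
    """Coefficient-magnitude importance averaged over split models.

    For each model the importance of column i is |b_i| / sum_j |b_j|
    with coefficients in autoscaled space; importances are averaged
    over models, then marginalised over positions and over the 12 BCUT
    descriptors.
    """
    if not models:
        raise ValueError("need at least one model")
    labels = models[0].column_labels
    per_model = []
    for model in models:
        if model.column_labels != labels:
            raise ValueError("models disagree on column labels")
        abscoef = np.abs(model.coefficients)
        total = abscoef.sum()
        if total == 0:
            raise ValueError("all-zero coefficient vector; importance undefined")
        per_model.append(abscoef / total)
    per_column = pd.Series(np.mean(per_model, axis=0), index=labels)
    positions, descriptors = zip(*(parse_column_label(lab) for lab in labels))
    frame = pd.DataFrame(
        {"importance": per_column.to_numpy(), "position": positions, "descriptor": descriptors}
    )
    pos_mean = frame.groupby("position")["importance"].mean()
    pos_marginal = pos_mean / pos_mean.sum()
    pos_marginal.index = [f"nt{p}" for p in pos_marginal.index]
    desc_mean = frame.groupby("descriptor")["importance"].mean()
    desc_marginal = desc_mean / desc_mean.sum()
    if L is not None and len(pos_marginal) != L:
        raise ValueError(f"expected {L} positions, found {len(pos_marginal)}")
    return ImportanceReport(per_column, pos_marginal, desc_marginal)
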