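"""Multi-split validation analyses: aggregates, scans, scrambling, importance."""

import numpy as np
import pandas as pd
import pytest

from sibcut.art2a import ART2aConfig, art2a_cluster
from sibcut.encoding import column_labels
from sibcut.pls import PLSConfig, PLSModel
from sibcut.split import generate_splits
from sibcut.synthetic import huesken_shaped_benchmark
from sibcut.validation import (
    multi_split_evaluation,
    pc_scan,
    relative_importance,
    training_size_scan,
    y_scramble_test,
)

VIG = 0.3  # moderate vigilance for 252-dim standardized random-sequence data


@pytest.fixture(scope="module")
def clustered_benchmark(small_benchmark):
    clustering = art2a_cluster(small_benchmark.X, ART2aConfig(vigilance=VIG, seed=0))
    return small_benchmark, clustering


@pytest.fixture(scope="module")
def splits(clustered_benchmark):
    encoded, clustering = clustered_benchmark
    return generate_splits(encoded, 10, 30, clustering=clustering, seed=0)


class TestMultiSplitEvaluation:
    def test_single_split_degenerate_aggregates(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        stats = multi_split_evaluation(encoded, splits[:1])
        agg = stats.aggregate("r")
        for row in ("Training", "Test"):
            assert agg.loc[row, "Standard Deviation"] == 0.0
            assert agg.loc[row, "Mean"] == agg.loc[row, "Maximum"] == agg.loc[row, "Minimum"]

    def test_strong_signal_benchmark_test_r_high(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        stats = multi_split_evaluation(encoded, splits)
        assert stats.mean("r", "test") >= 0.9

    def test_aggregate_layout_and_consistency_with_naive_recount(
        self, clustered_benchmark, splits
    ):
        encoded, _ = clustered_benchmark
        stats = multi_split_evaluation(encoded, splits)
        agg = stats.aggregate("r")
        assert list(agg.columns) == ["Mean", "Standard Deviation", "Maximum", "Minimum"]
        assert list(agg.index) == ["Training", "Test"]
        for subset, row in (("train", "Training"), ("test", "Test")):
            vals = stats.per_split.loc[stats.per_split["set"] == subset, "r"].to_numpy()
            assert agg.loc[row, "Mean"] == pytest.approx(vals.mean())
            assert agg.loc[row, "Standard Deviation"] == pytest.approx(vals.std(ddof=1))
            assert agg.loc[row, "Minimum"] <= agg.loc[row, "Mean"] <= agg.loc[row, "Maximum"]

    def test_invalid_split_aborts_with_index(self, clustered_benchmark, splits):
        from sibcut.split import SplitDesign

        encoded, _ = clustered_benchmark
        bad = SplitDesign(splits[0].train_idx[:-1], splits[0].test_idx)
        with pytest.raises(ValueError, match="split 1"):
            multi_split_evaluation(encoded, [splits[0], bad])


class TestPCScan:
    def test_single_entry_grid(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        scan = pc_scan(encoded, splits[0], ["all"])
        assert len(scan) == 1
        assert scan.loc[0, "n_components"] == "all"

    def test_training_r_nondecreasing_in_component_count(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        scan = pc_scan(encoded, splits[0], [1, 2, 3, 4, 6, 8])
        assert np.all(np.diff(scan["train_r"]) >= -1e-10)

    def test_empty_grid_rejected(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        with pytest.raises(ValueError, match="non-empty"):
            pc_scan(encoded, splits[0], [])


class TestTrainingSizeScan:
    def test_reports_one_row_per_usable_fraction(self, small_benchmark):
        scan = training_size_scan(
            small_benchmark, [0.2, 0.5, 0.8], ART2aConfig(vigilance=VIG, seed=1), seed=1
        )
        assert list(scan["fraction"]) == [0.2, 0.5, 0.8]
        assert (scan["n_train"] + scan["n_test"] == small_benchmark.n_samples).all()

    def test_too_small_fraction_skipped_with_warning(self, small_benchmark, caplog):
        with caplog.at_level("WARNING"):
            scan = training_size_scan(
                small_benchmark, [0.001, 0.5], ART2aConfig(vigilance=VIG, seed=1), seed=1
            )
        assert len(scan) == 1
        assert "skipped" in caplog.text

    def test_empty_fraction_list_gives_empty_table(self, small_benchmark):
        scan = training_size_scan(small_benchmark, [], ART2aConfig(vigilance=VIG))
        assert len(scan) == 0

    def test_larger_training_sets_trend_upward(self, small_benchmark):
        scan = training_size_scan(
            small_benchmark, [0.1, 0.5, 0.9], ART2aConfig(vigilance=VIG, seed=2), seed=2
        )
        assert scan["test_r"].iloc[-1] > scan["test_r"].iloc[0]


class TestYScrambling:
    def test_scrambled_signal_collapses(self, clustered_benchmark):
        encoded, clustering = clustered_benchmark
        report = y_scramble_test(encoded, clustering, 5, 30, PLSConfig("all"), seed=0)
        assert report.original.mean("r", "test") >= 0.8
        assert abs(report.scrambled.mean("r", "test")) < 0.2
        assert report.reduction_pct_test >= 60.0

    def test_scramble_preserves_potency_multiset(self, clustered_benchmark):
        encoded, clustering = clustered_benchmark
        rng = np.random.default_rng(0)
        scrambled = rng.permutation(encoded.y)
        np.testing.assert_allclose(np.sort(scrambled), np.sort(encoded.y))

    def test_reduction_nan_when_original_nonpositive(self):
        from sibcut.validation import _reduction_pct

        assert np.isnan(_reduction_pct(-0.1, 0.05))
        assert _reduction_pct(0.8, 0.2) == pytest.approx(75.0)


class TestRelativeImportance:
    def test_single_nonzero_coefficient_dominates(self):
        labels = column_labels(2)
        coef = np.zeros(24)
        coef[13] = 2.5  # an nt2 column
        model = PLSModel(
            x_mean=np.zeros(24),
            x_scale=np.ones(24),
            y_mean=0.0,
            y_scale=1.0,
            weights=np.zeros((24, 1)),
            loadings=np.zeros((24, 1)),
            y_loadings=np.ones(1),
            coefficients=coef,
            n_components_used=1,
            column_labels=labels,
        )
        report = relative_importance([model], 2)
        assert report.per_column[labels[13]] == pytest.approx(1.0)
        assert report.top_positions(1) == ["nt2"]

    def test_marginals_sum_to_one(self, clustered_benchmark, splits):
        encoded, _ = clustered_benchmark
        _, models = multi_split_evaluation(
            encoded, splits[:3], PLSConfig("all"), return_models=True
        )
        report = relative_importance(models, 21)
        assert report.per_column.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.per_position.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.per_descriptor.sum() == pytest.approx(1.0, abs=1e-9)
        assert (report.per_column >= 0).all()

    def test_signal_planted_on_first_two_positions_recovered(self):
        encoded = huesken_shaped_benchmark(seed=5, n=300, n_nonzero=8, positions=(1, 2))
        clustering = art2a_cluster(encoded.X, ART2aConfig(vigilance=VIG, seed=5))
        splits = generate_splits(encoded, 4, 30, clustering=clustering, seed=5)
        _, models = multi_split_evaluation(
            encoded, splits, PLSConfig("all"), return_models=True
        )
        report = relative_importance(models, 21)
        assert set(report.top_positions(2)) == {"nt1", "nt2"}

    def test_all_zero_coefficients_rejected(self):
        labels = column_labels(1)
        model = PLSModel(
            x_mean=np.zeros(12),
            x_scale=np.ones(12),
            y_mean=0.0,
            y_scale=1.0,
            weights=np.zeros((12, 1)),
            loadings=np.zeros((12, 1)),
            y_loadings=np.zeros(1),
            coefficients=np.zeros(12),
            n_components_used=1,
            column_labels=labels,
        )
        with pytest.raises(ValueError, match="all-zero"):
            relative_importance([model], 1)
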