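"""Metrics, the repeated-CV protocol, and aggregation of results tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mieeg import accuracy, kappa
from mieeg.evaluation import (
    EvaluationReport,
    aggregate_table,
    cross_validate,
    fold_assignments,
    method_differences,
    reports_to_table,
    summarize_methods,
)
from mieeg.published import ACCURACY_2B, DATASET_III, KAPPA_2B


class MeanPixelClassifier:
    """Fast stand-in estimator: thresholds the mean pixel value."""

    def __init__(self, seed=0):
        self.threshold = 0.0

    def fit(self, x, y):
        m = x.reshape(len(x), -1).mean(axis=1)
        self.threshold = 0.5 * (m[y == 0].mean() + m[y == 1].mean())
        self.flip = m[y == 1].mean() < m[y == 0].mean()
        return self

    def predict(self, x):
        m = x.reshape(len(x), -1).mean(axis=1)
        pred = (m > self.threshold).astype(int)
        return 1 - pred if self.flip else pred


def _informative_images(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    x = 0.5 + np.where(y == 0, -0.1, 0.1)[:, None, None]
    x = x + 0.05 * rng.standard_normal((n, 8, 8))
    return x, y


class TestAccuracy:
    @pytest.mark.parametrize(
        "pred,true,expected",
        [
            (["L", "R"], ["L", "R"], 1.0),
            (["L", "L"], ["L", "R"], 0.5),
            (["L", "R", "L", "R"], ["L", "R", "R", "R"], 0.75),
        ],
    )
    def test_match_fractions(self, pred, true, expected):
        assert accuracy(pred, true) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy([1, 2], [1])


class TestKappa:
    @pytest.mark.parametrize(
        "p0,expected",
        [(0.907, 0.814), (0.954, 0.908), (0.5, 0.0), (1.0, 1.0)],
    )
    def test_values_at_chance_half(self, p0, expected):
        assert kappa(p0) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p0=st.floats(0, 1, allow_nan=False))
    def test_linearity_for_balanced_binary(self, p0):
        assert kappa(p0, 0.5) == pytest.approx(2 * p0 - 1, abs=1e-12)

    def test_degenerate_chance_rejected(self):
        with pytest.raises(ValueError):
            kappa(0.9, 1.0)
        with pytest.raises(ValueError):
            kappa(1.2)

    def test_published_accuracy_and_kappa_tables_are_consistent(self):
        """Every published per-subject kappa equals 2*accuracy - 1 to the
        printed precision, for all nine subjects."""
        acc = ACCURACY_2B["IS-CBAM-CNN"]
        kap = KAPPA_2B["IS-CBAM-CNN"]
        for a, k, a_sd, k_sd in zip(
            acc["mean"], kap["mean"], acc["std"], kap["std"]
        ):
            assert kappa(a / 100) == pytest.approx(k, abs=1.5e-3)
            assert 2 * a_sd / 100 == pytest.approx(k_sd, abs=1.5e-3)


class TestCrossValidation:
    def test_folds_partition_every_trial_each_repetition(self):
        y = np.tile([0, 1], 60)
        for folds in fold_assignments(y, seed=3, n_repetitions=4, n_folds=10):
            joined = np.sort(np.concatenate(folds))
            assert np.array_equal(joined, np.arange(120))

    def test_same_seed_reproduces_assignments_and_metrics(self):
        x, y = _informative_images()
        r1 = cross_validate(x, y, MeanPixelClassifier, seed=5, n_repetitions=2,
                            n_folds=5)
        r2 = cross_validate(x, y, MeanPixelClassifier, seed=5, n_repetitions=2,
                            n_folds=5)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)

    def test_informative_data_beats_chance(self):
        x, y = _informative_images()
        r = cross_validate(x, y, MeanPixelClassifier, seed=1, n_repetitions=2,
                           n_folds=5)
        assert r.mean_accuracy > 0.9

    def test_shuffled_labels_fall_to_chance(self):
        # average over several label permutations: any single permutation
        # keeps an O(1/sqrt(n)) accidental class difference
        x, y = _informative_images(n=200)
        rng = np.random.default_rng(9)
        means = []
        for _ in range(4):
            y_sh = y[rng.permutation(len(y))]
            r = cross_validate(x, y_sh, MeanPixelClassifier, seed=1,
                               n_repetitions=1, n_folds=5)
            means.append(r.mean_accuracy)
        assert abs(np.mean(means) - 0.5) < 0.08

    def test_too_few_trials_per_class_rejected(self):
        x, y = _informative_images(n=10)
        with pytest.raises(ValueError, match="per.*class|class"):
            cross_validate(x, y, MeanPixelClassifier, seed=0, n_folds=10)

    def test_report_kappa_is_linear_in_accuracy(self):
        r = EvaluationReport(
            variant="IS-CNN",
            fold_accuracies=np.array([[0.8, 0.9], [0.7, 1.0]]),
            seed=0,
        )
        assert r.mean_kappa == pytest.approx(2 * r.mean_accuracy - 1)
        assert r.kappa_std == pytest.approx(2 * r.accuracy_std)

    def test_report_round_trip_files(self, tmp_path):
        r = EvaluationReport(
            variant="UD-CNN", fold_accuracies=np.full((2, 3), 0.75), seed=4
        )
        r.to_json(tmp_path / "r.json")
        r.to_csv(tmp_path / "r.csv")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["variant"] == "UD-CNN"
        assert len(loaded["fold_accuracies"]) == 2


class TestAggregation:
    def test_summary_of_published_accuracies(self):
        s = summarize_methods(ACCURACY_2B)
        assert s.loc["IS-CBAM-CNN", "mean"] == pytest.approx(79.6, abs=0.05)
        assert s.loc["IS-CBAM-CNN", "mean_std"] == pytest.approx(1.8, abs=0.05)
        assert s.loc["IS-CBAM-CNN", "spread"] == pytest.approx(27.7, abs=1e-9)

    def test_mean_differences_against_competitors(self):
        d = method_differences(ACCURACY_2B, "IS-CBAM-CNN")
        assert d["BP-SVM"] == pytest.approx(9.4, abs=0.1)
        assert d["CNN-SAE"] == pytest.approx(2.0, abs=0.1)
        assert d["CapsNet"] == pytest.approx(1.2, abs=0.1)

    def test_dataset_iii_row_consistency(self):
        row = DATASET_III["IS-CBAM-CNN"]
        assert kappa(row["accuracy"] / 100) == pytest.approx(
            row["kappa"], abs=1e-3
        )

    def test_formatted_table_layout(self):
        t = aggregate_table(ACCURACY_2B, decimals=1)
        assert t.shape == (10, 4)
        assert t.loc["Average", "IS-CBAM-CNN"] == "79.6 ± 1.8"
        assert t.loc["1", "CapsNet"] == "78.8"
        k = aggregate_table(KAPPA_2B, decimals=3)
        assert k.loc["4", "IS-CBAM-CNN"] == "0.908 ± 0.012"

    def test_reports_adapter(self):
        reports = [
            EvaluationReport("IS-CNN", np.full((2, 2), 0.8), 0),
            EvaluationReport("UD-CNN", np.full((2, 2), 0.7), 0),
        ]
        table = reports_to_table(reports)
        assert table["IS-CNN"]["mean"][0] == pytest.approx(80.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_methods({})

    def test_unknown_reference_method_rejected(self):
        with pytest.raises(KeyError):
            method_differences(ACCURACY_2B, "nonexistent")
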