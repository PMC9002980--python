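"""Metrics, Cohen's Kappa and the cross-validated classifier benchmark."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, precision_score, recall_score

from sarcoemg import (CLASSIFIER_NAMES, cohens_kappa,
                      compare_with_without_selection, fixed_paper_subset,
                      make_classifier, metric_set, run_cv)
from sarcoemg.core_io import ValidationError
from sarcoemg.evaluation import kappa_band
from sarcoemg.features import FeatureMatrix


def _labels_from_confusion(c):
    """Expand a confusion matrix into (true, predicted) label vectors."""
    t, p = [], []
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            t += [i] * int(c[i, j])
            p += [j] * int(c[i, j])
    return np.array(t), np.array(p)


class TestKappa:
    def test_diagonal_matrix_is_perfect(self):
        k, band = cohens_kappa(np.diag([10, 20, 30]))
        assert k == 1.0 and band == "perfect"

    def test_hand_computed_2x2(self):
        """[[25,5],[10,60]]: po=0.85, pe=0.56, k=(0.85-0.56)/0.44."""
        c = np.array([[25, 5], [10, 60]])
        k, band = cohens_kappa(c)
        assert k == pytest.approx(0.29 / 0.44, abs=1e-9)
        assert k == pytest.approx(0.6591, abs=5e-4)
        assert band == "good"

    def test_matches_sklearn_on_random_confusions(self, rng):
        for _ in range(10):
            c = rng.integers(0, 30, size=(3, 3))
            c[0, 0] += 1  # non-degenerate
            t, p = _labels_from_confusion(c)
            k, _ = cohens_kappa(c)
            assert k == pytest.approx(cohen_kappa_score(t, p), abs=1e-12)

    def test_chance_level_simulation(self):
        """Uniform random predictions on n=10,000: kappa stays within 0.05
        of zero for every seed."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            t = r.integers(0, 3, size=10_000)
            p = r.integers(0, 3, size=10_000)
            c = np.zeros((3, 3), int)
            np.add.at(c, (t, p), 1)
            k, _ = cohens_kappa(c)
            assert abs(k) < 0.05

    def test_single_cell_diagonal_defined_as_one(self):
        k, band = cohens_kappa(np.array([[5, 0], [0, 0]]))
        assert k == 1.0 and band == "perfect"

    @pytest.mark.parametrize("k,expected", [
        (0.10, "slight"), (0.20, "slight"), (0.21, "fair"), (0.40, "fair"),
        (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"), (0.80, "good"),
        (0.81, "perfect"), (1.00, "perfect"), (-0.3, "slight"),
    ])
    def test_agreement_bands(self, k, expected):
        assert kappa_band(k) == expected


class TestMetricSet:
    def test_perfect_diagonal(self):
        m = metric_set(np.diag([5, 5, 5]))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.kappa) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)
        assert m.band == "perfect"

    def test_never_predicted_class_contributes_zero_precision(self):
        # class 2 (last column) never predicted
        c = np.array([[5, 0, 0], [0, 5, 0], [0, 5, 0]])
        m = metric_set(c)
        assert m.precision < 1.0
        assert m.recall == pytest.approx(2 / 3)

    def test_hand_count_oracle(self):
        """Small-integer 3x3 matrix: macro precision/recall from explicit
        one-vs-rest TP/FP/FN counts."""
        c = np.array([[3, 1, 0], [2, 5, 1], [0, 1, 4]])
        m = metric_set(c)
        # per class: TP=(3,5,4); FP=(2,2,1); FN=(1,3,1)
        prec = np.mean([3 / 5, 5 / 7, 4 / 5])
        rec = np.mean([3 / 4, 5 / 8, 4 / 5])
        assert m.precision == pytest.approx(prec, abs=1e-12)
        assert m.recall == pytest.approx(rec, abs=1e-12)
        assert m.accuracy == pytest.approx(12 / 17, abs=1e-12)
        t, p = _labels_from_confusion(c)
        assert m.precision == pytest.approx(
            precision_score(t, p, average="macro"), abs=1e-12)
        assert m.recall == pytest.approx(
            recall_score(t, p, average="macro"), abs=1e-12)

    def test_accuracy_equals_trace_over_total(self, rng):
        c = rng.integers(0, 20, size=(3, 3)) + 1
        m = metric_set(c)
        assert m.accuracy == pytest.approx(np.trace(c) / c.sum(), abs=1e-12)

    def test_kappa_below_accuracy_when_imperfect(self, rng):
        for _ in range(5):
            c = rng.integers(1, 20, size=(3, 3))
            m = metric_set(c)
            if m.accuracy < 1.0:
                assert m.kappa < m.accuracy


class TestClassifierFactory:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_all_eight_instantiate_and_fit(self, name, rng):
        X = rng.normal(size=(60, 5))
        y = np.repeat([1, 2, 3], 20)
        X[:, 0] += 3.0 * y
        clf = make_classifier(name, seed=0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
            acc = np.mean(clf.predict(X) == y)
        assert acc > 0.5

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError, match="unknown classifier"):
            make_classifier("GPT")


class TestRunCv:
    def test_report_shape_and_conservation(self, balanced_matrix):
        rep = run_cv(balanced_matrix, specs=("KNN", "DT"), folds=5, seed=3)
        assert set(rep.metrics_mean) == {"KNN", "DT"}
        for name in ("KNN", "DT"):
            c = rep.confusions[name]
            assert c.shape == (3, 3)
            assert c.sum() == balanced_matrix.n_instances
        assert sum(rep.fold_sizes) == balanced_matrix.n_instances

    def test_deterministic_under_seed(self, balanced_matrix):
        a = run_cv(balanced_matrix, specs=("KNN",), folds=5, seed=9)
        b = run_cv(balanced_matrix, specs=("KNN",), folds=5, seed=9)
        assert a.to_json() == b.to_json()

    def test_class_smaller_than_folds_rejected(self, feature_matrix):
        with pytest.raises(ValidationError, match="fewer folds"):
            run_cv(feature_matrix, specs=("KNN",), folds=10)

    def test_empty_spec_list_rejected(self, balanced_matrix):
        with pytest.raises(ValidationError, match="nonempty"):
            run_cv(balanced_matrix, specs=())

    def test_permuted_labels_are_chance_level(self, balanced_matrix):
        """Shuffling the labels must drop the benchmark to chance: mean
        accuracy near 1/3 and kappa near 0."""
        rng = np.random.default_rng(2)
        perm = FeatureMatrix(
            data=balanced_matrix.data,
            labels=pd.Series(rng.permutation(balanced_matrix.labels.to_numpy()),
                             index=balanced_matrix.data.index))
        rep = run_cv(perm, specs=("KNN", "DT"), folds=5, seed=2)
        accs = [rep.metrics_mean[n]["accuracy"] for n in ("KNN", "DT")]
        kappas = [rep.metrics_mean[n]["kappa"] for n in ("KNN", "DT")]
        assert 0.23 <= np.mean(accs) <= 0.43
        assert -0.15 <= np.mean(kappas) <= 0.15

    def test_in_fold_balancing_runs_and_keeps_test_original(self, balanced_matrix):
        rep = run_cv(balanced_matrix, specs=("KNN",), folds=5, seed=1,
                     balance_in_fold=True)
        assert sum(rep.fold_sizes) == balanced_matrix.n_instances
        assert rep.config["balance_in_fold"] is True

    def test_stratification_within_one_instance(self, balanced_matrix):
        from sklearn.model_selection import StratifiedKFold
        y = balanced_matrix.labels.to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        global_frac = {c: np.mean(y == c) for c in (1, 2, 3)}
        for _, te in skf.split(balanced_matrix.data, y):
            for c in (1, 2, 3):
                got = np.sum(y[te] == c)
                expected = global_frac[c] * len(te)
                assert abs(got - expected) <= 1.0


class TestSelectionComparison:
    def test_all_ones_mask_gives_zero_deltas(self, balanced_matrix):
        from sarcoemg.selection import FeatureMask
        mask = FeatureMask(mask=np.ones(48, bool),
                           columns=balanced_matrix.columns)
        out = compare_with_without_selection(balanced_matrix, mask,
                                             specs=("KNN", "DT"), folds=5,
                                             seed=4)
        for d in out["deltas"].values():
            assert d["accuracy"] == pytest.approx(0.0, abs=1e-12)
            assert d["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_report_table_mirrors_published_layout(self, balanced_matrix):
        mask = fixed_paper_subset(balanced_matrix.columns)
        rep = run_cv(balanced_matrix, specs=CLASSIFIER_NAMES[:2], folds=5,
                     seed=0, mask=mask)
        table = rep.table()
        assert list(table.columns[:4]) == ["Accuracy", "Precision", "Recall", "F1"]
        assert list(table.index) == ["SVM", "DT"]
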