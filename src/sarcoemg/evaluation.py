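"""Classifier benchmark: 10-fold CV, confusion matrices, Cohen's Kappa.

Eight supervised classifiers are compared at their published grid-search
optima.  Per fold, 90% of the data trains and 10% tests; a further 10% of
the training split is held out as a validation set (kept for contract
fidelity — of these estimators none consumes it during fitting, so it is
logged only).  Metrics are accuracy, macro precision/recall/F1 and Cohen's
Kappa with its qualitative agreement band; they are averaged over folds, and
the per-fold confusion matrices are summed into one 3x3 table
(rows = true level, columns = predicted level).

The XGB entry is realised with sklearn gradient boosting at the same printed
hyper-parameters, as the xgboost package is not available in the target
environment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalancingParams, smote_enn
from .core_io import ValidationError, logger
from .features import FeatureMatrix
from .selection import FeatureMask, apply_mask

CLASSIFIER_NAMES = ("SVM", "DT", "RF", "LR", "KNN", "NB", "MLP", "XGB")
LEVELS = (1, 2, 3)

#: Agreement bands for Cohen's Kappa (half-open so the published boundary
#: values 0.20/0.40/0.60/0.80 are all defined).
KAPPA_BANDS = (
    (0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
    (0.80, "good"), (1.00, "perfect"),
)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the eight benchmark classifiers at its published
    hyper-parameters."""
    if name == "SVM":
        return SVC(kernel="linear", C=0.1, max_iter=100,
                   decision_function_shape="ovo", random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", max_depth=10,
                                      random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=10, max_depth=10,
                                      criterion="gini", random_state=seed)
    if name == "LR":
        # one-vs-rest logistic regression (the multi_class flag left sklearn)
        return OneVsRestClassifier(LogisticRegression(
            solver="newton-cg", max_iter=50, C=0.001))
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="minkowski",
                                    algorithm="auto", weights="distance")
    if name == "NB":
        return GaussianNB(var_smoothing=1e-5)
    if name == "MLP":
        return MLPClassifier(activation="identity", alpha=1e-4,
                             hidden_layer_sizes=(10, 10), solver="lbfgs",
                             max_iter=500, random_state=seed)
    if name == "XGB":
        return GradientBoostingClassifier(learning_rate=0.001, max_depth=2,
                                          n_estimators=214, random_state=seed)
    raise ValidationError(f"unknown classifier {name!r}; "
                          f"expected one of {CLASSIFIER_NAMES}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def kappa_band(kappa: float) -> str:
    """Qualitative agreement label for a Kappa value."""
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "perfect"


def cohens_kappa(confusion: np.ndarray) -> tuple[float, str]:
    """Chance-corrected agreement from a square confusion matrix.

    ``po`` is the observed agreement (trace/total), ``pe`` the agreement
    expected by chance from the marginals; kappa = (po - pe) / (1 - pe).
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    total = c.sum()
    if total <= 0:
        raise ValidationError("confusion matrix total must be > 0")
    po = np.trace(c) / total
    pe = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total ** 2)
    if pe == 1.0:
        if po == 1.0:
            return 1.0, kappa_band(1.0)
        raise ValidationError("kappa undefined: chance agreement pe = 1 with po < 1")
    k = float((po - pe) / (1.0 - pe))
    return k, kappa_band(k)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    band: str

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "kappa": self.kappa,
                "band": self.band}


def metric_set(confusion: np.ndarray) -> MetricSet:
    """Accuracy, macro precision/recall/F1 and Kappa from a confusion matrix.

    Per class (one vs rest): precision = TP/(TP+FP) (0 when the class is
    never predicted), recall = TP/(TP+FN), F1 = 2PR/(P+R) (harmonic mean);
    macro averages treat the classes equally.
    """
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("confusion matrix total must be > 0")
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    kappa, band = cohens_kappa(c)
    return MetricSet(accuracy=float(np.trace(c) / total),
                     precision=float(prec.mean()), recall=float(rec.mean()),
                     f1=float(f1.mean()), kappa=kappa, band=band)


# ---------------------------------------------------------------------------
# cross-validated benchmark
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-classifier fold-averaged metrics and summed confusion matrices."""

    metrics_mean: dict[str, dict]          # classifier -> metric -> mean
    metrics_sd: dict[str, dict]            # classifier -> metric -> sd over folds
    confusions: dict[str, np.ndarray]      # classifier -> 3x3 int array
    pooled: dict[str, dict]                # metrics on pooled predictions
    fold_sizes: list[int]
    folds: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_instances(self) -> int:
        return int(sum(self.fold_sizes))

    def table(self) -> pd.DataFrame:
        """Rows = classifiers, columns = Accuracy/Precision/Recall/F1/Kappa."""
        rows = {}
        for name, m in self.metrics_mean.items():
            rows[name] = {"Accuracy": m["accuracy"], "Precision": m["precision"],
                          "Recall": m["recall"], "F1": m["f1"],
                          "Kappa": m["kappa"], "Agreement": m["band"]}
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "folds": self.folds, "seed": self.seed, "config": self.config,
            "fold_sizes": self.fold_sizes,
            "metrics_mean": self.metrics_mean, "metrics_sd": self.metrics_sd,
            "pooled": self.pooled,
            "confusions": {k: v.tolist() for k, v in self.confusions.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _mean_sd(per_fold: list[MetricSet]) -> tuple[dict, dict]:
    keys = ("accuracy", "precision", "recall", "f1", "kappa")
    mean = {k: float(np.mean([getattr(m, k) for m in per_fold])) for k in keys}
    sd = {k: float(np.std([getattr(m, k) for m in per_fold])) for k in keys}
    mean["band"] = kappa_band(mean["kappa"])
    return mean, sd


def run_cv(fm: FeatureMatrix, specs: tuple[str, ...] = CLASSIFIER_NAMES,
           folds: int = 10, seed: int = 0, balance_in_fold: bool = False,
           mask: FeatureMask | None = None,
           balance_params: BalancingParams | None = None) -> EvaluationReport:
    """Stratified k-fold benchmark of the named classifiers.

    When ``balance_in_fold`` is set, SMOTE+ENN is fit on each fold's training
    portion only, so test folds never contain synthetic instances.  The
    feature mask (if any) is applied after balancing.  Fully deterministic
    under ``seed``.
    """
    if not specs:
        raise ValidationError("specs must be nonempty")
    counts = fm.class_counts()
    lacking = {c: n for c, n in counts.items() if n < folds}
    if lacking:
        raise ValidationError(
            f"classes {lacking} have fewer instances than {folds} folds; "
            "use fewer folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = fm.data.index.to_numpy()
    y_all = fm.labels.to_numpy()

    per_fold: dict[str, list[MetricSet]] = {name: [] for name in specs}
    confusions = {name: np.zeros((len(LEVELS), len(LEVELS)), dtype=int)
                  for name in specs}
    pooled_true: list[np.ndarray] = []
    pooled_pred: dict[str, list[np.ndarray]] = {name: [] for name in specs}
    fold_sizes: list[int] = []

    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(fm.data, y_all)):
        assert not set(ids[tr_idx]) & set(ids[te_idx])
        train = FeatureMatrix(data=fm.data.iloc[tr_idx], labels=fm.labels.iloc[tr_idx])
        test = FeatureMatrix(data=fm.data.iloc[te_idx], labels=fm.labels.iloc[te_idx])

        # inner validation split: 10% of the training data, held out.
        # Skipped when the training fold is too small to stratify it.
        n_classes = train.labels.nunique()
        if int(0.1 * len(tr_idx)) >= n_classes:
            fit_ids, val_ids = train_test_split(
                train.data.index, test_size=0.1, random_state=seed + fold_i,
                stratify=train.labels)
            logger.debug("fold %d: %d fit / %d validation / %d test instances",
                         fold_i, len(fit_ids), len(val_ids), len(te_idx))
            fit = FeatureMatrix(data=train.data.loc[fit_ids],
                                labels=train.labels.loc[fit_ids])
        else:
            logger.debug("fold %d: training fold too small for a validation "
                         "split; fitting on all %d", fold_i, len(tr_idx))
            fit = train

        if balance_in_fold:
            fit = smote_enn(fit, balance_params or BalancingParams(seed=seed + fold_i))
        if mask is not None:
            fit = apply_mask(fit, mask)
            test_m = apply_mask(test, mask)
        else:
            test_m = test

        X_tr, y_tr = fit.data.to_numpy(), fit.labels.to_numpy()
        X_te, y_te = test_m.data.to_numpy(), test_m.labels.to_numpy()
        fold_sizes.append(len(y_te))
        pooled_true.append(y_te)

        for name in specs:
            clf = make_classifier(name, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X_tr, y_tr)
                pred = clf.predict(X_te)
            c = _sk_confusion(y_te, pred, labels=list(LEVELS))
            confusions[name] += c
            per_fold[name].append(metric_set(c))
            pooled_pred[name].append(pred)

    metrics_mean, metrics_sd, pooled = {}, {}, {}
    y_true = np.concatenate(pooled_true)
    for name in specs:
        metrics_mean[name], metrics_sd[name] = _mean_sd(per_fold[name])
        c_pooled = _sk_confusion(y_true, np.concatenate(pooled_pred[name]),
                                 labels=list(LEVELS))
        pooled[name] = metric_set(c_pooled).as_dict()
        assert int(confusions[name].sum()) == len(y_true)

    return EvaluationReport(
        metrics_mean=metrics_mean, metrics_sd=metrics_sd, confusions=confusions,
        pooled=pooled, fold_sizes=fold_sizes, folds=folds, seed=seed,
        config={"balance_in_fold": balance_in_fold,
                "mask": None if mask is None else mask.selected,
                "classifiers": list(specs)})


def compare_with_without_selection(fm: FeatureMatrix, mask: FeatureMask,
                                   specs: tuple[str, ...] = CLASSIFIER_NAMES,
                                   folds: int = 10, seed: int = 0,
                                   balance_in_fold: bool = False,
                                   ) -> dict:
    """Benchmark with all features vs the masked subset; report deltas."""
    full = run_cv(fm, specs, folds=folds, seed=seed,
                  balance_in_fold=balance_in_fold)
    masked = run_cv(fm, specs, folds=folds, seed=seed,
                    balance_in_fold=balance_in_fold, mask=mask)
    deltas = {
        name: {
            "accuracy": masked.metrics_mean[name]["accuracy"]
                        - full.metrics_mean[name]["accuracy"],
            "kappa": masked.metrics_mean[name]["kappa"]
                     - full.metrics_mean[name]["kappa"],
        }
        for name in specs
    }
    return {"without_selection": full, "with_selection": masked, "deltas": deltas}


def plot_confusion_matrices(report: EvaluationReport, path: str | Path) -> Path:
    """Write a grid of per-classifier confusion-matrix heatmaps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.confusions)
    ncols = min(4, len(names))
    nrows = -(-len(names) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, name in zip(axes.ravel(), names):
        ax.set_visible(True)
        c = report.confusions[name]
        ax.imshow(c, cmap="Blues")
        for i in range(c.shape[0]):
            for j in range(c.shape[1]):
                ax.text(j, i, str(int(c[i, j])), ha="center", va="center")
        ax.set_title(name)
        ax.set_xticks(range(len(LEVELS)), [str(v) for v in LEVELS])
        ax.set_yticks(range(len(LEVELS)), [str(v) for v in LEVELS])
        ax.set_xlabel("predicted level")
        ax.set_ylabel("true level")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
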