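"""Diagnosis and severity classification with repeated holdout evaluation.

Three labelling schemes are supported: binary PD vs healthy control
(PDHC), the six Hoehn & Yahr classes (stage 0 for controls, 1-5 for
patients), and four motor-score severity classes (HC, mild <= 32,
moderate 33-58, severe >= 59 on the MDS-UPDRS Part III total).

The evaluation protocol is a repeated 9:1 holdout: for each repeat the
cohort is split 90/10 (stratified where feasible), each model family is
tuned by grid search with inner cross-validation on the training portion
only, refit on the full training split, and scored on the held-out 10%.
Metrics are accuracy N_c/N_t and weighted precision/recall/F1,
W = sum_i(w_i X_i) / sum_i(w_i) with w_i the per-class test counts,
because the severity classes are highly imbalanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .datamodel import FeatureTable, SubjectRecord

log = logging.getLogger(__name__)

SCHEMES = ("PDHC", "HY", "UPDRS")
UPDRS_CLASSES = ("HC", "mild", "moderate", "severe")
#: printed severity cut-offs on the motor score: mild/moderate at 32/33,
#: moderate/severe at 58/59
UPDRS_MILD_MAX = 32
UPDRS_MODERATE_MAX = 58

MODEL_NAMES = ("linear_nn", "svm", "logistic_regression", "random_forest", "xgboost")


# ---------------------------------------------------------------------------
# labelling

def label_pdhc(record: SubjectRecord) -> str:
    return record.group


def label_hy(record: SubjectRecord) -> int:
    """H&Y class: stage 0 for controls, the clinical stage 1-5 for PD."""
    if record.group == "HC":
        return 0
    if not (1 <= record.hy_stage <= 5):
        raise ValueError(f"PD subject {record.subject_id} has hy_stage {record.hy_stage}")
    return int(record.hy_stage)


def label_updrs(record: SubjectRecord) -> str:
    """Severity class from the motor score: HC, mild (<=32),
    moderate (33-58), severe (>=59)."""
    if record.updrs3_score < 0:
        raise ValueError("updrs3_score must be >= 0")
    if record.group == "HC":
        return "HC"
    if record.updrs3_score <= UPDRS_MILD_MAX:
        return "mild"
    if record.updrs3_score <= UPDRS_MODERATE_MAX:
        return "moderate"
    return "severe"


def scheme_labels(table: FeatureTable, scheme: str) -> np.ndarray:
    """Per-subject class labels for a scheme from the table's label columns."""
    lab = table.labels
    if scheme == "PDHC":
        return lab["group"].to_numpy()
    if scheme == "HY":
        return np.where(lab["group"] == "HC", 0, lab["hy_stage"]).astype(int)
    if scheme == "UPDRS":
        score = lab["updrs3_score"].to_numpy()
        out = np.where(lab["group"] == "HC", "HC",
                       np.where(score <= UPDRS_MILD_MAX, "mild",
                                np.where(score <= UPDRS_MODERATE_MAX, "moderate",
                                         "severe")))
        return out
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


# ---------------------------------------------------------------------------
# metrics

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def evaluate_metrics(truth, predicted) -> MetricSet:
    """Accuracy plus weighted precision/recall/F1 over the test classes.

    Weights are the per-class counts in ``truth``; undefined per-class
    ratios (a class never predicted) contribute 0.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise ValueError("empty label vectors")
    p, r, f, _ = precision_recall_fscore_support(
        truth, predicted, average="weighted", zero_division=0)
    return MetricSet(float(accuracy_score(truth, predicted)),
                     float(p), float(r), float(f))


# ---------------------------------------------------------------------------
# models

def build_models(seed: int, models: tuple[str, ...] = MODEL_NAMES,
                 ) -> dict[str, tuple[Pipeline, dict]]:
    """Model families with small published hyperparameter grids.

    Linear families (single-layer linear network trained with
    cross-entropy, SVM, logistic regression) see z-scored features; tree
    ensembles consume raw features.
    """
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("model", est)])  # noqa: E731
    raw = lambda est: Pipeline([("model", est)])  # noqa: E731
    registry: dict[str, tuple[Pipeline, dict]] = {
        "linear_nn": (
            scaled(SGDClassifier(loss="log_loss", max_iter=2000, tol=1e-3,
                                 random_state=seed)),
            {"model__alpha": [1e-4, 1e-3, 1e-2]},
        ),
        "svm": (
            scaled(SVC(random_state=seed)),
            {"model__C": [0.1, 1.0, 10.0], "model__kernel": ["linear", "rbf"]},
        ),
        "logistic_regression": (
            scaled(LogisticRegression(max_iter=5000)),
            {"model__C": [0.1, 1.0, 10.0]},
        ),
        "random_forest": (
            raw(RandomForestClassifier(random_state=seed)),
            {"model__n_estimators": [100], "model__max_depth": [None, 5]},
        ),
        "xgboost": (
            raw(XGBClassifier(random_state=seed, verbosity=0, n_jobs=1,
                              eval_metric="logloss")),
            {"model__n_estimators": [50, 100], "model__max_depth": [2, 4]},
        ),
    }
    unknown = set(models) - set(registry)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")
    return {name: registry[name] for name in models}


@dataclass(frozen=True)
class ExperimentConfig:
    scheme: str = "PDHC"
    models: tuple[str, ...] = MODEL_NAMES
    n_repeats: int = 100
    test_fraction: float = 0.1
    inner_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def replace(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


@dataclass
class ExperimentResult:
    """Per-repeat metrics for each model plus mean/SD summaries."""

    scheme: str
    per_repeat: dict[str, pd.DataFrame]  # model -> repeats x METRICS
    classes: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for model, df in self.per_repeat.items():
            row = {}
            for m in METRICS:
                row[f"{m}_mean"] = df[m].mean()
                row[f"{m}_sd"] = df[m].std(ddof=1) if len(df) > 1 else 0.0
            rows[model] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def mean_accuracy(self, model: str) -> float:
        return float(self.per_repeat[model]["accuracy"].mean())

    def best_model(self) -> str:
        """Model family with the highest mean accuracy (ties: first in
        registry order)."""
        best, best_acc = None, -1.0
        for model, df in self.per_repeat.items():
            acc = df["accuracy"].mean()
            if acc > best_acc:
                best, best_acc = model, acc
        return best

    def to_results_table(self) -> pd.DataFrame:
        """Models x metrics table formatted 'mean (SD)'."""
        s = self.summary()
        out = pd.DataFrame(index=s.index)
        for m in METRICS:
            out[m] = [f"{s.loc[i, f'{m}_mean']:.3f} ({s.loc[i, f'{m}_sd']:.3f})"
                      for i in s.index]
        return out


def _split_indices(y: np.ndarray, test_fraction: float, rs: int):
    """Stratified 90/10 split, falling back to unstratified when some
    class is a singleton (too small to stratify)."""
    idx = np.arange(len(y))
    _, counts = np.unique(y, return_counts=True)
    n_test = max(1, int(round(test_fraction * len(y))))
    stratify = y if (counts.min() >= 2 and n_test >= len(counts)) else None
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=rs,
                              stratify=stratify)
    return tr, te


def _inner_cv(y_train: np.ndarray, folds: int, rs: int):
    _, counts = np.unique(y_train, return_counts=True)
    k = min(folds, int(counts.min()), len(y_train) - 1)
    if k >= 2 and counts.min() >= k:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
    return KFold(n_splits=max(2, min(folds, len(y_train) - 1)), shuffle=True,
                 random_state=rs)


def run_experiment(table: FeatureTable, config: ExperimentConfig) -> ExperimentResult:
    """Repeated 9:1 holdout with leakage-free grid search per model.

    Splits are a deterministic function of the config seed and the label
    vector only, so two tables with the same subjects and labels (e.g. an
    all-features and a task-subset table) share identical split sequences.
    """
    config.validate()
    X = table.features.to_numpy(dtype=float)
    y_raw = scheme_labels(table, config.scheme)
    classes, y = np.unique(y_raw, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present to classify")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repeats)
    per_repeat = {m: [] for m in config.models}
    for rep in range(config.n_repeats):
        rs = int(seeds[rep] % (2**31 - 1))
        tr, te = _split_indices(y, config.test_fraction, rs)
        if len(np.unique(y[tr])) < 2:
            log.warning("repeat %d: training split has a single class; skipped", rep)
            continue
        cv = _inner_cv(y[tr], config.inner_folds, rs)
        for name, (pipe, grid) in build_models(rs, config.models).items():
            search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
            search.fit(X[tr], y[tr])
            pred = search.best_estimator_.predict(X[te])
            per_repeat[name].append(evaluate_metrics(y[te], pred).as_dict())
    frames = {m: pd.DataFrame(rows, columns=list(METRICS))
              for m, rows in per_repeat.items()}
    cls = [c.item() if hasattr(c, "item") else c for c in classes]
    return ExperimentResult(config.scheme, frames, classes=cls)


def fit_best_model(table: FeatureTable, config: ExperimentConfig,
                   result: ExperimentResult | None = None):
    """Refit the best model family (by mean holdout accuracy) on the full
    cohort, tuned by cross-validation; returns (fitted estimator, name,
    class labels)."""
    if result is None:
        result = run_experiment(table, config)
    name = result.best_model()
    X = table.features.to_numpy(dtype=float)
    y_raw = scheme_labels(table, config.scheme)
    classes, y = np.unique(y_raw, return_inverse=True)
    rs = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31 - 1))
    pipe, grid = build_models(rs, (name,))[name]
    cv = _inner_cv(y, config.inner_folds, rs)
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, name, list(classes)
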