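"""Label schemes, metric formulas and the repeated-holdout protocol."""

import numpy as np
import pandas as pd
import pytest

from pdscreen import (
    ExperimentConfig,
    FeatureTable,
    evaluate_metrics,
    label_hy,
    label_pdhc,
    label_updrs,
    run_experiment,
)
from pdscreen.classify import scheme_labels
from pdscreen.datamodel import SubjectRecord


def subject(group, score=10, stage=None):
    stage = stage if stage is not None else (2 if group == "PD" else 0)
    return SubjectRecord("s", group, score, stage, 28, 70, "F")


# ---------------------------------------------------------------------------
# labelling

@pytest.mark.parametrize("score,expected", [
    (8, "mild"), (32, "mild"),            # mild <= 32
    (33, "moderate"), (58, "moderate"),   # 33 <= moderate <= 58
    (59, "severe"), (68, "severe"),       # severe >= 59
])
def test_updrs_cutoffs(score, expected):
    assert label_updrs(subject("PD", score)) == expected


def test_updrs_hc_and_errors():
    assert label_updrs(subject("HC", 30)) == "HC"
    with pytest.raises(ValueError):
        label_updrs(subject("PD", -1))


def test_hy_labels():
    assert label_hy(subject("HC")) == 0
    assert label_hy(subject("PD", stage=3)) == 3
    bad = SubjectRecord("s", "PD", 10, 0, 28, 70, "F")
    with pytest.raises(ValueError):
        label_hy(bad)
    assert label_pdhc(subject("PD")) == "PD"


def test_scheme_class_sets(small_table):
    assert set(scheme_labels(small_table, "PDHC")) <= {"PD", "HC"}
    assert set(scheme_labels(small_table, "HY")) <= set(range(6))
    assert set(scheme_labels(small_table, "UPDRS")) <= {"HC", "mild", "moderate",
                                                        "severe"}


# ---------------------------------------------------------------------------
# metrics vs a from-scratch confusion-matrix oracle

def metrics_oracle(truth, pred):
    """Accuracy + weighted precision/recall/F1 from an explicitly built
    confusion matrix, with 0 for undefined per-class ratios."""
    classes = sorted(set(truth) | set(pred))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[idx[t], idx[p]] += 1
    acc = np.trace(cm) / cm.sum()
    weights = cm.sum(axis=1)  # per-class truth counts
    prec = rec = f1 = 0.0
    for i in range(len(classes)):
        tp = cm[i, i]
        p_i = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        r_i = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
        f_i = 2 * p_i * r_i / (p_i + r_i) if (p_i + r_i) else 0.0
        prec += weights[i] * p_i
        rec += weights[i] * r_i
        f1 += weights[i] * f_i
    w = weights.sum()
    return acc, prec / w, rec / w, f1 / w


def test_metric_basics():
    truth = list("AAAAABBBBB")
    pred = list("AAAABBBBAA")  # 7 of 10 correct
    m = evaluate_metrics(truth, pred)
    assert m.accuracy == pytest.approx(7 / 10)
    m = evaluate_metrics(list("ABAB"), list("ABAB"))
    assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        evaluate_metrics(["A"], ["A", "B"])


def test_metrics_match_confusion_matrix_oracle_on_random_vectors():
    rng = np.random.default_rng(8)
    for _ in range(300):
        n = int(rng.integers(2, 40))
        k = int(rng.integers(2, 5))
        truth = rng.integers(0, k, n)
        pred = rng.integers(0, k, n)
        m = evaluate_metrics(truth, pred)
        acc, p, r, f = metrics_oracle(list(truth), list(pred))
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert m.precision == pytest.approx(p, abs=1e-12)
        assert m.recall == pytest.approx(r, abs=1e-12)
        assert m.f1 == pytest.approx(f, abs=1e-12)


def test_metrics_invariant_to_class_relabelling():
    rng = np.random.default_rng(9)
    truth = rng.integers(0, 3, 30)
    pred = rng.integers(0, 3, 30)
    relabel = {0: "x", 1: "y", 2: "z"}
    a = evaluate_metrics(truth, pred)
    b = evaluate_metrics([relabel[t] for t in truth], [relabel[p] for p in pred])
    assert a == b


# ---------------------------------------------------------------------------
# repeated holdout

FAST = ("logistic_regression", "random_forest")


def test_experiment_beats_chance_on_separable_cohort(small_table):
    cfg = ExperimentConfig(scheme="PDHC", models=FAST, n_repeats=4, seed=1)
    res = run_experiment(small_table, cfg)
    for model in FAST:
        assert res.mean_accuracy(model) > 0.5
    summary = res.summary()
    assert ((summary >= 0) & (summary <= 1)).all().all()


def test_experiment_is_reproducible(small_table):
    cfg = ExperimentConfig(scheme="PDHC", models=("logistic_regression",),
                           n_repeats=2, seed=5)
    a = run_experiment(small_table, cfg)
    b = run_experiment(small_table, cfg)
    pd.testing.assert_frame_equal(a.per_repeat["logistic_regression"],
                                  b.per_repeat["logistic_regression"])


def test_permuted_labels_give_chance_accuracy(small_table):
    """With labels randomly permuted, accuracy falls to ~majority rate."""
    table = FeatureTable(small_table.features.copy(), small_table.labels.copy())
    rng = np.random.default_rng(3)
    table.labels["group"] = rng.permutation(table.labels["group"].to_numpy())
    cfg = ExperimentConfig(scheme="PDHC", models=("logistic_regression",),
                           n_repeats=15, seed=2)
    res = run_experiment(table, cfg)
    majority = table.labels["group"].value_counts(normalize=True).max()
    assert res.mean_accuracy("logistic_regression") < majority + 0.15


def test_single_class_table_rejected(small_table):
    table = FeatureTable(small_table.features.copy(), small_table.labels.copy())
    table.labels["group"] = "PD"
    with pytest.raises(ValueError, match="2 classes"):
        run_experiment(table, ExperimentConfig(scheme="PDHC", n_repeats=1))


def test_best_model_and_results_table(small_table):
    cfg = ExperimentConfig(scheme="PDHC", models=FAST, n_repeats=2, seed=0)
    res = run_experiment(small_table, cfg)
    assert res.best_model() in FAST
    tab = res.to_results_table()
    assert list(tab.columns) == ["accuracy", "precision", "recall", "f1"]
    assert "(" in tab.iloc[0, 0]  # 'mean (SD)' formatting
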