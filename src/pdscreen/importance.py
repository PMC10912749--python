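"""Shapley-value feature and task importance for fitted classifiers.

The attribution of a prediction to its features follows the additive
explanation model g(x') = phi_0 + sum_j phi_j x'_j over simplified binary
inputs x' in {0,1}^M, where phi_0 is the model output with every feature
"absent" and phi_j is the Shapley value of feature j.  Absence is
realized by substituting the background reference value (cohort median by
default) for the feature.

Shapley values are computed by exact subset enumeration when the number
of features M <= ``exact_max_features`` and otherwise by antithetic
permutation sampling (each sampled permutation is paired with its
reverse).  Both estimators satisfy local accuracy exactly:
phi_0 + sum_j phi_j equals the model output for every explained sample,
because each permutation's marginal contributions telescope from the
background output to the full output.

Global feature importance is the mean absolute Shapley value over all
explained samples (per class for multi-class models); task importance is
the sum of those values over a task's features restricted to the global
top-k (k=10 by default), so a task with many weak features cannot outrank
one with a few strong features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .classify import ExperimentConfig, ExperimentResult, fit_best_model, run_experiment
from .datamodel import FeatureTable, feature_task


@dataclass(frozen=True)
class ImportanceConfig:
    top_k: int = 10
    n_permutations: int = 32        # antithetic: must be even
    exact_max_features: int = 12
    seed: int = 0

    def replace(self, **kw) -> "ImportanceConfig":
        return replace(self, **kw)


@dataclass
class AttributionSet:
    """Per-sample, per-feature (per-class) Shapley values.

    ``values`` has shape (n_samples, n_features, n_classes);
    ``base_values`` has shape (n_classes,) and is the expected model
    output with all features absent (evaluated at the background).
    """

    values: np.ndarray
    base_values: np.ndarray
    feature_names: list[str]
    class_names: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def local_accuracy_residual(self, outputs: np.ndarray) -> float:
        """Max abs deviation of phi_0 + sum_j phi_j from the model outputs
        (shape (n_samples, n_classes))."""
        recon = self.base_values[None, :] + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - outputs)))


def _model_output(model, X: np.ndarray) -> np.ndarray:
    """Per-class scores as an (n, n_classes) array."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X), dtype=float)
    if hasattr(model, "decision_function"):
        out = np.asarray(model.decision_function(X), dtype=float)
        if out.ndim == 1:
            out = np.column_stack([-out, out])
        return out
    raise ValueError("model exposes neither predict_proba nor decision_function")


def _shapley_exact_sample(model, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values for one sample by enumerating all feature
    subsets; returns (M, n_classes)."""
    M = len(x)
    masks = []
    subsets = []
    for size in range(M + 1):
        for comb in combinations(range(M), size):
            masks.append(comb)
    rows = np.tile(background, (len(masks), 1))
    for i, comb in enumerate(masks):
        rows[i, list(comb)] = x[list(comb)]
    outputs = _model_output(model, rows)
    index = {comb: i for i, comb in enumerate(masks)}
    n_classes = outputs.shape[1]
    phi = np.zeros((M, n_classes))
    fact = [factorial(k) for k in range(M + 1)]
    for j in range(M):
        others = [f for f in range(M) if f != j]
        for size in range(M):
            w = fact[size] * fact[M - size - 1] / fact[M]
            for comb in combinations(others, size):
                with_j = tuple(sorted(comb + (j,)))
                phi[j] += w * (outputs[index[with_j]] - outputs[index[comb]])
    return phi


def _shapley_sampling_sample(model, x: np.ndarray, background: np.ndarray,
                             permutations: np.ndarray) -> np.ndarray:
    """Permutation-sampling Shapley values for one sample.

    For each permutation, features are switched from background to the
    sample's values one at a time; the marginal output changes are
    credited to the switched feature.  Contributions telescope, so the
    estimate satisfies local accuracy exactly for any permutation set.
    """
    M = len(x)
    P = len(permutations)
    # rows: for each permutation, the M+1 prefix-substituted inputs
    rows = np.tile(background, (P * (M + 1), 1))
    for p, perm in enumerate(permutations):
        base = p * (M + 1)
        for step, j in enumerate(perm):
            rows[base + step + 1] = rows[base + step]
            rows[base + step + 1, j] = x[j]
    outputs = _model_output(model, rows)
    n_classes = outputs.shape[1]
    phi = np.zeros((M, n_classes))
    for p, perm in enumerate(permutations):
        base = p * (M + 1)
        diffs = outputs[base + 1: base + M + 1] - outputs[base: base + M]
        phi[perm] += diffs
    return phi / P


def shapley_attributions(model, X: np.ndarray, background: np.ndarray,
                         feature_names: list[str] | None = None,
                         class_names: list | None = None,
                         config: ImportanceConfig | None = None) -> AttributionSet:
    """Shapley attributions of per-class model outputs for each row of X.

    ``background`` is the single reference vector realizing feature
    absence.  Exact enumeration is used for M <= config.exact_max_features,
    antithetic permutation sampling otherwise.
    """
    config = config or ImportanceConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.asarray(background, dtype=float).ravel()
    if background.size != X.shape[1]:
        raise ValueError("background length does not match feature count")
    n, M = X.shape
    base = _model_output(model, background[None, :])[0]
    exact = M <= config.exact_max_features
    if not exact:
        rng = np.random.default_rng(config.seed)
        half = max(1, config.n_permutations // 2)
        perms = []
        for _ in range(half):
            p = rng.permutation(M)
            perms.append(p)
            perms.append(p[::-1])  # antithetic pair
        permutations = np.array(perms)
    values = np.zeros((n, M, len(base)))
    for i in range(n):
        if exact:
            values[i] = _shapley_exact_sample(model, X[i], background)
        else:
            values[i] = _shapley_sampling_sample(model, X[i], background, permutations)
    return AttributionSet(values, base, list(feature_names or map(str, range(M))),
                          list(class_names or []))


@dataclass
class GlobalImportance:
    """Mean absolute Shapley value per feature (columns = classes)."""

    per_class: pd.DataFrame  # features x classes
    total: pd.Series         # per-feature sum over classes

    def ranking(self) -> list[str]:
        """Features by descending total importance, ties broken
        lexicographically by name."""
        order = sorted(self.total.index, key=lambda f: (-self.total[f], f))
        return order


def global_importance(att: AttributionSet) -> GlobalImportance:
    if att.values.shape[0] < 1:
        raise ValueError("need at least one explained sample")
    mean_abs = np.abs(att.values).mean(axis=0)  # (M, n_classes)
    cols = att.class_names or list(range(mean_abs.shape[1]))
    df = pd.DataFrame(mean_abs, index=att.feature_names, columns=[str(c) for c in cols])
    return GlobalImportance(df, df.sum(axis=1))


@dataclass
class TaskImportance:
    """Per-task sums of top-k feature importances (+ per-class breakdown)."""

    total: pd.Series           # task id -> importance (0 for absent tasks)
    per_class: pd.DataFrame    # tasks x classes
    top_features: list[str]

    def ranking(self) -> list[int]:
        return sorted(self.total.index, key=lambda t: (-self.total[t], t))


def task_importance(gi: GlobalImportance, k: int = 10,
                    tasks: tuple[int, ...] = tuple(range(1, 12))) -> TaskImportance:
    """Sum the top-k features' mean-abs Shapley values within each task.

    Multi-class importances are ranked by the per-feature sum over
    classes; tasks contributing no top-k feature score 0.
    """
    top = gi.ranking()[:max(0, k)]
    total = pd.Series(0.0, index=list(tasks))
    per_class = pd.DataFrame(0.0, index=list(tasks), columns=gi.per_class.columns)
    for feat in top:
        task = feature_task(feat)
        total[task] += gi.total[feat]
        per_class.loc[task] += gi.per_class.loc[feat]
    return TaskImportance(total, per_class, top)


def explain_experiment(table: FeatureTable, config: ExperimentConfig,
                       imp_config: ImportanceConfig | None = None,
                       result: ExperimentResult | None = None,
                       ) -> tuple[AttributionSet, GlobalImportance, TaskImportance, str]:
    """Full importance analysis for one labelling scheme.

    The best model family by mean holdout accuracy is refit on the whole
    cohort and explained on every subject against the cohort-median
    background.
    """
    imp_config = imp_config or ImportanceConfig()
    model, name, classes = fit_best_model(table, config, result)
    X = table.features.to_numpy(dtype=float)
    background = np.median(X, axis=0)
    att = shapley_attributions(model, X, background,
                               feature_names=table.feature_names,
                               class_names=classes, config=imp_config)
    gi = global_importance(att)
    ti = task_importance(gi, imp_config.top_k)
    return att, gi, ti, name


@dataclass
class AblationResult:
    all_features: ExperimentResult
    task_only: ExperimentResult
    task_id: int

    def accuracy_table(self) -> pd.DataFrame:
        """Per-model mean accuracy with standard error for both arms."""
        rows = {}
        for model in self.all_features.per_repeat:
            a = self.all_features.per_repeat[model]["accuracy"]
            t = self.task_only.per_repeat[model]["accuracy"]
            rows[model] = {
                "all_mean": a.mean(),
                "all_se": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0,
                "task_only_mean": t.mean(),
                "task_only_se": t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0,
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def ablation_experiment(table: FeatureTable, config: ExperimentConfig,
                        task_id: int = 2) -> AblationResult:
    """Compare classification on all features vs features of one task.

    Both arms use identical seeds, hence identical split sequences (the
    splits depend only on labels and the seed, not on the feature set).
    """
    sub = table.task_subset(task_id)
    if not sub.feature_names:
        raise ValueError(f"table has no task-{task_id} features")
    return AblationResult(
        all_features=run_experiment(table, config),
        task_only=run_experiment(sub, config),
        task_id=task_id,
    )
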