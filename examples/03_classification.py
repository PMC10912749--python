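"""Repeated-holdout diagnosis and severity classification.

Runs the 9:1 repeated-holdout protocol (here 10 repeats for speed) for
the binary diagnosis scheme and the 4-class motor-score severity scheme,
and prints the mean (SD) of accuracy and weighted F1 per model family.
"""

from pdscreen import ExperimentConfig, extract_cohort, run_experiment, simulate_cohort
from pdscreen import GeneratorConfig

table = extract_cohort(simulate_cohort(GeneratorConfig(n_pd=50, n_hc=29, seed=3)))

for scheme in ("PDHC", "UPDRS"):
    cfg = ExperimentConfig(scheme=scheme, n_repeats=10, seed=4,
                           models=("logistic_regression", "random_forest",
                                   "xgboost"))
    res = run_experiment(table, cfg)
    print(f"\n=== {scheme} ({len(res.classes)} classes: {res.classes}) ===")
    print(res.to_results_table()[["accuracy", "f1"]].to_string())
    print(f"best model: {res.best_model()}")

print("\nAccuracy is the fraction of correct holdout predictions; F1 is "
      "weighted by per-class test counts because severity classes are "
      "imbalanced.  Diagnosis (2 classes) is easier than multi-class severity (a small cohort may not sample the rare severe class at all).")
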