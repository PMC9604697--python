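"""Predict ablation outcome with repeated cross-validated LDA.

Evaluates univariate models on gamma and f0 (and their combination) with
stratified patient-based 10-fold cross-validation repeated 25 times, and
compares two models with McNemar's test.
"""

from fibwave import (
    CrossValConfig,
    mcnemar_compare,
    repeated_cv,
    simulate_feature_cohort,
)

cohort = simulate_feature_cohort(n_recur=48, n_sr=103, seed=4)
cfg = CrossValConfig(k=10, repeats=25, seed=4)

reports = {}
for features in (["gamma"], ["f0"], ["gamma", "f0"]):
    rep = repeated_cv(cohort, features, cfg)
    reports["+".join(features)] = rep
    print(f"{'+'.join(features):10s} Se {rep.se:5.1f}%  Sp {rep.sp:5.1f}%  "
          f"Acc {rep.acc:5.1f}%  AUC {rep.auc:.3f}  "
          f"PPV {rep.ppv:5.1f}%  NPV {rep.npv:5.1f}%")

stat, p = mcnemar_compare(
    cohort["label"].to_numpy(),
    reports["gamma"].predicted,
    reports["f0"].predicted,
)
print()
print(f"McNemar gamma vs f0: statistic {stat:.2f}, p = {p:.4f}")
print()
print("AUC ~0.7 for gamma vs ~0.6 for f0 mirrors the published ranking of")
print("the two predictors; the McNemar p-value tests whether their")
print("misclassification rates genuinely differ on these patients.")
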