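"""Train the two-layer stacked ensemble and diagnose held-out subjects.

Subject-grouped 80/20 split -> center/scale + PCA -> eight base learners
with repeated stratified CV -> GBM stacking on out-of-fold probabilities
-> cell-level prediction -> subject-level diagnosis.  CV is reduced to
3-fold x 1 repeat here to keep the example quick; the package default is
10-fold x 5 repeats.
"""

import numpy as np

import scrsdx as sx
from scrsdx.ensemble import (
    CVConfig, collapse_labels, collapse_to_three, diagnose_subjects,
    evaluate, model_correlation, predict_cells, scrs_matrix, split_train_test,
    train_ensemble,
)

cfg = sx.default_config(
    seed=5, group_sizes={g: 6 for g in sx.GROUPS},
    cells_per_subject=5, acquisitions_per_cell=(2, 3),
)
cohort = sx.generate_cohort(cfg)
cells, _ = sx.run_preprocess(cohort.spectra)
X, labels, subjects = scrs_matrix(cells, cohort.groups_by_subject())

plan = split_train_test(labels, subjects, grouping="subject", seed=0)
model = train_ensemble(X[plan.train_idx], labels[plan.train_idx],
                       subjects[plan.train_idx], cv=CVConfig(3, 1), seed=0)

print("Base-learner CV accuracy:",
      {k: round(v, 2) for k, v in model.base.cv_accuracy.items()})
corr = model_correlation(model.base).to_numpy()
off = corr[~np.eye(8, dtype=bool)]
print(f"Mean |pairwise accuracy-trace correlation|: {np.nanmean(np.abs(off)):.2f}")

proba, pred = predict_cells(model, X[plan.test_idx])
summary = evaluate(pred, labels[plan.test_idx], model.classes)
print(f"\n5-class held-out cell accuracy: {summary.accuracy:.2f} "
      f"(95% CI {summary.ci95[0]:.2f}-{summary.ci95[1]:.2f}, n={summary.n_test})")

p3 = collapse_to_three(proba)
lab3 = np.asarray(p3.columns)[np.argmax(p3.to_numpy(), axis=1)]
s3 = evaluate(lab3, collapse_labels(labels[plan.test_idx]), ["HC", "ME", "MS"])
print(f"3-class (HC/ME/MS) held-out accuracy: {s3.accuracy:.2f}; "
      f"ME sensitivity {s3.sensitivity['ME']:.2f}, specificity {s3.specificity['ME']:.2f}")

diag = diagnose_subjects(model, proba, pred, subjects[plan.test_idx])
truth = {s: g for s, g in zip(subjects, labels)}
correct = sum(truth[r.subject_id] == r.diagnosis for r in diag.itertuples())
print(f"Subject-level diagnoses: {correct}/{len(diag)} correct "
      f"({diag['aggregator'].iloc[0]} aggregator)")
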