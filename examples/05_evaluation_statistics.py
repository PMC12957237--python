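"""Evaluation statistics: kappa, permutation test, paired t-test,
bootstrap CI, and ROC points on small worked examples."""

import numpy as np

from scbam import (
    ConfusionMatrix,
    accuracy,
    bootstrap_ci,
    cohens_kappa,
    paired_ttest,
    permutation_test,
    roc_points,
)

cm = ConfusionMatrix([[8, 2], [3, 7]], class_labels=[1, 2])
print(f"confusion [[8,2],[3,7]]: accuracy {accuracy(cm):.2f}, "
      f"kappa {cohens_kappa(cm):.2f}")

rng = np.random.default_rng(0)
truth = np.repeat([1, 2, 3, 4, 5], 20)
good = truth.copy()
noisy = rng.random(100) < 0.3
good[noisy] = rng.integers(1, 6, size=int(noisy.sum()))
res = permutation_test(truth, good, n_perm=5000, rng=1)
print(f"decoder at {res['acc_observed']:.2f} accuracy vs null mean "
      f"{res['null_mean']:.3f}: p = {res['p_value']:.4f}")

model_a = np.array([0.86, 0.83, 0.88, 0.79, 0.84, 0.81, 0.87, 0.85, 0.80, 0.82])
model_b = model_a - rng.uniform(0.02, 0.06, size=10)
t, p, stars = paired_ttest(model_a, model_b)
print(f"paired t-test over 10 finger pairs: t = {t:.2f}, p = {p:.2e} {stars}")

subjects = [0.74, 0.81, 0.69, 0.77, 0.85]
lo, hi = bootstrap_ci(subjects, n_boot=1000, rng=2)
print(f"subject mean accuracy {np.mean(subjects):.3f}, "
      f"95% bootstrap CI [{lo:.3f}, {hi:.3f}]")

labels = rng.integers(0, 2, size=200)
scores = np.clip(labels * 0.4 + rng.random(200) * 0.6, 0, 1)
_, auc = roc_points(scores, labels)
print(f"ROC AUC of a partially informative score: {auc:.3f}")

# The permutation p-value is add-one smoothed, (1 + #{null >= observed})
# / (n_perm + 1), so it can never be exactly zero.
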