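"""Evaluation toolkit: the five confusion metrics, ROC/AUC, paired t-tests
with Holm-Bonferroni correction.
"""

import numpy as np

from osfpnet import (
    confusion, holm_bonferroni, metrics, paired_t_test, roc_auc,
)

labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
preds = [1, 1, 1, 0, 0, 0, 0, 0, 1, 0]
scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2, 0.1, 0.35, 0.6, 0.15]

c = confusion(labels, preds)
print(f"TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
m = metrics(c)
print({k: round(v, 3) for k, v in m.as_dict().items()})

r = roc_auc(labels, scores)
print(f"AUC = {r.auc:.3f}  (1.0 = perfect ranking, 0.5 = chance)")

# compare two methods' per-fold accuracies with a paired two-sided t-test
ours = [0.95, 0.92, 0.97, 0.93, 0.96]
baseline = [0.86, 0.84, 0.90, 0.85, 0.88]
t = paired_t_test(ours, baseline)
print(f"paired t: t={t.statistic:.2f}, p={t.p_value:.2e}")

# correcting several such comparisons: k-th smallest p times (N - k + 1)
raw_p = [t.p_value, 0.04, 0.30]
print("Holm-corrected:", [round(float(p), 4) for p in holm_bonferroni(raw_p)])
# Corrected p-values are never smaller than the raw ones; significance at
# alpha=0.05 after correction is the reported criterion.
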