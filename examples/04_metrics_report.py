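"""Compute the full metric suite on a synthetic 4-class prediction set.

Shows the one-vs-rest decomposition: per-class TP/TN/FP/FN feed
accuracy, recall, precision, F-score and MCC; the multi-class MCC comes
from the full confusion matrix (covariance form); AUC is the
Mann-Whitney statistic per class, macro-averaged.
"""

import numpy as np

from hahnet.metrics import multiclass_report

rng = np.random.default_rng(5)
n, k = 400, 4
y_true = rng.integers(0, k, n)
# a moderately good classifier: correct 70% of the time
y_pred = np.where(rng.random(n) < 0.7, y_true, rng.integers(0, k, n))
scores = rng.random((n, k)) * 0.2
scores[np.arange(n), y_pred] += 1.0
scores /= scores.sum(axis=1, keepdims=True)

r = multiclass_report(y_true, y_pred, scores, k)
print(f"accuracy {r.accuracy:.3f}  (fraction of correctly classified tiles)")
print(f"macro precision {r.precision:.3f}, recall {r.recall:.3f}, "
      f"F-score {r.f_score:.3f}")
print(f"multi-class MCC {r.mcc:.3f}  (0 = chance, 1 = perfect)")
print(f"macro one-vs-rest AUC {r.auc:.3f}")
print("confusion matrix (rows = true class):")
print(r.confusion)
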