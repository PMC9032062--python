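"""Evaluation conventions: confusion metrics, degenerate MCC, ROC/AUC.

Shows why MCC is the headline metric: a degenerate all-positive
classifier scores 50% accuracy and perfect recall on a balanced set but
MCC 0 — no better than chance.
"""

import numpy as np

from rotordetect.evaluate import (
    ConfusionCounts,
    confusion,
    evaluate_predictions,
    metrics,
)

# degenerate classifier: predicts "rotor" for every window
labels = np.r_[np.ones(500), np.zeros(500)]
rep = metrics(confusion(labels, np.ones(1000)))
print("all-positive on a balanced set:")
print(f"  accuracy {rep.accuracy:.2%}, precision {rep.precision:.2%}, "
      f"recall {rep.recall:.2%}, specificity {rep.specificity:.2%}, "
      f"MCC {rep.mcc:.3f}")

# an informative classifier
rep2 = metrics(ConfusionCounts(tp=420, fp=110, tn=390, fn=80))
print("\na useful classifier (TP=420 FP=110 TN=390 FN=80):")
print(f"  accuracy {rep2.accuracy:.2%}, MCC {rep2.mcc:.3f}")

# ROC from probabilistic scores
rng = np.random.default_rng(0)
scores = np.clip(0.5 + 0.25 * (2 * labels - 1) + 0.2 * rng.normal(size=1000),
                 0, 1)
full = evaluate_predictions(labels, scores)
print(f"\nprobabilistic scores: AUC {full.auc:.3f} "
      f"({len(full.roc_points)} ROC points from (0,0) to (1,1))")
print("AUC equals the probability a random rotor window outscores a random "
      "non-rotor window (ties counted one half).")
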