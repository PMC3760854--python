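"""Residue-level ROC/AUC evaluation of a prediction track.

Builds a noisy score track over labelled residues and walks through the
curve machinery: thresholds, operating points and the trapezoidal AUC,
which equals the probability that a random binding residue outranks a
random non-binding one (ties count one half).
"""

import numpy as np

from pepbind import auc, roc_points

rng = np.random.default_rng(0)
labels = rng.integers(0, 2, size=2000)
# informative but noisy scores: mean 0.65 for binders, 0.35 for the rest
scores = np.clip(rng.normal(0.35 + 0.3 * labels, 0.2), 0, 1)

curve = roc_points(scores, labels)
print(f"curve has {len(curve.thresholds)} operating points")
for t in (0.7, 0.5, 0.3):
    i = int(np.searchsorted(-curve.thresholds, -t))
    print(f"threshold ~{t}: FPR {curve.fpr[i]:.3f}, TPR {curve.tpr[i]:.3f}")
print(f"AUC: {auc(curve):.3f}")
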