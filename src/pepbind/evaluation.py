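"""Residue-level ROC curves and AUC.

Predictions and labels from all regions are pooled into one vector pair and
swept with a decreasing threshold: a residue is called binding when its
score is >= the threshold, giving a (FPR, TPR) point per distinct score.
The area under the resulting polyline equals the probability that a random
binding residue outranks a random non-binding one (ties counted half), so
0.5 is a random ranking and 1.0 a perfect one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sklearn_roc_curve

from .errors import EvaluationError


@dataclass
class ROCCurve:
    """A ROC polyline: thresholds (decreasing) and (FPR, TPR) points."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    @property
    def auc(self) -> float:
        return auc(self)


def roc_points(scores, labels) -> ROCCurve:
    """Sweep thresholds from high to low over pooled residue scores.

    At threshold t a residue is predicted binding iff its score >= t.
    Thresholds are the distinct scores plus a leading sentinel above the
    maximum, so the curve starts at (0, 0); it always ends at (1, 1).
    Thresholds are reported clipped to [0, 1], matching score tracks that
    live on that scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1-D arrays")
    if labels.min() == labels.max():
        raise EvaluationError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sklearn_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thresholds=np.clip(thr, 0.0, 1.0), fpr=fpr, tpr=tpr)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the (FPR, TPR) polyline."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def roc_auc(scores, labels) -> float:
    """Convenience: pooled residue-level AUC in one call."""
    return auc(roc_points(scores, labels))


def curve_frame(curve: ROCCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    )


def write_curve(curve: ROCCurve, path: str | Path) -> None:
    """Export a curve as TSV with a trailing AUC summary line."""
    path = Path(path)
    frame = curve_frame(curve)
    with open(path, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write(f"# AUC\t{auc(curve):.6g}\n")


def plot_curve(curve: ROCCurve, path: str | Path, title: str = "ROC") -> None:
    """Optional matplotlib rendering of a curve (diagonal = random)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, lw=1.5, label=f"AUC = {auc(curve):.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
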