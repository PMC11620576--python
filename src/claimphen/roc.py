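"""ROC curves, AUC, and Youden-optimal cutoffs.

Works for coarse integer scores (the six-item manual score yields at most
seven thresholds) as well as continuous classifier probabilities.  The
curve keeps one point per distinct score value (ties collapsed), the AUC
is the trapezoidal area — numerically identical to the tie-corrected
Mann-Whitney statistic U/(n1*n0) — and the cutoff is chosen by Youden's
method (maximise sensitivity + specificity - 1), breaking ties toward
higher specificity.  A classification rule reads ``score >= cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["ROCResult", "roc_curve", "auc_mean_sd"]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # descending; aligned with points[1:]
    points: np.ndarray      # (n_thresholds + 1, 2) of (fpr, tpr), from (0,0) to (1,1)
    auc: float
    youden_cutoff: float
    youden_sn: float
    youden_sp: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self):
        import pandas as pd

        thr = np.concatenate([[np.inf], self.thresholds])
        return pd.DataFrame({"threshold": thr, "fpr": self.fpr, "tpr": self.tpr})


def roc_curve(scores, labels) -> ROCResult:
    """Build the ROC curve of a score vector against boolean labels.

    Raises ``ValueError`` unless both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both a positive and a negative class")

    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    # sklearn's first threshold is +inf (the empty-positive point (0,0));
    # report a finite cutoff that still classifies nobody as positive.
    thresholds = thr[1:]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = int(np.lexsort((fpr, -j))[0])  # max Youden J, ties -> lowest fpr
    if best == 0:
        cutoff = float(scores.max()) + 1.0
    else:
        cutoff = float(thr[best])
    return ROCResult(
        thresholds=thresholds,
        points=points,
        auc=auc,
        youden_cutoff=cutoff,
        youden_sn=float(tpr[best]),
        youden_sp=float(1.0 - fpr[best]),
    )


def auc_mean_sd(aucs) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of fold AUCs."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 2:
        raise ValueError("need at least two values for a mean +/- SD summary")
    return float(aucs.mean()), float(aucs.std(ddof=1))
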