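"""ROC and precision-recall curves by descending-score threshold sweep.

Tied scores are collapsed into a single threshold, the curves therefore
have one point per distinct score, and areas are computed with the
trapezoid rule.  AUROC computed this way equals the concordance
probability P(s+ > s-) + 0.5 P(s+ = s-).
"""

from __future__ import annotations

import numpy as np


def _check(scores, labels):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return scores, labels, n_pos, n_neg


def roc_curve(scores, labels):
    """(thresholds, fpr, tpr) with predictions = score >= threshold.

    The sweep starts at (0, 0) (threshold above the maximum score) and ends
    at (1, 1).
    """
    scores, labels, n_pos, n_neg = _check(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    last = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]  # collapse ties
    thresholds = np.r_[np.inf, s[last]]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return thresholds, fpr, tpr


def roc_auroc(scores, labels):
    """((fpr, tpr) points, area under the ROC curve by trapezoid rule)."""
    _, fpr, tpr = roc_curve(scores, labels)
    return (fpr, tpr), float(np.trapezoid(tpr, fpr))


def pr_curve(scores, labels):
    """(thresholds, precision, recall), precision = TP/(TP+FP).

    Anchored at recall 0 with the precision of the highest-score tie group.
    """
    scores, labels, n_pos, _ = _check(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y == 1)
    predicted = np.arange(1, len(s) + 1)
    last = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    precision = tp[last] / predicted[last]
    recall = tp[last] / n_pos
    thresholds = np.r_[np.inf, s[last]]
    precision = np.r_[precision[0], precision]
    recall = np.r_[0.0, recall]
    return thresholds, precision, recall


def pr_auprc(scores, labels):
    """((recall, precision) points, area under the PR curve, trapezoid)."""
    _, precision, recall = pr_curve(scores, labels)
    return (recall, precision), float(np.trapezoid(precision, recall))


def write_roc_tsv(scores, labels, path) -> None:
    thresholds, fpr, tpr = roc_curve(scores, labels)
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t, f, r in zip(thresholds, fpr, tpr):
            fh.write(f"{t:.6g}\t{f:.6f}\t{r:.6f}\n")


def write_pr_tsv(scores, labels, path) -> None:
    thresholds, precision, recall = pr_curve(scores, labels)
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\n")
        for t, p, r in zip(thresholds, precision, recall):
            fh.write(f"{t:.6g}\t{p:.6f}\t{r:.6f}\n")
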