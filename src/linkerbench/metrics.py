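"""Evaluation metrics for ranked per-residue (or per-protein) propensities.

Five metrics are computed from a scored, binary-labeled sample:

* ``auc`` — area under the tie-corrected ROC curve (trapezoidal); equal to the
  Mann-Whitney probability that a random positive outscores a random negative,
  with half credit for ties.
* ``low_auc_ratio`` — partial ROC area over false positive rates in [0, f],
  where f is the positive-class rate, divided by the partial area f^2/2 of a
  random predictor.  1 means random-level early retrieval; 2 means twice the
  random partial area.  This focuses on the conservative regime where no more
  residues are predicted positive than are positive in the ground truth.
* ``auprc`` — area under the precision-recall curve, computed as average
  precision (step-wise sum of precision times recall increments; no linear
  interpolation in PR space, which is known to be over-optimistic).
* ``f1max`` / ``mccmax`` — maxima of F1 and of the Matthews correlation
  coefficient over all binarization thresholds of the propensities.  The
  binarization predicate is ``score >= threshold``; ties between equally good
  thresholds resolve to the higher threshold (fewer predicted positives).

Curve construction is delegated to scikit-learn; the partial-area ratio and
the threshold scans are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_curve as _sk_roc_curve

METRIC_NAMES = ("auc", "low_auc_ratio", "auprc", "f1max", "mccmax")


@dataclass(frozen=True)
class ScoredSample:
    """Paired score and {0,1} label arrays, optionally with provenance.

    ``provenance`` is a parallel sequence of (protein_id, position) pairs and
    is carried for diagnostics only.
    """

    scores: np.ndarray
    labels: np.ndarray
    provenance: Sequence[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int8))
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D arrays of equal length")
        if self.labels.size and not np.all((self.labels == 0) | (self.labels == 1)):
            raise ValueError("labels must be binary")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


@dataclass(frozen=True)
class RocCurve:
    """Tie-corrected ROC curve: one vertex per distinct score threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class PrCurve:
    """Precision-recall vertices at each distinct descending threshold."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class MetricBundle:
    """The five evaluation metrics for one method in one scenario repeat.

    ``f_positive_rate`` is the false-positive-rate cap used by the partial
    AUC; by construction ``low_auc_ratio <= 2 / f_positive_rate``.
    """

    auc: float
    low_auc_ratio: float
    auprc: float
    f1max: float
    mccmax: float
    f_positive_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([self.auc, self.low_auc_ratio, self.auprc, self.f1max, self.mccmax])

    def __getitem__(self, metric: str) -> float:
        if metric not in METRIC_NAMES:
            raise KeyError(metric)
        return float(getattr(self, metric))


def _require_both_classes(sample: ScoredSample) -> None:
    if sample.n_pos == 0 or sample.n_neg == 0:
        raise ValueError(
            f"sample must contain both classes (got {sample.n_pos} positives, "
            f"{sample.n_neg} negatives)"
        )


def roc_curve(sample: ScoredSample) -> RocCurve:
    """ROC vertices swept over unique scores descending, ties grouped."""
    _require_both_classes(sample)
    fpr, tpr, thr = _sk_roc_curve(sample.labels, sample.scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def low_auc_ratio(curve: RocCurve, f: float) -> float:
    """Partial AUC over FPR in [0, f], normalized by a random predictor's.

    The curve is linearly interpolated at FPR = f; vertical segments (tied
    FPR) contribute no area.  The random predictor's partial area is f^2/2.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    fpr, tpr = curve.fpr, curve.tpr
    # last vertex with fpr <= f, then the interpolated point at f itself
    i = int(np.searchsorted(fpr, f, side="right")) - 1
    if fpr[i] == f:
        t_at_f = tpr[i]
    else:
        t_at_f = tpr[i] + (tpr[i + 1] - tpr[i]) * (f - fpr[i]) / (fpr[i + 1] - fpr[i])
    xs = np.append(fpr[: i + 1], f)
    ys = np.append(tpr[: i + 1], t_at_f)
    partial = float(np.trapezoid(ys, xs))
    return partial / (f * f / 2.0)


def pr_curve(sample: ScoredSample) -> PrCurve:
    if sample.n_pos == 0:
        raise ValueError("precision-recall curve requires at least one positive")
    precision, recall, thr = _sk_pr_curve(sample.labels, sample.scores)
    return PrCurve(precision=precision, recall=recall, thresholds=thr)


def auprc(curve: PrCurve) -> float:
    """Average precision: sum of precision times recall increments."""
    # recall is non-increasing in the stored order; increments are negative
    return float(-np.sum(np.diff(curve.recall) * curve.precision[:-1]))


def _threshold_scan(sample: ScoredSample) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Confusion counts at every distinct threshold, descending.

    Returns (thresholds, tp, n_predicted_positive) with an implicit extra
    all-negative threshold handled by callers.  Predicate: score >= threshold.
    """
    order = np.argsort(-sample.scores, kind="stable")
    s = sample.scores[order]
    y = sample.labels[order].astype(np.float64)
    last = np.r_[np.diff(s) != 0, True]  # last index of each tied group
    tp = np.cumsum(y)[last]
    k = (np.flatnonzero(last) + 1).astype(np.float64)
    return s[last], tp, k


def f1_max(sample: ScoredSample) -> tuple[float, float]:
    """Maximal F1 over all binarization thresholds -> (threshold, f1)."""
    if sample.n_pos == 0:
        raise ValueError("F1 requires at least one positive")
    thr, tp, k = _threshold_scan(sample)
    p = float(sample.n_pos)
    f1 = 2.0 * tp / (p + k)  # == 2TP / (2TP + FP + FN)
    # all-negative threshold (above max score) has F1 = 0
    thr = np.r_[np.inf, thr]
    f1 = np.r_[0.0, f1]
    i = int(np.argmax(f1))  # first max in descending order -> highest threshold
    return float(thr[i]), float(f1[i])


def mcc_max(sample: ScoredSample) -> tuple[float, float]:
    """Maximal Matthews correlation over thresholds -> (threshold, mcc).

    Any threshold whose confusion matrix makes the MCC denominator zero is
    assigned MCC 0, keeping the scan total.
    """
    _require_both_classes(sample)
    thr, tp, k = _threshold_scan(sample)
    p, n = float(sample.n_pos), float(sample.n_neg)
    fp = k - tp
    fn = p - tp
    tn = n - fp
    num = tp * tn - fp * fn
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(denom > 0, num / denom, 0.0)
    thr = np.r_[np.inf, thr]
    mcc = np.r_[0.0, mcc]
    i = int(np.argmax(mcc))
    return float(thr[i]), float(mcc[i])


def metric_bundle(sample: ScoredSample, f: float) -> MetricBundle:
    """All five metrics from one sample; ``f`` caps the partial AUC."""
    _require_both_classes(sample)
    roc = roc_curve(sample)
    return MetricBundle(
        auc=auc(roc),
        low_auc_ratio=low_auc_ratio(roc, f),
        auprc=auprc(pr_curve(sample)),
        f1max=f1_max(sample)[1],
        mccmax=mcc_max(sample)[1],
        f_positive_rate=f,
    )


def mean_bundle(bundles: Sequence[MetricBundle]) -> MetricBundle:
    """Arithmetic mean of metric bundles (e.g., across scenario repeats)."""
    if not bundles:
        raise ValueError("no bundles to average")
    arr = np.mean([b.as_array() for b in bundles], axis=0)
    return MetricBundle(*arr, f_positive_rate=bundles[0].f_positive_rate)
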