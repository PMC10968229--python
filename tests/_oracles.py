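"""Brute-force reference implementations used only to check the real ones.

Everything here is written for clarity over speed and stays independent of
the code paths it validates: pair counting instead of curve integration,
explicit threshold loops instead of vectorized scans, itertools enumeration
instead of sliding views.
"""

import itertools

import numpy as np


def auc_pair_counting(scores, labels):
    """Mann-Whitney: P(random positive > random negative), ties half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _confusion(scores, labels, threshold):
    pred = np.asarray(scores, dtype=float) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, fn, tn


def _thresholds(scores):
    return sorted(set(float(s) for s in scores)) + [float(np.max(scores)) + 1.0]


def f1_enumeration(scores, labels):
    best = (0.0, np.inf)
    for t in _thresholds(scores):
        tp, fp, fn, _ = _confusion(scores, labels, t)
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best[0] or (f1 == best[0] and t > best[1]):
            best = (f1, t)
    return best[0]


def mcc_enumeration(scores, labels):
    best = (-np.inf, np.inf)
    for t in _thresholds(scores):
        tp, fp, fn, tn = _confusion(scores, labels, t)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
        if mcc > best[0] or (mcc == best[0] and t > best[1]):
            best = (mcc, t)
    # the scan always includes the all-negative threshold with MCC 0
    return max(best[0], 0.0)


def ap_step_sum(scores, labels):
    """Average precision by explicit threshold enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    prev_recall = 0.0
    ap = 0.0
    for t in sorted(set(scores), reverse=True):
        tp, fp, _, _ = _confusion(scores, labels, t)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def window_enumeration(values, w):
    values = list(map(float, values))
    if len(values) <= w:
        return float(np.mean(values))
    return max(float(np.mean(values[i : i + w])) for i in range(len(values) - w + 1))


def topk_enumeration(values, k):
    values = list(map(float, values))
    if len(values) <= k:
        return float(np.mean(values))
    return max(float(np.mean(c)) for c in itertools.combinations(values, k))
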