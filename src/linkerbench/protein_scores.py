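"""Protein-level DL scores derived from residue-level propensity vectors.

A residue-level predictor emits one propensity per residue; identifying
*proteins* that harbor a disordered flexible linker requires collapsing that
vector to a scalar.  Four schemes are supported:

* sliding window of size 10 (the minimal DL length) or 31 (the median DL
  length): the protein score is the highest window mean, mimicking the
  segment-based nature of linkers;
* top-k for k = 10 or 20: the mean of the k highest propensities anywhere in
  the sequence.

A whole-sequence average is deliberately not offered: linkers cover a small
fraction of a typical sequence, so a global mean mostly measures disorder
content, not linker presence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import Dataset, PredictionSet
from .metrics import ScoredSample, auc, auprc, pr_curve, roc_curve


class SchemeKind(str, Enum):
    SLIDING_WINDOW = "window"
    TOP_K = "topk"


@dataclass(frozen=True)
class SchemeSpec:
    kind: SchemeKind
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("scheme size must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.kind.value}{self.size}"


#: the four schemes compared in the assessment, in tie-breaking order
DEFAULT_SCHEMES = (
    SchemeSpec(SchemeKind.SLIDING_WINDOW, 10),
    SchemeSpec(SchemeKind.SLIDING_WINDOW, 31),
    SchemeSpec(SchemeKind.TOP_K, 10),
    SchemeSpec(SchemeKind.TOP_K, 20),
)


def window_score(propensities: np.ndarray, w: int) -> float:
    """Highest mean over all fully-contained length-``w`` windows.

    Windows never extend past either end (no padding); a sequence shorter
    than ``w`` falls back to the whole-sequence mean.
    """
    x = np.asarray(propensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty propensity vector")
    if w < 1:
        raise ValueError("window size must be >= 1")
    if x.size <= w:
        return float(x.mean())
    means = np.lib.stride_tricks.sliding_window_view(x, w).mean(axis=1)
    return float(means.max())


def topk_score(propensities: np.ndarray, k: int) -> float:
    """Mean of the ``k`` largest propensities (all of them if len < k)."""
    x = np.asarray(propensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty propensity vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size <= k:
        return float(x.mean())
    top = np.partition(x, x.size - k)[x.size - k :]
    return float(top.mean())


def apply_scheme(propensities: np.ndarray, scheme: SchemeSpec) -> float:
    if scheme.kind is SchemeKind.SLIDING_WINDOW:
        return window_score(propensities, scheme.size)
    return topk_score(propensities, scheme.size)


def score_all(predset: PredictionSet, scheme: SchemeSpec) -> dict[str, float]:
    """Protein-level score for every protein the method predicts."""
    return {pid: apply_scheme(vec, scheme) for pid, vec in predset.scores.items()}


@dataclass(frozen=True)
class SchemeReport:
    scheme: SchemeSpec
    best_auc_method: str
    best_auc: float
    best_auprc_method: str
    best_auprc: float


@dataclass(frozen=True)
class SchemeComparison:
    reports: tuple[SchemeReport, ...]
    winner: SchemeSpec  # highest best-AUC; ties resolve to earlier scheme order


def compare_schemes(
    dataset: Dataset,
    schemes: tuple[SchemeSpec, ...] = DEFAULT_SCHEMES,
) -> SchemeComparison:
    """Best method per scheme (by AUC and by AUPRC) and the winning scheme.

    Every method's protein-level sample is evaluated on the proteins it
    predicts, against the "harbors a DL" protein truth.
    """
    if not dataset.predictions:
        raise ValueError("no prediction sets to compare")
    truth = {e.protein_id: int(e.has_dl) for e in dataset.entries}
    if not any(truth.values()):
        raise ValueError("no DL-positive proteins in reference")
    reports = []
    for scheme in schemes:
        best_auc = (-np.inf, "")
        best_ap = (-np.inf, "")
        for predset in dataset.predictions:
            scores = score_all(predset, scheme)
            pids = list(scores)
            sample = ScoredSample(
                scores=np.array([scores[p] for p in pids]),
                labels=np.array([truth[p] for p in pids]),
            )
            a = auc(roc_curve(sample))
            ap = auprc(pr_curve(sample))
            if a > best_auc[0]:
                best_auc = (a, predset.method_name)
            if ap > best_ap[0]:
                best_ap = (ap, predset.method_name)
        reports.append(
            SchemeReport(
                scheme=scheme,
                best_auc_method=best_auc[1],
                best_auc=float(best_auc[0]),
                best_auprc_method=best_ap[1],
                best_auprc=float(best_ap[0]),
            )
        )
    winner = reports[int(np.argmax([r.best_auc for r in reports]))].scheme
    return SchemeComparison(reports=tuple(reports), winner=winner)
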