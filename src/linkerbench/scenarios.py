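"""The three evaluation scenarios and the class-rebalancing sampler.

* **S1** (residues, all): DL residues vs. every non-DL, non-unknown residue —
  the typical use of a linker predictor on whole sequences.
* **S2** (residues, disordered): DL residues vs. *other disordered* residues —
  can a method tell linkers apart from the rest of the disordered proteome?
* **S3** (proteins): does the protein harbor a DL at all?  Residue propensity
  vectors are collapsed to protein scores by a :mod:`~linkerbench.protein_scores`
  scheme; no rebalancing is applied at the protein level.

For the residue scenarios, every repeat keeps all positives and subsamples
negatives without replacement so that the positive fraction equals a target
``f`` (by default the dataset's disorder content, which makes linker results
directly comparable with published disorder-prediction results).  The same
sampled index set is applied to every method within a repeat, so methods are
always compared on identical residues; residues of proteins a method does not
predict are dropped for that method only, at extraction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .io import Dataset, PredictionSet, ReferenceEntry, ResidueLabel
from .metrics import MetricBundle, ScoredSample, mean_bundle, metric_bundle

logger = logging.getLogger(__name__)


class ScenarioId(str, Enum):
    S1_RESIDUE_ALL = "S1"
    S2_RESIDUE_DISORDERED = "S2"
    S3_PROTEIN = "S3"


@dataclass(frozen=True)
class ScenarioSpec:
    """What to evaluate and how to repeat it.

    ``target_positive_fraction=None`` resolves to the dataset's disorder
    content for S1/S2 and to the DL-protein rate for S3 (S3 applies no
    rebalancing; the rate only parameterizes the partial AUC).
    """

    scenario_id: ScenarioId
    target_positive_fraction: float | None = None
    n_repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        f = self.target_positive_fraction
        if f is not None and not 0.0 < f < 1.0:
            raise ValueError("target_positive_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ResiduePool:
    """Flattened candidate residues for one residue-level scenario."""

    entry_idx: np.ndarray  # index into dataset.entries
    position: np.ndarray  # 0-based residue position
    y: np.ndarray  # bool, True for DL residues

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.y).sum())


@dataclass
class ScenarioResult:
    """Per-method metric bundles, mean-ranked, with optional marks.

    ``methods`` is sorted by descending mean AUC (name ascending on ties);
    ``marks`` maps method -> metric -> "+" (significantly different from the
    top method) or "=" (not significant), absent for the top method.
    """

    scenario_id: ScenarioId
    f_positive_rate: float
    methods: list[str]
    mean: dict[str, MetricBundle]
    repeats: dict[str, list[MetricBundle]]
    marks: dict[str, dict[str, str]] | None = None

    @property
    def top_method(self) -> str:
        return self.methods[0]


# ---------------------------------------------------------------------------
# dataset summaries used as sampling targets
# ---------------------------------------------------------------------------

def disorder_content(dataset: Dataset) -> float:
    """Fraction of labeled residues that are disordered (DL included)."""
    lab = np.concatenate([e.residue_labels for e in dataset.entries])
    known = lab != ResidueLabel.UNKNOWN
    if not known.any():
        raise ValueError("no labeled residues")
    dis = (lab == ResidueLabel.DL) | (lab == ResidueLabel.DISORDERED_OTHER)
    return float(dis[known].mean())


def protein_truth(dataset: Dataset) -> np.ndarray:
    """Boolean array aligned with ``dataset.entries``: harbors >= 1 DL residue."""
    return np.array([e.has_dl for e in dataset.entries], dtype=bool)


def dl_protein_rate(dataset: Dataset) -> float:
    return float(protein_truth(dataset).mean())


# ---------------------------------------------------------------------------
# residue pools and rebalancing
# ---------------------------------------------------------------------------

def residue_pool(dataset: Dataset, scenario_id: ScenarioId) -> ResiduePool:
    """Collect candidate residues; unknown residues never enter any pool."""
    if scenario_id is ScenarioId.S3_PROTEIN:
        raise ValueError("S3 is protein-level; it has no residue pool")
    idx_parts, pos_parts, y_parts = [], [], []
    for i, e in enumerate(dataset.entries):
        lab = e.residue_labels
        if scenario_id is ScenarioId.S1_RESIDUE_ALL:
            keep = lab != ResidueLabel.UNKNOWN
        else:
            keep = (lab == ResidueLabel.DL) | (lab == ResidueLabel.DISORDERED_OTHER)
        pos = np.flatnonzero(keep)
        if pos.size == 0:
            continue
        idx_parts.append(np.full(pos.size, i, dtype=np.int32))
        pos_parts.append(pos.astype(np.int32))
        y_parts.append(lab[pos] == ResidueLabel.DL)
    if not idx_parts:
        raise ValueError("empty residue pool")
    pool = ResiduePool(
        entry_idx=np.concatenate(idx_parts),
        position=np.concatenate(pos_parts),
        y=np.concatenate(y_parts),
    )
    if pool.n_pos == 0:
        raise ValueError("residue pool contains no DL-positive residues")
    return pool


def rebalance_sample(pool: ResiduePool, f: float, seed) -> np.ndarray:
    """All positives plus ``round(P(1-f)/f)`` negatives sampled uniformly.

    Returns sorted indices into the pool.  The draw is without replacement
    from the negative pool and fully determined by ``seed``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("target positive fraction must lie in (0, 1)")
    p = pool.n_pos
    n_neg = round(p * (1.0 - f) / f)
    neg_idx = np.flatnonzero(~pool.y)
    if neg_idx.size < n_neg:
        raise ValueError(
            f"rebalancing needs {n_neg} negatives but the pool has only {neg_idx.size}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg_idx, size=n_neg, replace=False)
    return np.sort(np.r_[np.flatnonzero(pool.y), chosen])


# ---------------------------------------------------------------------------
# score extraction
# ---------------------------------------------------------------------------

def _flat_scores(dataset: Dataset, predset: PredictionSet) -> np.ndarray:
    """One score slot per residue of the whole reference; NaN where the
    method does not (completely) predict the protein."""
    lengths = [e.length for e in dataset.entries]
    flat = np.full(int(np.sum(lengths)), np.nan)
    offset = 0
    for e, L in zip(dataset.entries, lengths):
        vec = predset.scores.get(e.protein_id)
        if vec is not None and len(vec) == L:
            flat[offset : offset + L] = vec
        offset += L
    return flat


def _pool_flat_index(dataset: Dataset, pool: ResiduePool) -> np.ndarray:
    offsets = np.r_[0, np.cumsum([e.length for e in dataset.entries])[:-1]]
    return offsets[pool.entry_idx] + pool.position


def extract_sample(
    dataset: Dataset,
    pool: ResiduePool,
    selection: np.ndarray,
    predset: PredictionSet,
) -> ScoredSample:
    """One method's scores on a sampled residue index set.

    Residues of proteins the method leaves unpredicted are dropped here, so
    the shared selection stays comparable across methods.
    """
    flat = _flat_scores(dataset, predset)
    vals = flat[_pool_flat_index(dataset, pool)[selection]]
    ok = ~np.isnan(vals)
    return ScoredSample(scores=vals[ok], labels=pool.y[selection][ok])


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def _rank(mean: Mapping[str, MetricBundle]) -> list[str]:
    return sorted(mean, key=lambda m: (-mean[m].auc, m))


def run_residue_scenario(dataset: Dataset, spec: ScenarioSpec) -> ScenarioResult:
    """Run S1 or S2: ``n_repeats`` rebalanced draws, metrics per method.

    Repeat ``r`` draws one negative sample with seed ``base_seed + r`` and
    applies it to every method; the reported bundle per method is the
    arithmetic mean across repeats and methods are ranked by mean AUC.
    """
    if spec.scenario_id is ScenarioId.S3_PROTEIN:
        raise ValueError("use run_protein_scenario for S3")
    if not dataset.predictions:
        raise ValueError("dataset has no prediction sets")
    f = spec.target_positive_fraction
    if f is None:
        f = disorder_content(dataset)
    pool = residue_pool(dataset, spec.scenario_id)
    flat_idx = _pool_flat_index(dataset, pool)
    flats = {p.method_name: _flat_scores(dataset, p) for p in dataset.predictions}

    repeats: dict[str, list[MetricBundle]] = {m: [] for m in flats}
    for r in range(spec.n_repeats):
        sel = rebalance_sample(pool, f, spec.base_seed + r)
        y_sel = pool.y[sel]
        for name, flat in flats.items():
            vals = flat[flat_idx[sel]]
            ok = ~np.isnan(vals)
            sample = ScoredSample(scores=vals[ok], labels=y_sel[ok])
            repeats[name].append(metric_bundle(sample, f))
    mean = {m: mean_bundle(bs) for m, bs in repeats.items()}
    return ScenarioResult(
        scenario_id=spec.scenario_id,
        f_positive_rate=f,
        methods=_rank(mean),
        mean=mean,
        repeats=repeats,
    )


def protein_sample(
    dataset: Dataset,
    predset: PredictionSet,
    scheme,
) -> ScoredSample:
    """Protein-level scores vs. "harbors a DL" truth for one method."""
    from .protein_scores import score_all

    truth = {e.protein_id: int(e.has_dl) for e in dataset.entries}
    scores = score_all(predset, scheme)
    pids = [p for p in truth if p in scores]
    missing = len(truth) - len(pids)
    if missing:
        logger.info("%s: %d unpredicted protein(s) absent from S3 sample", predset.method_name, missing)
    return ScoredSample(
        scores=np.array([scores[p] for p in pids]),
        labels=np.array([truth[p] for p in pids]),
        provenance=[(p, 0) for p in pids],
    )


def run_protein_scenario(dataset: Dataset, scheme, spec: ScenarioSpec) -> ScenarioResult:
    """Run S3 with one protein-level scheme.

    No rebalancing: each method is evaluated once on its predicted proteins
    with the partial AUC capped at the empirical DL-protein rate.  Variation
    for significance marks comes from the 50%-protein subsampling protocol
    (see :mod:`~linkerbench.significance`), not from repeats here.
    """
    if spec.scenario_id is not ScenarioId.S3_PROTEIN:
        raise ValueError("run_protein_scenario requires the protein scenario")
    if not dataset.predictions:
        raise ValueError("dataset has no prediction sets")
    f = spec.target_positive_fraction
    if f is None:
        f = dl_protein_rate(dataset)
        if not 0.0 < f < 1.0:
            raise ValueError("protein truth is single-class; cannot evaluate S3")
    repeats = {
        p.method_name: [metric_bundle(protein_sample(dataset, p, scheme), f)]
        for p in dataset.predictions
    }
    mean = {m: bs[0] for m, bs in repeats.items()}
    return ScenarioResult(
        scenario_id=ScenarioId.S3_PROTEIN,
        f_positive_rate=f,
        methods=_rank(mean),
        mean=mean,
        repeats=repeats,
    )


def subset_dataset(dataset: Dataset, entry_indices: Sequence[int]) -> Dataset:
    """Restriction of a dataset to a protein subset (predictions filtered)."""
    entries = [dataset.entries[i] for i in entry_indices]
    keep = {e.protein_id for e in entries}
    preds = [
        PredictionSet(
            method_name=p.method_name,
            scores={pid: v for pid, v in p.scores.items() if pid in keep},
            binary={pid: v for pid, v in p.binary.items() if pid in keep},
        )
        for p in dataset.predictions
    ]
    return Dataset(entries=entries, predictions=preds)
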