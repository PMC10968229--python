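"""Robustness testing of method rankings by repeated protein subsampling.

The protocol: sample 50% of the test proteins ``n_subsamples`` times,
recompute the scenario metric on each subsample for every method (the
scenario's own negative rebalancing is re-drawn inside each subsample with a
per-subsample seed shared by all methods), and compare each method's series
against the top-ranked method's series, one metric at a time.

Paired differences are screened for normality with the Anderson-Darling test;
normal-looking differences go to a paired t-test, the rest to the Wilcoxon
signed-rank test (zero differences dropped, Wilcoxon's original treatment).
A method earns the mark ``+`` for a metric when the two-sided p-value falls
strictly below ``alpha_test``, and ``=`` otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import Dataset
from .metrics import METRIC_NAMES, MetricBundle, metric_bundle
from .scenarios import (
    ScenarioId,
    ScenarioResult,
    ScenarioSpec,
    protein_sample,
    protein_truth,
    rebalance_sample,
    residue_pool,
    run_residue_scenario,
    subset_dataset,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceConfig:
    subsample_fraction: float = 0.5
    n_subsamples: int = 10
    alpha_normality: float = 0.05
    alpha_test: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")


def protein_subsamples(dataset: Dataset, config: SignificanceConfig) -> list[np.ndarray]:
    """Protein-index subsets of size ``round(fraction * n)``.

    Drawn without replacement within each subset, independently across
    subsets.  A subset without any DL-positive protein is redrawn with an
    incremented seed (logged); failure to find one after many attempts is an
    error.
    """
    n = len(dataset.entries)
    if n == 0:
        raise ValueError("empty dataset")
    size = round(config.subsample_fraction * n)
    truth = protein_truth(dataset)
    if not truth.any():
        raise ValueError("no DL-positive proteins; subsamples cannot satisfy the positive constraint")
    subsets = []
    for j in range(config.n_subsamples):
        for attempt in range(1000):
            rng = np.random.default_rng([config.seed + attempt, j])
            idx = np.sort(rng.choice(n, size=size, replace=False))
            if truth[idx].any():
                if attempt:
                    logger.info("subsample %d redrawn %d time(s) to include a positive protein", j, attempt)
                subsets.append(idx)
                break
        else:
            raise ValueError(f"could not draw a subsample with a positive protein (subset {j})")
    return subsets


def metric_series(
    dataset: Dataset,
    subsets: Sequence[np.ndarray],
    scenario_id: ScenarioId,
    f: float,
    config: SignificanceConfig,
    scheme=None,
) -> dict[str, np.ndarray]:
    """Per-method array of shape (n_subsamples, 5): the scenario metrics
    recomputed on each protein subsample.

    For residue scenarios the rebalanced negative draw inside subsample ``j``
    uses seed ``(config.seed, j)``, identical for all methods, so the series
    are paired.  For S3 the partial-AUC cap is the subsample's own DL-protein
    rate.
    """
    out = {p.method_name: np.empty((len(subsets), 5)) for p in dataset.predictions}
    for j, idx in enumerate(subsets):
        sub = subset_dataset(dataset, idx)
        if scenario_id is ScenarioId.S3_PROTEIN:
            f_sub = float(protein_truth(sub).mean())
            for p in sub.predictions:
                out[p.method_name][j] = metric_bundle(protein_sample(sub, p, scheme), f_sub).as_array()
        else:
            pool = residue_pool(sub, scenario_id)
            sel = rebalance_sample(pool, f, [config.seed, j])
            from .scenarios import extract_sample

            for p in sub.predictions:
                sample = extract_sample(sub, pool, sel, p)
                out[p.method_name][j] = metric_bundle(sample, f).as_array()
    return out


def compare_to_best(
    best_series: np.ndarray,
    other_series: np.ndarray,
    config: SignificanceConfig,
) -> tuple[str, float]:
    """Mark one method against the top method for one metric.

    Returns ``("+", p)`` when the paired two-sided test rejects at
    ``alpha_test`` (strict inequality), ``("=", p)`` otherwise.  Identical
    series short-circuit to ``("=", 1.0)``.
    """
    best = np.asarray(best_series, dtype=float)
    other = np.asarray(other_series, dtype=float)
    if best.shape != other.shape:
        raise ValueError("series must have equal length")
    diffs = best - other
    if np.allclose(diffs, 0.0):
        return "=", 1.0
    normal = False
    if np.std(diffs) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ad = stats.anderson(diffs, dist="norm")
        if hasattr(ad, "critical_values"):
            # critical values are tabulated at [15, 10, 5, 2.5, 1]% significance
            crit = dict(zip(ad.significance_level, ad.critical_values))
            normal = ad.statistic < crit[config.alpha_normality * 100.0]
        else:  # newer scipy returns a p-value directly
            normal = float(ad.pvalue) > config.alpha_normality
    if normal:
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    else:
        nz = diffs[diffs != 0.0]
        if nz.size == 0:
            return "=", 1.0
        p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
    return ("+" if p < config.alpha_test else "="), p


def annotate(
    result: ScenarioResult,
    dataset: Dataset,
    config: SignificanceConfig,
    scheme=None,
) -> ScenarioResult:
    """Attach per-metric marks relative to the top-ranked method.

    The top method (highest mean AUC) carries no marks; every other method
    gets one ``+``/``=`` mark per metric.  Marks do not depend on the order
    of the prediction sets in the dataset.
    """
    if result.scenario_id is ScenarioId.S3_PROTEIN and scheme is None:
        raise ValueError("S3 annotation requires the protein-level scheme")
    subsets = protein_subsamples(dataset, config)
    series = metric_series(dataset, subsets, result.scenario_id, result.f_positive_rate, config, scheme)
    best = result.top_method
    marks: dict[str, dict[str, str]] = {}
    for method in result.methods[1:]:
        marks[method] = {}
        for k, metric in enumerate(METRIC_NAMES):
            mark, _p = compare_to_best(series[best][:, k], series[method][:, k], config)
            marks[method][metric] = mark
    return ScenarioResult(
        scenario_id=result.scenario_id,
        f_positive_rate=result.f_positive_rate,
        methods=result.methods,
        mean=result.mean,
        repeats=result.repeats,
        marks=marks,
    )
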