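"""End-to-end orchestration and tabular exports.

:func:`run_all` drives a complete assessment from a single
:class:`RunConfig` — either on CAID-style files on disk or on a freshly
generated synthetic corpus — and writes:

* ``table_s1.tsv`` / ``table_s2.tsv`` / ``table_s3.tsv`` — per-method metric
  tables, methods sorted by descending mean AUC, each non-top cell suffixed
  with its significance mark (``+``/``=``) relative to the top method;
* ``scheme_comparison.tsv`` — best method per protein-level scoring scheme;
* ``curves/`` — ROC and PR vertices for the top methods per scenario;
* ``summary.tsv`` — per-method (AUC_S1, AUC_S2, AUC_S3) triples;
* ``dataset_stats.tsv`` and ``run.log``.

Metric cells print at 3 decimals, the partial-AUC ratio at 2, matching the
precision the metrics are conventionally reported at.  A failed stage aborts
the run and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import statistics
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    Channel,
    Dataset,
    ReferenceEntry,
    ResidueLabel,
    filter_by_coverage,
    merge_channels,
    read_predictions,
    read_reference,
)
from .metrics import METRIC_NAMES, pr_curve, roc_curve
from .protein_scores import DEFAULT_SCHEMES, SchemeComparison, SchemeKind, SchemeSpec, compare_schemes
from .scenarios import (
    ScenarioId,
    ScenarioResult,
    ScenarioSpec,
    protein_sample,
    rebalance_sample,
    residue_pool,
    extract_sample,
    run_protein_scenario,
    run_residue_scenario,
)
from .significance import SignificanceConfig, annotate
from .synthetic import SyntheticConfig, SyntheticPredictorSpec, generate_corpus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset statistics
# ---------------------------------------------------------------------------

def dl_segment_lengths(entries: Sequence[ReferenceEntry]) -> list[int]:
    """Lengths of maximal runs of DL-labeled residues, across all proteins."""
    out = []
    for e in entries:
        is_dl = np.r_[False, e.residue_labels == ResidueLabel.DL, False].astype(np.int8)
        edges = np.diff(is_dl)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        out.extend((ends - starts).tolist())
    return out


@dataclass(frozen=True)
class DatasetStats:
    """Headline composition of a labeled benchmark dataset."""

    n_proteins: int
    n_residues: int
    n_unknown: int
    n_disordered: int
    n_dl_residues: int
    n_dl_proteins: int
    dl_length_min: int | None = None
    dl_length_median: float | None = None
    dl_length_max: int | None = None

    @classmethod
    def from_counts(
        cls,
        n_proteins: int,
        n_residues: int,
        n_disordered: int,
        n_dl_residues: int,
        n_dl_proteins: int,
        n_unknown: int = 0,
        dl_lengths: Sequence[int] | None = None,
    ) -> "DatasetStats":
        kw = {}
        if dl_lengths:
            kw = dict(
                dl_length_min=min(dl_lengths),
                dl_length_median=float(statistics.median(dl_lengths)),
                dl_length_max=max(dl_lengths),
            )
        return cls(
            n_proteins=n_proteins,
            n_residues=n_residues,
            n_unknown=n_unknown,
            n_disordered=n_disordered,
            n_dl_residues=n_dl_residues,
            n_dl_proteins=n_dl_proteins,
            **kw,
        )

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "DatasetStats":
        if not dataset.entries:
            raise ValueError("empty dataset")
        lab = np.concatenate([e.residue_labels for e in dataset.entries])
        lengths = dl_segment_lengths(dataset.entries)
        return cls.from_counts(
            n_proteins=len(dataset.entries),
            n_residues=int(lab.size),
            n_unknown=int(np.sum(lab == ResidueLabel.UNKNOWN)),
            n_disordered=int(np.sum((lab == ResidueLabel.DL) | (lab == ResidueLabel.DISORDERED_OTHER))),
            n_dl_residues=int(np.sum(lab == ResidueLabel.DL)),
            n_dl_proteins=int(sum(e.has_dl for e in dataset.entries)),
            dl_lengths=lengths or None,
        )

    @property
    def pct_dl_proteins(self) -> float:
        """Percentage of proteins harboring at least one DL."""
        return 100.0 * self.n_dl_proteins / self.n_proteins

    @property
    def pct_disordered(self) -> float:
        """Disorder content as a percentage of labeled residues."""
        return 100.0 * self.n_disordered / (self.n_residues - self.n_unknown)

    @property
    def pct_dl_of_disordered(self) -> float:
        """DL residues as a percentage of all disordered residues."""
        return 100.0 * self.n_dl_residues / self.n_disordered

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_proteins", self.n_proteins),
            ("n_residues", self.n_residues),
            ("n_unknown_residues", self.n_unknown),
            ("n_disordered_residues", self.n_disordered),
            ("pct_disordered", round(self.pct_disordered, 2)),
            ("n_dl_residues", self.n_dl_residues),
            ("pct_dl_of_disordered", round(self.pct_dl_of_disordered, 1)),
            ("n_dl_proteins", self.n_dl_proteins),
            ("pct_dl_proteins", round(self.pct_dl_proteins, 1)),
            ("dl_length_min", self.dl_length_min),
            ("dl_length_median", self.dl_length_median),
            ("dl_length_max", self.dl_length_max),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def dataset_stats(dataset: Dataset) -> DatasetStats:
    """Convenience alias for :meth:`DatasetStats.from_dataset`."""
    return DatasetStats.from_dataset(dataset)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one assessment run.

    Exactly one input mode applies: ``synthetic`` (a generator config, with
    optional explicit ``predictors``) or file paths (``linker_reference``,
    optionally ``disorder_reference``, plus ``prediction_paths``).
    """

    outdir: str = "linkerbench_out"
    seed: int = 0
    n_repeats: int = 10
    coverage_threshold: float = 0.9
    annotate_significance: bool = True
    top_curves: int = 10
    synthetic: SyntheticConfig | None = None
    predictors: list[SyntheticPredictorSpec] | None = None
    linker_reference: str | None = None
    disorder_reference: str | None = None
    prediction_paths: dict[str, str] | None = None
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.predictors is not None:
            for p in d["predictors"]:
                p["kind"] = str(p["kind"].value) if hasattr(p["kind"], "value") else str(p["kind"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if d.get("predictors") is not None:
            from .synthetic import PredictorKind

            d["predictors"] = [
                SyntheticPredictorSpec(
                    name=p["name"],
                    kind=PredictorKind(p["kind"]),
                    discriminability=p.get("discriminability", 1.0),
                    noise_seed=p.get("noise_seed", 0),
                )
                for p in d["predictors"]
            ]
        if d.get("significance") is not None:
            d["significance"] = SignificanceConfig(**d["significance"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# table / curve writers
# ---------------------------------------------------------------------------

_DECIMALS = {"auc": 3, "low_auc_ratio": 2, "auprc": 3, "f1max": 3, "mccmax": 3}
_COLUMN_TITLES = {
    "auc": "AUC",
    "low_auc_ratio": "lowAUCratio",
    "auprc": "AUPRC",
    "f1max": "F1max",
    "mccmax": "MCCmax",
}


def format_cell(value: float, metric: str, mark: str | None = None) -> str:
    text = f"{value:.{_DECIMALS[metric]}f}"
    return text + mark if mark else text


def result_table(result: ScenarioResult) -> pd.DataFrame:
    """Tabular view of a scenario result: one row per method, top first."""
    rows = []
    for method in result.methods:
        bundle = result.mean[method]
        marks = (result.marks or {}).get(method, {})
        row = {"Predictor": method}
        for metric in METRIC_NAMES:
            row[_COLUMN_TITLES[metric]] = format_cell(bundle[metric], metric, marks.get(metric))
        rows.append(row)
    return pd.DataFrame(rows)


def scheme_table(comparison: SchemeComparison) -> pd.DataFrame:
    rows = [
        {
            "scheme": r.scheme.name,
            "best_AUC_method": r.best_auc_method,
            "AUC": f"{r.best_auc:.3f}",
            "best_AUPRC_method": r.best_auprc_method,
            "AUPRC": f"{r.best_auprc:.3f}",
        }
        for r in comparison.reports
    ]
    df = pd.DataFrame(rows)
    df["winner"] = [r.scheme == comparison.winner for r in comparison.reports]
    return df


def _write_curves(
    dataset: Dataset,
    result: ScenarioResult,
    outdir: Path,
    scheme: SchemeSpec | None,
    top_n: int,
    seed: int,
) -> None:
    """ROC/PR vertex export for the top methods of one scenario.

    Residue scenarios use the first repeat's rebalanced draw so the exported
    curves match the first entry of each method's repeat series.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    preds = {p.method_name: p for p in dataset.predictions}
    if result.scenario_id is not ScenarioId.S3_PROTEIN:
        pool = residue_pool(dataset, result.scenario_id)
        sel = rebalance_sample(pool, result.f_positive_rate, seed)
    for method in result.methods[:top_n]:
        if result.scenario_id is ScenarioId.S3_PROTEIN:
            sample = protein_sample(dataset, preds[method], scheme)
        else:
            sample = extract_sample(dataset, pool, sel, preds[method])
        roc = roc_curve(sample)
        pr = pr_curve(sample)
        frames = [
            pd.DataFrame({"curve": "roc", "x": roc.fpr, "y": roc.tpr}),
            pd.DataFrame({"curve": "pr", "x": pr.recall, "y": pr.precision}),
        ]
        path = outdir / f"{result.scenario_id.value.lower()}_{method}.tsv"
        pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def load_dataset(config: RunConfig) -> Dataset:
    """Materialize the dataset a config describes (synthetic or from files)."""
    if config.synthetic is not None:
        return generate_corpus(config.synthetic, config.predictors)
    if config.linker_reference is None or not config.prediction_paths:
        raise ValueError("config must provide either a synthetic section or reference + prediction paths")
    linker = read_reference(config.linker_reference, Channel.LINKER)
    disorder = (
        read_reference(config.disorder_reference, Channel.DISORDER)
        if config.disorder_reference
        else None
    )
    if disorder is None:
        logger.warning("no disorder channel configured; S2 will be skipped")
    entries = merge_channels(linker, disorder)
    predictions = [
        read_predictions(path, name, reference=entries)
        for name, path in sorted(config.prediction_paths.items())
    ]
    return Dataset(entries=entries, predictions=predictions)


def run_all(config: RunConfig) -> Path:
    """Execute the full assessment; returns the output directory.

    Stages: load/generate -> coverage filter -> dataset stats -> S1 -> S2 ->
    scheme comparison -> S3 (winning scheme) -> curves -> summary.  Any stage
    error aborts the run with a stage-named message and removes the partial
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    stage_dir = Path(tempfile.mkdtemp(prefix=".linkerbench-", dir=outdir.parent))
    handler = logging.FileHandler(stage_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("linkerbench")
    keep_level = root.level
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    stage = "setup"
    try:
        stage = "load"
        dataset = load_dataset(config)
        stage = "coverage-filter"
        dataset = filter_by_coverage(dataset, config.coverage_threshold)
        if not dataset.predictions:
            raise ValueError("no methods left after the coverage filter")

        stage = "dataset-stats"
        stats = DatasetStats.from_dataset(dataset)
        stats.to_frame().to_csv(stage_dir / "dataset_stats.tsv", sep="\t", index=False)

        sig = replace(config.significance, seed=config.significance.seed + config.seed)
        results: dict[str, ScenarioResult] = {}

        stage = "scenario-s1"
        spec1 = ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, n_repeats=config.n_repeats, base_seed=config.seed)
        res1 = run_residue_scenario(dataset, spec1)
        if config.annotate_significance:
            res1 = annotate(res1, dataset, sig)
        results["s1"] = res1

        stage = "scenario-s2"
        has_other = any(
            np.any(e.residue_labels == ResidueLabel.DISORDERED_OTHER) for e in dataset.entries
        )
        if has_other:
            spec2 = ScenarioSpec(
                ScenarioId.S2_RESIDUE_DISORDERED, n_repeats=config.n_repeats, base_seed=config.seed
            )
            res2 = run_residue_scenario(dataset, spec2)
            if config.annotate_significance:
                res2 = annotate(res2, dataset, sig)
            results["s2"] = res2
        else:
            logger.warning("no other-disordered residues available; skipping S2")

        stage = "scheme-comparison"
        comparison = compare_schemes(dataset)
        scheme_table(comparison).to_csv(stage_dir / "scheme_comparison.tsv", sep="\t", index=False)

        stage = "scenario-s3"
        spec3 = ScenarioSpec(ScenarioId.S3_PROTEIN, base_seed=config.seed)
        res3 = run_protein_scenario(dataset, comparison.winner, spec3)
        if config.annotate_significance:
            res3 = annotate(res3, dataset, sig, scheme=comparison.winner)
        results["s3"] = res3

        stage = "tables"
        for key, res in results.items():
            result_table(res).to_csv(stage_dir / f"table_{key}.tsv", sep="\t", index=False)

        stage = "curves"
        for key, res in results.items():
            _write_curves(
                dataset,
                res,
                stage_dir / "curves",
                scheme=comparison.winner,
                top_n=config.top_curves,
                seed=config.seed,
            )

        stage = "summary"
        methods = sorted({m for res in results.values() for m in res.methods})
        summary = pd.DataFrame(
            {
                "Predictor": methods,
                **{
                    f"AUC_{key.upper()}": [
                        f"{results[key].mean[m].auc:.3f}" if key in results and m in results[key].mean else ""
                        for m in methods
                    ]
                    for key in ("s1", "s2", "s3")
                    if key in results
                },
            }
        )
        summary.to_csv(stage_dir / "summary.tsv", sep="\t", index=False)

        stage = "config"
        config.to_yaml(stage_dir / "run_config.yaml")
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(keep_level)
        shutil.rmtree(stage_dir, ignore_errors=True)
        raise RuntimeError(f"run failed during stage '{stage}': {exc}") from exc
    root.removeHandler(handler)
    handler.close()
    root.setLevel(keep_level)

    outdir.mkdir(parents=True, exist_ok=True)
    for item in stage_dir.iterdir():
        target = outdir / item.name
        if target.exists():
            if target.is_dir():
                shutil.rmtree(target)
            else:
                target.unlink()
        shutil.move(str(item), str(target))
    stage_dir.rmdir()
    return outdir
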