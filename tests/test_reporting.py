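import numpy as np
import pandas as pd
import pytest

from linkerbench import (
    Dataset,
    ReferenceEntry,
    RunConfig,
    SignificanceConfig,
    dataset_stats,
)
from linkerbench.reporting import DatasetStats, format_cell, load_dataset, result_table, run_all
from linkerbench.synthetic import default_predictor_suite, generate_corpus, write_corpus

from conftest import small_config


class TestDatasetStats:
    def test_benchmark_count_arithmetic(self):
        """Percentages derived from the benchmark's published counts."""
        stats = DatasetStats.from_counts(
            n_proteins=348,
            n_residues=287_020,
            n_disordered=37_072,
            n_dl_residues=2_023,
            n_dl_proteins=40,
        )
        assert round(stats.pct_dl_proteins, 1) == 11.5
        assert round(stats.pct_disordered, 2) == 12.92
        assert round(stats.pct_dl_of_disordered, 1) == 5.5

    def test_curated_database_rate(self):
        stats = DatasetStats.from_counts(
            n_proteins=2649, n_residues=1, n_disordered=1, n_dl_residues=0, n_dl_proteins=282
        )
        assert round(stats.pct_dl_proteins, 1) == 10.6

    def test_from_dataset_counts(self):
        labels = np.array([2, 2, 1, 0, 0, -1], dtype=np.int8)
        ds = Dataset([ReferenceEntry("P1", "A" * 6, labels)])
        stats = dataset_stats(ds)
        assert stats.n_residues == 6
        assert stats.n_unknown == 1
        assert stats.n_disordered == 3  # DL residues count as disordered
        assert stats.n_dl_residues == 2
        assert stats.n_dl_proteins == 1
        assert stats.dl_length_min == stats.dl_length_max == 2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            dataset_stats(Dataset([]))


class TestFormatting:
    def test_metric_precision_three_decimals(self):
        assert format_cell(0.71234, "auc") == "0.712"
        assert format_cell(0.5, "f1max", "+") == "0.500+"

    def test_partial_auc_ratio_two_decimals(self):
        assert format_cell(2.649, "low_auc_ratio") == "2.65"


@pytest.fixture(scope="module")
def run_dirs(tmp_path_factory):
    """Two identical small runs, used for smoke and determinism checks."""
    base = tmp_path_factory.mktemp("runs")
    outs = []
    for name in ("one", "two"):
        cfg = RunConfig(
            outdir=str(base / name),
            seed=3,
            n_repeats=3,
            synthetic=small_config(seed=3),
            significance=SignificanceConfig(n_subsamples=6),
        )
        outs.append(run_all(cfg))
    return outs


ARTIFACTS = [
    "table_s1.tsv",
    "table_s2.tsv",
    "table_s3.tsv",
    "scheme_comparison.tsv",
    "summary.tsv",
    "dataset_stats.tsv",
    "run.log",
]


class TestRunAll:
    def test_all_artifacts_exist_and_parse(self, run_dirs):
        out = run_dirs[0]
        for name in ARTIFACTS:
            assert (out / name).exists(), name
            if name.endswith(".tsv"):
                assert not pd.read_csv(out / name, sep="\t").empty
        assert any(out.joinpath("curves").glob("s1_*.tsv"))

    def test_tables_sorted_by_auc_and_top_row_unmarked(self, run_dirs):
        df = pd.read_csv(run_dirs[0] / "table_s1.tsv", sep="\t")
        assert not df.loc[0, "AUC"].endswith(("+", "="))
        vals = [float(v.rstrip("+=")) for v in df["AUC"]]
        assert vals == sorted(vals, reverse=True)
        for v in df["AUC"][1:]:
            assert v.endswith(("+", "="))

    def test_reruns_are_byte_identical(self, run_dirs):
        one, two = run_dirs
        for name in [a for a in ARTIFACTS if a.endswith(".tsv")]:
            assert (one / name).read_bytes() == (two / name).read_bytes(), name

    def test_partial_outputs_removed_on_failure(self, tmp_path):
        cfg = RunConfig(outdir=str(tmp_path / "bad"), synthetic=None, prediction_paths=None)
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_all(cfg)
        assert not (tmp_path / "bad").exists()
        assert not list(tmp_path.glob(".linkerbench-*"))


class TestFileBackedConfig:
    def test_missing_disorder_channel_skips_s2(self, tmp_path, caplog):
        ds = generate_corpus(small_config(seed=5), default_predictor_suite(noise_seed=6)[:2])
        paths = write_corpus(ds, tmp_path / "corpus")
        cfg = RunConfig(
            outdir=str(tmp_path / "out"),
            seed=1,
            n_repeats=2,
            annotate_significance=False,
            linker_reference=str(paths["linker"]),
            disorder_reference=None,
            prediction_paths={
                p.method_name: str(paths[p.method_name]) for p in ds.predictions
            },
        )
        with caplog.at_level("WARNING", logger="linkerbench"):
            out = run_all(cfg)
        assert (out / "table_s1.tsv").exists()
        assert (out / "table_s3.tsv").exists()
        assert not (out / "table_s2.tsv").exists()
        assert any("S2" in m for m in caplog.messages)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(
            outdir="x",
            seed=9,
            synthetic=small_config(seed=2),
            significance=SignificanceConfig(n_subsamples=4, seed=1),
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back == cfg

    def test_load_dataset_from_files_matches_memory(self, tmp_path):
        ds = generate_corpus(small_config(seed=6), default_predictor_suite(noise_seed=7)[:1])
        paths = write_corpus(ds, tmp_path / "corpus")
        cfg = RunConfig(
            linker_reference=str(paths["linker"]),
            disorder_reference=str(paths["disorder"]),
            prediction_paths={ds.predictions[0].method_name: str(paths[ds.predictions[0].method_name])},
        )
        loaded = load_dataset(cfg)
        assert [e.protein_id for e in loaded.entries] == [e.protein_id for e in ds.entries]
        for a, b in zip(loaded.entries, ds.entries):
            assert np.array_equal(a.residue_labels, b.residue_labels)
        # scores survive at the 3-decimal file precision
        for pid, vec in loaded.predictions[0].scores.items():
            assert np.allclose(vec, ds.predictions[0].scores[pid], atol=5e-4)
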