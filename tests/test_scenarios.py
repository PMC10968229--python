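import numpy as np
import pytest

from linkerbench import (
    Dataset,
    PredictionSet,
    PredictorKind,
    ReferenceEntry,
    ResidueLabel,
    ScenarioId,
    ScenarioSpec,
    SchemeKind,
    SchemeSpec,
    SyntheticPredictorSpec,
    disorder_content,
    dl_protein_rate,
    generate_predictions,
    protein_truth,
    rebalance_sample,
    residue_pool,
    run_protein_scenario,
    run_residue_scenario,
)
from linkerbench.scenarios import extract_sample, subset_dataset

DL = int(ResidueLabel.DL)
OTH = int(ResidueLabel.DISORDERED_OTHER)
UNK = int(ResidueLabel.UNKNOWN)


def _entry(pid, labels):
    labels = np.array(labels, dtype=np.int8)
    return ReferenceEntry(pid, "A" * len(labels), labels)


class TestResiduePool:
    def test_pool_definitions_differ_between_scenarios(self):
        ds = Dataset([_entry("P1", [DL, OTH, 0])])
        s1 = residue_pool(ds, ScenarioId.S1_RESIDUE_ALL)
        s2 = residue_pool(ds, ScenarioId.S2_RESIDUE_DISORDERED)
        assert (s1.n_pos, s1.n_neg) == (1, 2)
        assert (s2.n_pos, s2.n_neg) == (1, 1)

    def test_unknown_never_pooled(self):
        ds = Dataset([_entry("P1", [DL, UNK, 0, UNK])])
        s1 = residue_pool(ds, ScenarioId.S1_RESIDUE_ALL)
        assert s1.y.size == 2

    def test_no_positives_is_error(self):
        ds = Dataset([_entry("P1", [0, 0, OTH])])
        with pytest.raises(ValueError, match="positive"):
            residue_pool(ds, ScenarioId.S1_RESIDUE_ALL)


class TestRebalanceSample:
    def _pool(self, p, n):
        ds = Dataset([_entry("P1", [DL] * p + [0] * n)])
        return residue_pool(ds, ScenarioId.S1_RESIDUE_ALL)

    def test_negative_count_arithmetic(self):
        pool = self._pool(100, 1000)
        sel = rebalance_sample(pool, 0.2, seed=0)
        assert sel.size == 500  # 100 positives + round(100*0.8/0.2) negatives

    def test_half_fraction_balances_classes(self):
        pool = self._pool(37, 100)
        sel = rebalance_sample(pool, 0.5, seed=1)
        assert pool.y[sel].sum() == 37 and sel.size == 74

    def test_caid_scale_arithmetic(self):
        pool = self._pool(2023, 20000)
        sel = rebalance_sample(pool, 0.12916, seed=0)
        assert sel.size - 2023 == round(2023 * (1 - 0.12916) / 0.12916)

    def test_every_positive_kept_exactly_once(self):
        pool = self._pool(25, 400)
        sel = rebalance_sample(pool, 0.3, seed=3)
        assert np.unique(sel).size == sel.size
        assert pool.y[sel].sum() == 25
        realized = pool.y[sel].mean()
        assert abs(realized - 0.3) <= 1.0 / sel.size

    def test_insufficient_negatives_reported(self):
        pool = self._pool(50, 10)
        with pytest.raises(ValueError, match="10"):
            rebalance_sample(pool, 0.2, seed=0)

    def test_seed_determinism(self):
        pool = self._pool(10, 500)
        assert np.array_equal(rebalance_sample(pool, 0.2, 7), rebalance_sample(pool, 0.2, 7))
        assert not np.array_equal(rebalance_sample(pool, 0.2, 7), rebalance_sample(pool, 0.2, 8))


class TestRunResidueScenario:
    def test_oracle_predictor_is_perfect_in_both_scenarios(self, small_corpus):
        oracle = generate_predictions(
            small_corpus.entries, SyntheticPredictorSpec("oracle", PredictorKind.ORACLE)
        )
        ds = Dataset(small_corpus.entries, [oracle])
        for sid in (ScenarioId.S1_RESIDUE_ALL, ScenarioId.S2_RESIDUE_DISORDERED):
            res = run_residue_scenario(ds, ScenarioSpec(sid, n_repeats=2, base_seed=0))
            assert res.mean["oracle"].auc == pytest.approx(1.0)

    def test_constant_predictor_is_random_level(self, small_corpus):
        flat = PredictionSet(
            "flat", {e.protein_id: np.full(e.length, 0.5) for e in small_corpus.entries}
        )
        ds = Dataset(small_corpus.entries, [flat])
        res = run_residue_scenario(
            ds, ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, n_repeats=3, base_seed=0)
        )
        assert res.mean["flat"].auc == pytest.approx(0.5)
        assert res.mean["flat"].low_auc_ratio == pytest.approx(1.0)

    def test_identical_seeds_reproduce_bundles_exactly(self, small_corpus):
        spec = ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, n_repeats=2, base_seed=5)
        a = run_residue_scenario(small_corpus, spec)
        b = run_residue_scenario(small_corpus, spec)
        for m in a.mean:
            assert np.array_equal(a.mean[m].as_array(), b.mean[m].as_array())

    def test_mean_bundle_is_average_of_repeats(self, small_corpus):
        res = run_residue_scenario(
            small_corpus, ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, n_repeats=4, base_seed=0)
        )
        for m in res.methods:
            stacked = np.mean([b.as_array() for b in res.repeats[m]], axis=0)
            assert res.mean[m].as_array() == pytest.approx(stacked)

    def test_methods_ranked_by_mean_auc(self, small_corpus):
        res = run_residue_scenario(
            small_corpus, ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, n_repeats=2, base_seed=0)
        )
        aucs = [res.mean[m].auc for m in res.methods]
        assert aucs == sorted(aucs, reverse=True)

    def test_unpredicted_proteins_dropped_per_method(self, small_corpus):
        partial = {
            e.protein_id: np.full(e.length, 0.5) for e in small_corpus.entries[: len(small_corpus.entries) // 2]
        }
        ds = Dataset(small_corpus.entries, [PredictionSet("half", partial)])
        pool = residue_pool(ds, ScenarioId.S1_RESIDUE_ALL)
        sel = rebalance_sample(pool, disorder_content(ds), seed=0)
        sample = extract_sample(ds, pool, sel, ds.predictions[0])
        assert sample.scores.size < sel.size  # residues of missing proteins removed

    def test_disorder_aware_is_random_in_s2_but_not_s1(self, small_corpus):
        """A generic disorder predictor cannot separate linkers from other
        disordered residues, while remaining clearly better than random on
        the whole-sequence task."""
        spec = dict(n_repeats=5, base_seed=2)
        s1 = run_residue_scenario(small_corpus, ScenarioSpec(ScenarioId.S1_RESIDUE_ALL, **spec))
        s2 = run_residue_scenario(small_corpus, ScenarioSpec(ScenarioId.S2_RESIDUE_DISORDERED, **spec))
        assert abs(s2.mean["disorder-strong"].auc - 0.5) < 0.05
        assert s1.mean["disorder-strong"].auc > s2.mean["disorder-strong"].auc + 0.2


class TestProteinScenario:
    def test_protein_truth_definition(self):
        ds = Dataset([_entry("P1", [DL, 0]), _entry("P2", [OTH, OTH]), _entry("P3", [0, 0])])
        assert protein_truth(ds).tolist() == [True, False, False]
        assert dl_protein_rate(ds) == pytest.approx(1 / 3)

    def test_dl_protein_count_matches_config_rounding(self, small_corpus):
        # round(100 * 0.115) = 12 DL-harboring proteins in the small corpus
        assert int(protein_truth(small_corpus).sum()) == 12

    def test_oracle_scores_identify_dl_proteins_perfectly(self, small_corpus):
        oracle = generate_predictions(
            small_corpus.entries, SyntheticPredictorSpec("oracle", PredictorKind.ORACLE)
        )
        ds = Dataset(small_corpus.entries, [oracle])
        res = run_protein_scenario(
            ds, SchemeSpec(SchemeKind.SLIDING_WINDOW, 10), ScenarioSpec(ScenarioId.S3_PROTEIN)
        )
        assert res.mean["oracle"].auc == pytest.approx(1.0)

    def test_constant_predictor_random_at_protein_level(self, small_corpus):
        flat = PredictionSet(
            "flat", {e.protein_id: np.full(e.length, 0.5) for e in small_corpus.entries}
        )
        ds = Dataset(small_corpus.entries, [flat])
        res = run_protein_scenario(
            ds, SchemeSpec(SchemeKind.TOP_K, 10), ScenarioSpec(ScenarioId.S3_PROTEIN)
        )
        assert res.mean["flat"].auc == pytest.approx(0.5)

    def test_missing_proteins_absent_from_sample(self, small_corpus):
        half = {
            e.protein_id: np.full(e.length, 0.5) for e in small_corpus.entries[:90]
        }
        ds = Dataset(small_corpus.entries, [PredictionSet("half", half)])
        from linkerbench import protein_sample

        sample = protein_sample(ds, ds.predictions[0], SchemeSpec(SchemeKind.TOP_K, 10))
        assert sample.labels.size == 90


def test_subset_dataset_restricts_entries_and_predictions(small_corpus):
    sub = subset_dataset(small_corpus, [0, 5, 7])
    assert len(sub.entries) == 3
    keep = {e.protein_id for e in sub.entries}
    for p in sub.predictions:
        assert set(p.scores) <= keep
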