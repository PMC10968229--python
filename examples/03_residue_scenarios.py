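"""Run the two residue-level scenarios on a synthetic predictor panel.

Scenario 1 asks whether a method finds linker residues among all residues;
scenario 2 asks the harder question of separating linker residues from
*other disordered* residues.  Generic disorder predictors do well in S1 but
collapse to random in S2, because linkers and other disordered residues are
exchangeable for them — the central contrast this toolkit measures.
"""

from linkerbench import (
    ScenarioId,
    ScenarioSpec,
    SyntheticConfig,
    default_predictor_suite,
    generate_corpus,
    run_residue_scenario,
)

dataset = generate_corpus(SyntheticConfig(seed=0), default_predictor_suite(noise_seed=1))

for sid, label in [
    (ScenarioId.S1_RESIDUE_ALL, "S1: DL vs all non-DL residues"),
    (ScenarioId.S2_RESIDUE_DISORDERED, "S2: DL vs other disordered residues"),
]:
    res = run_residue_scenario(dataset, ScenarioSpec(sid, n_repeats=10, base_seed=0))
    print(label)
    for m in res.methods:
        b = res.mean[m]
        print(f"  {m:>16}  AUC={b.auc:.3f}  lowAUCratio={b.low_auc_ratio:.2f}  AUPRC={b.auprc:.3f}")
    print()
print("-> disorder-aware methods drop to AUC ~0.5 in S2; linker-aware ones do not.")
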