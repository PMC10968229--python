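# Methods

`linkerbench` evaluates predictors of disordered flexible linkers (DLs) —
intrinsically disordered regions that connect and permit movement between
adjacent functional regions of a protein.  Predictors emit one propensity in
[0, 1] per residue; the toolkit scores those propensities against per-residue
ground truth in three scenarios, attaches resampling-based significance
marks, and ships a synthetic benchmark generator with analytically known
ground truth so the whole pipeline is testable without external data.

## Data model

Ground truth arrives as two FASTA-like channel files (header, sequence, and a
`1/0/-` label string): a *linker* channel and a *disorder* channel.  Merging
them yields four residue classes: `DL`, `DISORDERED_OTHER`, `ORDERED`, and
`UNKNOWN` (`-` in either channel).  A residue flagged as linker but not
disordered is kept as `DL` with a logged warning — the linker annotation is
the evaluation's ground truth and the disorder channel is auxiliary.
`UNKNOWN` residues are excluded from every positive/negative pool, but a
method must still score them for the protein to count as predicted: partial
score vectors are treated as the protein being unpredicted, because mixing
residue subsets across methods would make the comparisons incommensurable.

Methods with coverage (fraction of fully predicted proteins) strictly below
90% are excluded; a method at exactly 90% is retained.

## Scenarios and rebalanced sampling

* **S1** — DL residues vs. all non-DL, non-unknown residues.
* **S2** — DL residues vs. other disordered residues only.
* **S3** — proteins harboring at least one DL residue vs. the rest.

DL residues are rare (~0.7% of residues), so S1/S2 samples are rebalanced:
all positives are kept and `round(P(1-f)/f)` negatives are drawn uniformly
without replacement, making the positive fraction equal a target `f` — by
default the dataset's disorder content (12.92% at the default generator
scale).  This puts linker results on the same class balance as published
disorder-prediction results.  The draw is repeated (default 10 repeats,
seeds `base_seed..base_seed+9`); each draw is shared by all methods, and
reported values are arithmetic means over repeats.  Methods are ranked by
mean AUC.  S3 applies no rebalancing; its empirical positive rate only
parameterizes the partial AUC.

## Metrics

For a scored sample with positive rate `f`:

* **AUC** — trapezoidal area under the tie-grouped ROC curve (equals the
  Mann–Whitney probability with half credit for ties).
* **lowAUCratio** — the ROC area restricted to false positive rates in
  `[0, f]` (curve linearly interpolated at `f`), divided by `f²/2`, the same
  partial area of a random predictor.  1 is random-level; 2 is twice the
  random partial area; the attainable maximum is `2/f`.  It isolates the
  conservative regime where no more residues are called linker than truly
  are.
* **AUPRC** — average precision (step-wise sum of precision × recall
  increments).  No linear interpolation is used in PR space, which is known
  to be optimistic.
* **F1max / MCCmax** — maxima over all binarization thresholds with the
  predicate `score >= threshold`; threshold ties resolve to the higher
  threshold (fewer predicted positives); any confusion matrix that zeroes
  the MCC denominator scores 0, keeping the scan total.

Curve construction is delegated to scikit-learn; the partial-area ratio and
the threshold scans are implemented here and are verified in the test suite
against exhaustive pair-counting and enumeration oracles on all small
samples.

## Protein-level scores

Four schemes collapse a residue propensity vector to one protein score:
highest sliding-window mean at window length 10 (minimal DL length) or 31
(median DL length), and the mean of the top 10 or top 20 propensities.
Windows are fully contained (no padding; edge-truncated windows would dilute
edge linkers asymmetrically); sequences shorter than the window fall back to
the whole-sequence mean.  A whole-sequence average is deliberately not a
scheme, since linkers cover a small fraction of a sequence.  Scheme
comparison reports the best method per scheme by AUC and by AUPRC; ties
between schemes resolve in the listed order (window10, window31, top10,
top20) for determinism.

## Significance protocol

To test whether the top method's lead is robust, 50% of the proteins are
sampled 10 times; every method's metrics are recomputed on each subsample
(the rebalancing draw inside a subsample uses one shared per-subsample seed,
so series are paired across methods); each method's series is compared with
the top method's series per metric.  The paired differences are screened
with the Anderson–Darling normality test at 0.05; normal-looking differences
go to a paired t-test, others to the Wilcoxon signed-rank test (zeros
dropped).  Tests are two-sided; `+` requires p strictly below 0.05.
Identical series short-circuit to `=` with p = 1.

**Caveat.**  This protocol quantifies sensitivity of the ranking to the
protein sample, not sampling error in the methods themselves.  Conditional
on one realized pair of score sets, the performance gap between two methods
is a fixed quantity of the same order as the subsample-to-subsample
fluctuation, and the ten 50% subsamples overlap, so the paired test detects
even gaps that are pure noise at the method level.  Measured on pairs of
identically generated synthetic predictors, the per-metric `+` rate is
roughly 0.4–0.5 rather than the nominal 0.05 (the test suite computes this
number; see also `null_plus_rate_auc` in the acceptance script output).
Marks should therefore be read as "the gap is stable across protein
subsets", not as evidence that two methods differ beyond their own noise.

## Synthetic benchmark generator

The generator reproduces the composition of the benchmark the toolkit
targets.  Defaults: 348 proteins with log-normal lengths
(`exp(N(6.55, 0.70²))`, clipped to [50, 2000]; ≈820 residues per protein,
≈287k in total); exactly `round(0.115 × n)` = 40 proteins receive 1–2
non-overlapping DL segments; segment lengths are log-normal
(`median 31, σ_log = 0.6`, clipped to [10, 288]) with the sample log-median
recentred onto 31, and extra segments are appended only while they bring the
DL-residue total closer to 5.5% of the disorder target; other-disordered
segments (log-normal, median ≈22) are then placed until disorder content
reaches 12.92% as closely as segment granularity allows; DL segments are
flanked by other-disordered context with probability 0.5 per side, mimicking
linkers embedded in disordered regions.  All randomness flows from named
seeds, and equal seeds give byte-identical files.

Synthetic predictors are Gaussian-latent: latent = `d·1[positive class] +
N(0, 1)` and propensity = `logistic(latent)`.  The squashing is strictly
monotone, so ranking metrics are untouched and the expected AUC against the
stated negative class is `Φ(d/√2)` exactly — which gives the test suite an
analytic surface to verify the pipeline against (a predictor built for
AUC 0.75 must measure 0.75 ± Monte Carlo error end-to-end).  Kinds:
`DL_AWARE` (positive class = DL), `DISORDER_AWARE` (positive class = all
disordered; by exchangeability its expected S2 AUC is 0.5, reproducing the
qualitative failure of generic disorder predictors on the linker-vs-other-
disordered task), `RANDOM`, and `ORACLE`.  Default discriminabilities target
expected AUC 0.85 for the strong disorder predictor (typical of leading
disorder predictors on their own task) and 0.75/0.65 for the linker-aware
pair (bracketing the best published linker-prediction AUCs).

What the generator does *not* emulate: realistic amino-acid composition or
sequence-dependent error structure, correlated errors along the chain, or
per-protein difficulty heterogeneity beyond segment placement.  Passing
tests therefore demonstrate correctness of the evaluation machinery and of
the statistical contrasts it is designed to expose, not the behaviour of
any real predictor on real proteins.

## Numerical and design choices

* Tie handling in ROC curves follows the standard grouped-threshold
  convention (one vertex per distinct score, half credit in the area).
* 1-based residue indices on disk, 0-based in memory; all file outputs are
  1-based.  Prediction files round propensities to 3 decimals.
* Table cells print at 3 decimals (2 for lowAUCratio).
* `round()` (banker's rounding) is used for all count targets; at the
  default scale none of the targets sit on a .5 boundary.
* Scaled-down problem sizes in the test suite: a 100-protein corpus with
  proportionally shorter proteins and DL segments (median 14) keeps the
  rebalancing sampler feasible inside 50% protein subsamples; the
  calibration study uses 60-protein corpora over 200 generator seeds; the
  full-scale 348-protein corpus is used wherever a claim depends on the
  benchmark's actual composition.

## Known limitations

* The significance protocol's anticonservatism under method-level noise
  (above) is inherent to the protocol, not fixed here, because the point of
  the package is to implement that protocol as practised.
* The generator's segment-granularity stopping rule leaves the realized
  DL fraction of disordered residues within about ±0.5 percentage points of
  its 5.5% target on typical seeds.
* S2 requires an other-disordered negative pool at least `(1-f)/f` times the
  DL residue count; datasets (or subsamples) that are too linker-rich raise
  an explicit error rather than silently shrinking the sample.
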