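# Methods

## Problem and scope

`compscore` implements the quantitative machinery for interpreting yeast
functional-complementation assays of human disease-gene variants.  A human
gene that rescues a temperature-sensitive (ts) yeast mutant at the
nonpermissive temperature defines an assay: a missense variant that fails to
rescue is evidence of pathogenicity.  The package covers the downstream
analysis only — growth-curve kinetics, the FCS/FCT scores, reference-set
construction, benchmarking against computational predictors, score
calibration and fusion, contamination sensitivity, and Bayesian posterior
conversion.  Wet-lab steps, spot-image quantification and the computation of
predictor scores (PolyPhen2-like tools) are out of scope; spotting grades
and predictor scores enter as curated inputs.

## Growth kinetics

A well's OD600 time course is reduced to an exponential rate as follows.

1. **Baseline and detection.** Baseline is the mean of the first three
   reads.  Growth is detected at the first read where OD exceeds baseline by
   `detect_threshold` (default 0.05 OD).  The threshold is a knob because
   "detectable growth" has no standard operationalisation; 0.05 sits well
   above plate-reader noise (typically < 0.01 OD) while catching cultures
   early in log phase.
2. **Provisional rate.** The maximum slope of ln(OD) over all 5-read sliding
   windows after detection.  This fixes the doubling time used for the
   window cap without any iterative fitting.
3. **Log-phase fit.** The reported rate is the least-squares slope of
   ln(OD) vs time over a window that starts at detection and ends, at the
   latest, five doubling times (of the provisional rate) later.  Within that
   cap the window end is chosen to maximise the fit R², with near-ties
   (within 1e-9) resolved toward the longer window.  The R² selection is
   what makes the estimate robust to saturation: on a noise-free logistic
   curve with carrying capacity 100x the inoculum, a fixed five-doubling
   window drags the estimate 11–22% low because detection (at OD ~0.07)
   leaves barely five doublings before the carrying capacity, whereas the
   R²-selected end keeps the error under 5%.  On noise-free exponentials all
   window ends tie and the full five-doubling window is used, recovering the
   closed-form rate to well under 1%.
4. **Units and floors.** Times are minutes everywhere; rates are per hour,
   converted only at the fit.  OD values ≤ 0 (possible after noise) are
   floored at half the smallest positive OD so the log is defined.

The relative growth rate µ divides a test strain's rate by that of the same
ts strain carrying the wild-type human allele.  Saturation bias largely
cancels in this ratio because, for strains measured under the same
conditions, the bias is approximately a fixed fraction of the rate.  An
undetected test strain has µ = 0; an undetected (or non-growing) wild-type
reference invalidates the assay, because rescue by the wild-type allele is
the assay's positive control.  Replicates combine by the arithmetic mean;
replicate concordance is the Pearson correlation of µ vectors across ≥ 3
strains and is reported as undefined otherwise.

## Complementation scores

* **FCS** maps the four spotting grades onto {0, 0.6, 0.8, 1}; scores at or
  above 0.6 are deleterious calls.  The threshold is closed at 0.6 so the
  "reduced complementation" grade itself counts as deleterious.
* **FCT** = (1 − µ_VARIANT)/(1 − µ_GFP), clamped to [0, 1] with the raw
  value kept for diagnostics.  It requires µ_GFP < 1 (a GFP control as fast
  as the wild-type rescue means no signal window).
* **Reversed mode** handles genes where the wild-type human allele itself
  slows the yeast host, so loss-of-function variants grow *faster* than
  wild type (the uroporphyrinogen III synthase behaviour):
  FCT_rev = (µ_VARIANT − 1)/(µ_FASTEST − 1), with the inverted grade
  vocabulary for FCS.  A gene is flagged for reversed scoring when the
  median µ across ≥ 3 of its variants exceeds 1; the median makes the
  trigger robust to a single fast outlier, and with fewer than 3 variants
  standard mode is kept.

Clamping is a package decision: the 0–1 scale is declared but out-of-range
behaviour is not defined anywhere, and a variant rescuing better than wild
type in standard mode is "0, wild-type-like" for interpretation purposes.

## Reference sets

The positive class can be restricted by annotation stringency: all
disease-annotated variants; HGMD disease-causing (DM) only; DM intersected
with ClinVar-pathogenic; DM absent from ClinVar; and, within the
DM-and-ClinVar set, four allele-frequency modes (ExAC MAF available,
< 1e-5, < 1e-4, < 1e-3).  MAF thresholds are strict inequalities and
records without a MAF are excluded from every ExAC mode.  Negatives (the
non-disease-annotated variants) are never filtered.  Causality
classification is binary: DM is causal; DM?, DP, DFP, FP and unannotated
are noncausal.

## Benchmark statistics

* PR curves group tied scores into one operating point per unique value;
  AUPRC is the conservative step sum Σ (r_i − r_{i−1})·p_i with no linear
  interpolation (linear PR interpolation is known to be optimistic).
* AUROC is the normalised Mann-Whitney rank-sum with ties counting 1/2 —
  exactly the probability that a random positive outranks a random negative.
* REC90 is the maximum recall over operating points with precision ≥ 90%.
* MCC is computed at a stated threshold: 0.6 for FCS/FCT; computational
  scorers are binarized at the threshold matching the FCS recall (the
  matched-recall comparison), since no canonical cutoff exists for them.
* Matched-recall threshold: the largest score value whose recall reaches
  the target; tie grouping means this is also the highest-precision such
  point.
* Variants missing a score are excluded pairwise and counted.
* Fisher's exact test, the Wilcoxon rank-sum test and Pearson correlation
  are delegated to scipy.stats; the odds ratio reported is the sample
  (ad)/(bc).  Fisher tests default to two-sided; the one-sided variant
  tests enrichment of the top-left cell.

## Calibration and fusion

Raw FCS and predictor scores are incommensurable, so both are mapped to
precisions by 10-fold held-out calibration: for a held-out allele with raw
score s, the calibrated score is the precision among training alleles with
score ≥ s.  Two edge rules: when no training allele reaches s, the value is
the training prior (the limit of the precision as the cutoff drops through
the whole training set); folds are redrawn (up to 100 seeded attempts) if
any training split lacks a class.  No smoothing is applied, so calibrated
scores need not be monotone in the raw score within a fold — this is a
property of precision-at-cutoff, documented rather than "fixed".  The
combiners are minimum, maximum, mean, and weighted means with 0.9/0.8/0.7/
0.6 weight on the experimental score; all are bounded by their inputs.

## Contamination and Bayes

Disease-mutation databases carry false annotations (prior estimates run as
high as 27%).  The contamination simulation holds the positive-set size
fixed and replaces ⌈c·n⌉ stringent positives with negatives sampled without
replacement (c = 0.27 by default); sampled negatives are removed from the
negative class so no variant scores on both sides.  Performance is tracked
as AUPRC_norm = AUPRC/prior, which removes the mechanical effect of the
prior on precision; the distribution over 10,000 rebuilds is compared with
the clean value.  The fixed-size replacement reading keeps the positive
class at the stated 73/27 composition without changing the benchmark's
class balance.

Likelihood ratios come from the assay's confusion counts, LR+ =
sens/(1 − spec), LR− = (1 − sens)/spec, and update any disease prior
through posterior odds = prior odds × LR.  Perfect specificity yields an
infinite LR+ marker (posterior 1); zero specificity is rejected.

## Synthetic data

The generator defines the conditions under which everything is tested.

* **Growth curves**: lag phase (default 120 min), then logistic growth at
  rate `base_rate · true_mu` toward a carrying capacity, plus i.i.d.
  Gaussian read noise.  Defaults: 15-min read cadence, 97 reads (24 h),
  inoculum OD 0.02 (≈10⁵ cells in 100 µL), carrying capacity 2.0 OD,
  wild-type rate ~0.45/h (doubling ≈ 90 min).  Logistic rather than
  exponential growth is deliberate so the log-phase windowing is exercised;
  real OD noise levels are unreported anywhere, so `noise_sd` is free
  (tests use up to 10% of the inoculum OD).
* **Cohorts**: 101 disease / 78 nondisease variants by default, matching
  the study composition.  Disease variants receive a deleterious FCS level
  with probability `assay_sensitivity` (0.82 by default, the observed
  fraction of disease variants called deleterious), nondisease with
  probability 1 − `assay_specificity` (0.87).  Deleterious draws split
  0.25/0.25/0.5 over levels 0.6/0.8/1 — all levels exercised, complete
  loss commonest; the exact mix is not load-bearing.  FCT is Beta-
  distributed around the FCS level with concentration 2.2, chosen so the
  FCS–FCT Pearson correlation matches the ~81% observed between the two
  real assays.  The predictor is binormal — disease ~ N(d, 1), nondisease
  ~ N(0, 1), d = √2·Φ⁻¹(AUROC) — with default AUROC 0.79, the binormal
  value implied by the printed matched-recall operating point (precision
  74%, specificity 64% at recall 78%).  MAF is log-uniform on [1e-6, 1e-2]
  so every ExAC filter bites.  A `contamination` fraction of
  disease-labeled rows can be drawn from the nondisease generative process
  (annotation errors with known ground truth).

What the generator does **not** emulate: gene-level effect correlation
(variants of one gene sharing assay behaviour), dominant-negative or
gain-of-function alleles, PKLR-style solid/liquid disagreement (handled as
an input-level exclusion flag), or the score-mass-at-1 shape of real
PolyPhen2 distributions — binormal predictor tails make simulated REC90 for
the predictor lower than a real tool's.  Passing tests therefore establish
the correctness of the *computations*, not the field performance of any
particular predictor.

## Problem sizes and numerical choices

Tests run metric-oracle equivalence on 1,000 random instances of up to 200
variants (1e-12 agreement), growth-rate recovery on 100 seeded curves,
cohort-parameter recovery on a 3×3×3 grid at 2,000 variants per class
(3 Monte-Carlo SEs), and a 200-rep contamination pilot; the acceptance
script uses 10,000 contamination resamples.  All randomness flows from
single master seeds through `numpy.random.SeedSequence` spawning, so any
run is reproducible from one integer.  Ties in PR curves are grouped before
integration; MCC returns a flagged 0 on degenerate margins; the pipeline's
per-stage seeds are derived, not shared, so adding a stage never perturbs
another stage's stream.

## Known limitations

* The rate estimator assumes a single log phase; diauxic shifts would be
  fit as whichever phase wins the R² selection.
* µ for very slow variants saturates at 0 once growth never reaches the
  detection threshold within the observation window — a detection-limit
  feature, not a bug, but it compresses the low end of the µ scale.
* Calibrated scores inherit fold-to-fold variance at small n; with ~180
  variants the 10-fold calibration is noticeably seed-dependent.
* The reversed-mode trigger (median µ > 1) is a decision rule for behaviour
  that was originally identified by inspection; genes with mixed
  fast/slow variant effects would need manual review.
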