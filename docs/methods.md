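# Methods

## The model

The unit of analysis is a patient's multiset of leukocyte CNV fragment
sizes after segmentation-quality filtering (size ≥ 2000 bp inclusive,
marker support ≥ 10, call p-value < 0.001 strict). The large-size ratio

LSR(δ) = (number of fragments with size ≥ δ) / (number of fragments)

is a one-parameter burden statistic; "large size" membership is inclusive
(≥ δ). An empty post-filter profile raises an error rather than scoring 0:
an unmeasured genome is not evidence of small CNVs. LSR is monotonically
non-increasing in δ, bounded in [0, 1], and invariant under any common
rescaling of sizes and δ.

δ is tuned on training data by maximizing the AUC of LSR against outcome
labels over a log₁₀(bp) grid, default 3.3–6.5 in steps of 0.1 (both
reported study optima, 10^4.5 = 31622 bp and 10^5.7 = 501187 bp, lie on a
0.1 grid; log-to-bp conversion floors to an integer). Ties in δ and in all
cutoff optimizations break toward the smallest qualifying value, so every
fit is deterministic.

The decision cutoff on any model score maximizes the Youden index
J = sensitivity + specificity − 1 with the rule score ≥ cutoff → positive.
Candidate cutoffs are the distinct observed scores plus the midpoints of
adjacent distinct scores; this makes the fitted cutoff for perfectly
separated classes the midpoint between them while keeping the all-ties
case well-defined (cutoff = the common value, J = 0). A 10⁻¹² tolerance is
used when locating the smallest maximizer so the answer does not depend on
float summation order.

### Modalities and fusion

Three clinical covariates join the CNV modality: Gleason grade binarized
at > 7; the externally computed nomogram 7-year progression-free
probability, flipped to 1 − p so that every feature is oriented
higher = more likely recurrent; and fusion-transcript status binarized at
≥ 1 of the 8 assayed transcripts. Combinations are scored by two-class
LDA in closed form, w = S⁻¹_pooled(μ₊ − μ₋), with a ridge
ε = 10⁻⁶·trace(S)/d added to the diagonal when the pooled covariance is
singular or has condition number above 10¹² — with binary covariates on
half-cohort splits, exact singularity is common, and the ridge preserves
the ranking while keeping weights finite. Single-modality models use the
raw oriented feature as the score.

### Cross-validation protocol

One repeat: an equal random split; δ (if the CNV modality is present),
LDA weights, and the decision cutoff are fitted on one half and evaluated
on both halves; the halves then swap roles; the two train-role and two
test-role evaluations are averaged. Splits that land all of one class in
a half are redrawn (logged, at most 100 attempts). δ is re-optimized
inside every training half rather than fixed globally — the protocol's
per-split wording supports either reading, and per-half refitting is the
one that keeps the test half untouched. The repeat is run 14 times; the
2 repeats with the highest and 2 with the lowest train+test AUC sums are
discarded and the remaining 10 averaged (trim = 0 reduces to the plain
mean). p-values are aggregated geometrically (exp of the mean log);
all other metrics arithmetically. A representative split — the retained
repeat whose concatenated train/test metric vector is closest in
Euclidean distance to the averaged vector — is recorded for plotting.

Both the raw overall accuracy and the balanced accuracy
(mean of sensitivity and specificity) are emitted: the protocol's single
"accuracy" column is not pinned to either definition, so neither is
guessed.

### Outcome contrasts

- recurrence: recurrent vs non-recurrent with ≥ 90 months of follow-up;
- fast recurrence: PSADT ≤ 4 months vs (eligible non-recurrent or
  PSADT ≥ 15 months); recurrences with 4 < PSADT < 15 are excluded;
- lethal: recurrence within 12 months with PSADT ≤ 4, vs eligible
  non-recurrent.

These nest: lethal ⊆ fast-recurrent ⊆ recurrent (a tested invariant).
Samples failing an eligibility rule are flagged and excluded from the
affected contrast, never silently dropped from the dataset.

### Survival layer

Risk groups come from the merged two-fold cross-fit: each patient is
predicted by the model trained on the half not containing them, so every
patient gets exactly one call. The exception is the single-modality
Gleason model, which is a fixed global > 7 threshold without
cross-fitting. Kaplan–Meier curves (lifelines) are truncated at 90
months — later events become censorings at 90 — and compared with the
standard two-group log-rank test. Model A vs model B is compared by
U = |χ²_A − χ²_B| referred to a Monte-Carlo null of the absolute
difference of two independent χ²₁ draws (default 10⁷ draws; the tests use
10⁵ for speed). The Monte-Carlo p uses the plus-one estimator
(k+1)/(n+1), which cannot return 0. The null's independence assumption
between the two models' statistics is inherited from the protocol being
reproduced — the two statistics are computed on the same patients and are
not independent in general — and is documented rather than endorsed. An
exact cross-check of the null survival function,
P(|X−Y| ≥ u) = (2/π)∫_{u/2}^∞ K₀(w) dw, backs the Monte-Carlo in tests.

### Gene-level track

Gene involvement is interval overlap (≥ 1 bp, half-open coordinates)
between a sample's filtered segments and a BED gene annotation, pooling
gains and losses by default (a flag restricts by state). Per-gene
association with outcome uses the two-sided Fisher exact test (sum of
table probabilities ≤ observed; sidedness is a convention choice, the
protocol does not state one) with BH correction across genes; constant
genes get p = 1. Gene sets (GMT) are scored by a two-sample KS test of
in-set vs out-of-set adjusted p-values, BH-corrected across sets. No gene
annotation ships with the package; any BED is accepted, and totals will
differ between annotations.

## Synthetic cohort generator

The generator reproduces the statistical structure the pipeline consumes,
not the assay:

- class design defaults to 35 non-recurrent (follow-up ≥ 90 months),
  55 fast-recurrent (PSADT uniform on [1, 4] months), 53 slow-recurrent
  (PSADT uniform on [15, 60]);
- fragment counts per genome are negative binomial with mean 152
  (= round(41589 fragments / 273 genomes)) and dispersion 20 — the
  reported data give only the mean, so the dispersion is an assumption
  allowing mild overdispersion;
- fragment sizes are log-normal, log₁₀ mean 4.5 and sd 0.5 in
  non-recurrent genomes (≈ 61 kb arm mean; no size variance is reported,
  so the sd is an assumption); recurrent genomes draw each fragment from
  a two-component mixture whose upper-tail component (weight 0.25) is
  placed analytically so the recurrent/non-recurrent arm mean ratio
  equals the configured fold (default 3.2): the component mean ratio is
  r = (fold − 1)/weight + 1. The tail component's location can also be
  set explicitly for planted-threshold experiments;
- between-patient heterogeneity: a per-sample log₁₀ location shift
  (sd 0.12, same law in every class, so arm mean ratios are unchanged in
  expectation) and a per-sample Beta-distributed tail weight (sd 0.10);
- covariates are class-dependent: P(Gleason > 7), a Beta-distributed
  nomogram probability, and fusion positivity, each with defaults giving
  moderate association in the direction reported (non-recurrent patients
  have higher nomogram probabilities, fewer fusions, lower grades);
  `CovariateEffects.null()` removes all covariate signal;
- event times are exponential (scale 13 months for fast, 65 for slow
  recurrences); non-recurrent follow-up is uniform on [90, 150] months;
- a configurable fraction (8%) of sub-threshold junk segments exercises
  the filter;
- all randomness flows from one seed through per-sample sub-streams:
  the same spec yields byte-identical output files.

What the generator does **not** emulate — and hence what green tests do
not establish about patient data: fragments are drawn i.i.d. within a
patient, so a genome with ~150 fragments measures its own large-size
probability with binomial precision and the classes separate far more
cleanly (cross-validated AUC ≈ 0.98 at the default settings) than in real
cohorts, where the reported test accuracy is in the 60–75% range;
chromosomal placement is uniform, with no hotspots, recurrent loci or
correlated co-occurrence, so the gene-level track is null by construction
on default cohorts; and PSADT, nomogram and Gleason are drawn from
parametric families rather than clinical joint distributions. Passing
tests demonstrate that the statistics and the protocol are implemented
correctly, not that the biological effect size is as stated.

## Problem sizes

The test suite and analysis scripts run cohorts of 42–750 patients
(protocol-level tests use 54–143; convergence checks use up to 510
samples or ≥ 10⁴ fragments per arm), 14-repeat cross-validations, 10⁵-draw
U-test nulls with 5000 calibration replicates, and exhaustive enumeration
oracles up to C(16, 8) label assignments. The planted-threshold recovery
experiment uses 300 patients with 60 fragments each, a weak localized
tail (weight 0.05 at 10^5.4 bp), and a 0.3-step grid, sized so the AUC
curve has a single non-saturated interior peak — with the default strong
signal the curve plateaus at AUC 1.0 and "the" optimum is ill-defined.

## Known limitations

- The U test inherits the independence-of-models null (above).
- The LSR cutoff search is over observed values and midpoints; with very
  few distinct scores (binary covariates alone) the cutoff is coarse.
- `roc_pvalue`'s exact permutation mode enumerates label assignments and
  is only practical below ~12 samples per class; the default
  normal-approximation Mann–Whitney p is accurate to ~0.02 there.
- Chromosome names are compared verbatim ("chr1" ≠ "1"); harmonizing
  annotation naming is the caller's responsibility.
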