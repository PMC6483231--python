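# Methods

## Problem setting

`adhdtree` implements an interpretable diagnostic-classification pipeline for
child/adolescent ADHD from resting-state fMRI and phenotypic data. Each
subject is described by up to 120 features: four phenotypic attributes
(gender, age, IQ, Edinburgh handedness score) and, for each of the 116
regions of the AAL parcellation (odd ids left hemisphere, even ids right),
the variance of the region-averaged BOLD timecourse. The variance is a
measure of the energy of spontaneous activity in a region, so every feature
remains individually meaningful — the prerequisite for models whose
predictions clinicians can audit as a chain of literal questions.

The pipeline runs in two stages. A *blind* stage selects features
automatically and trains a decision tree. Its artifacts (rendered tree,
selection frequencies, decision chains) are meant for review by a domain
expert; the review itself is a human judgment and is deliberately not
automated. A *knowledge-guided* stage then retrains with the feature space
restricted to an expert-chosen region set — packaged here as 26 limbic-system
ROIs grouped into affective (ids 3–10, 13–16) and executive (31–42, 77–78)
subsystems — plus gender.

## Feature extraction

`roi_variance` is the unbiased sample variance (denominator T−1). The choice
of denominator is fixed and documented because split thresholds in the trees
depend on it. Variance is translation-invariant and scales quadratically;
both properties are tested. Gender is kept categorical inside the feature
table so the tree can split it multiway; it is numerically encoded (F=0,
M=1) only where a Pearson correlation needs a number. Class labels are
encoded TD=0, ADHD=1 for the same purpose; absolute correlations are used
throughout, so the encoding direction is immaterial.

## Feature selection (CFS with a bootstrap ensemble)

A candidate subset S of k features has merit

    M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

with r̄_cf the mean |Pearson| feature–class correlation and r̄_ff the mean
|Pearson| pairwise feature–feature correlation. Zero-variance features are
assigned correlation 0. The subset search is best-first forward: a priority
queue over subsets ordered by merit, each expansion adding every unused
feature to the best open subset, terminating after 5 consecutive expansions
that fail to improve the best merit found (the termination count is
configurable). For a singleton the merit collapses to |r_cf|, and adding an
exact duplicate of a selected feature leaves merit unchanged — both
identities are tested.

Robustness comes from an ensemble wrapper: the search is repeated on 20
seeded bootstrap resamples, each a with-replacement draw of 75% of the
training subjects (a flag switches to without-replacement subsampling; the
with-replacement default follows the bootstrap reading of the procedure).
A resample that happens to contain a single class is redrawn, up to 100
attempts. Features are retained when selected in at least 25% of resamples
— the threshold comparison is inclusive, so 5 of 20 is kept and 4 of 20 is
not.

Known limitation: best-first search with a finite termination count is not
an exhaustive search. On tables where *every* feature is moderately
informative, the queue can exhaust its non-improving budget before reaching
the global merit maximum; in the sparse-signal regime this package targets
(a few discriminative regions among many irrelevant ones) the search
matches brute-force enumeration on every tested table. A second consequence
of the merit definition is that strongly redundant discriminative features
are deliberately *not* all selected: once one of them is in the subset, the
others lower merit. Selection frequency therefore measures non-redundant
relevance, not relevance per se (see the synthetic-recovery discussion
below).

## Tree induction

Trees are grown greedily. Node impurity is the two-class entropy
i(t) = −Σ_c (N_c/N)·log2(N_c/N) (0·log0 ≡ 0), and a split is scored by the
information gain i(t) − Σ_k (N_k/N)·i(t_k). Numeric splits are strictly
binary at midpoints between consecutive distinct sorted values, with values
equal to the threshold taking the ≤ branch; the categorical gender split is
multiway with one branch per category. The single complexity parameter is
the minimum leaf size m: a split is admissible only if every child holds at
least m training instances, and growth stops at pure nodes, when no
admissible split exists, or when the best gain is zero. No post-pruning is
applied; m is the only complexity control.

Determinism is guaranteed by explicit tie-breaks: gains tied to within
1e−12 (the float tolerance between equivalent formula evaluations) resolve
by feature order in the table — phenotypics first, then ascending ROI id —
and then by the smaller threshold; leaf-label ties resolve toward the
parent's majority class, then toward ADHD (a slight bias toward sensitivity,
appropriate when the cost of a missed diagnosis exceeds that of a false
alarm).

## Model selection and evaluation

m is tuned over the integer range [5, 20] — the upper end being roughly 10%
of a ~200-subject training set — by leave-one-out cross-validation, which
trains on datasets of size n−1, the closest possible to the final training
run; because m is an absolute rather than relative quantity, validation-set
size matters. Among equally accurate values the smallest m is chosen. A
stratified 4-fold CV mean ± sd (population sd, divide by k; folds stratified
by diagnosis to stabilize their composition) is reported as a stability
summary of the final model.

Test-set evaluation reports the confusion matrix and accuracy, specificity
(true-negative rate over TD subjects) and sensitivity (true-positive rate
over ADHD subjects) as percentages, displayed to one decimal with unrounded
values retained. A rate with a zero denominator is reported as undefined,
not zero. The test cohort is touched only at this point, never during
selection or tuning.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without access to clinical data:

* **Demographics.** Exact group sizes and per-group gender counts; ages and
  IQs are normal draws (clipped positive) rounded to one decimal. The
  defaults reproduce the NYU-site cohort: training 93 TD (50 F) / 117 ADHD
  (25 F) with age 12.1±3.1 / 11.3±2.7 and IQ 110.8±13.8 / 107.0±13.3; test
  12 TD (4 F) / 29 ADHD (9 F). Handedness is drawn from N(0.7, 0.25) clipped
  to [−1, 1] — a mostly right-handed cohort on the Edinburgh scale; nothing
  downstream thresholds it.
* **Timecourses.** 176 timepoints at TR = 2 s by default (the TR is the
  acquisition value; the length is a free choice consistent with a ~6-minute
  scan after initial-volume removal). Each series is white Gaussian noise
  shaped in the frequency domain: coefficients outside the open band
  (0.009, 0.08) Hz are zeroed and the series rescaled so the unbiased sample
  variance has expectation exactly the target σ²_r. Frequency-domain shaping
  gives exact variance control with no filter transients; the DC bin is
  excluded by the band, so every series has exactly zero mean.
* **Planted effects.** A diagnosis effect is a multiplicative variance ratio
  (ADHD/TD) in one ROI, optionally restricted to one gender. The default
  configuration plants ratio 0.25 (reduced resting activity in ADHD) in ROIs
  15 and 40 globally and ROI 88 in girls only, mimicking a gender-conditional
  discriminative structure; effect sizes are free parameters since the
  source analysis reports threshold locations, not group variance ratios.
  `effect_recovery_reference` exposes the generative log-variance gaps as
  ground truth for recovery tests.

What the generator does *not* emulate: temporal autocorrelation beyond band
limitation, spatial correlation between regions, head motion and
physiological artifacts, site or scanner heterogeneity, and any phenotypic
association with diagnosis other than the gender imbalance. Passing recovery
tests therefore demonstrates that the pipeline's machinery works as
specified on data satisfying its assumptions — not that comparable accuracy
is attainable on clinical data, where reported accuracies are several tens
of points lower.

On the synthetic recovery conditions used in the acceptance run (three
ratio-4 effects, one gender-scoped), the per-subject sample variance of a
planted ROI separates the groups almost perfectly (sample-variance CV at
T=176 is ≈10.7% while the group ratio is 4). Consequently the two global
effects are selected in every resample and a depth-1 tree classifies the
held-out cohort perfectly, while the gender-scoped effect — statistically
redundant given either global effect — is excluded by the CFS merit, with
selection frequency 0. This is the redundancy-elimination behavior described
above, and it is why selection frequency should not be read as a completeness
guarantee over all truly affected regions.

## Numerical and degenerate-input conventions

* Entropy of an empty node is an error; an empty child contributes 0 to a
  gain sum (weight 0).
* Correlations involving a zero-variance column are 0; CFS merit of an
  empty subset is an error.
* Timecourse files must be rectangular, numeric, ≥2 rows, exactly 116
  columns; phenotypic rows with missing or unparseable cells are rejected
  with their row and column named, never imputed.
* Seeds: one global pipeline seed deterministically derives per-stage seeds
  via SHA-256 (all below 2³¹); identical configuration and seed reproduce
  every artifact byte-for-byte, including written cohort files (timecourses
  serialized at %.17g so doubles round-trip exactly).

## Known limitations

* Best-first CFS is exhaustive-equivalent only in sparse-signal regimes
  (see above).
* Leaf-count monotonicity in m holds on all tested tables but is a
  structural expectation, not a theorem, for greedy growth.
* The feature-selection stage precedes m-tuning and is not re-run inside
  each LOOCV iteration (matching the staged design); accuracy estimates
  therefore carry the usual selection-before-validation optimism on small
  cohorts.
* The phenotype-variant stage re-tunes m by default (a flag reuses the
  blind stage's m instead); the original staging leaves this open.
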