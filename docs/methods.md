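# Methods

This note records the models, conventions and design choices behind
`immunocentroid`, in the order the pipeline runs them.

## Normalization

The canonical expression layer is produced from raw counts in three fixed
steps: (1) `v = log2(1 + x)`; (2) per-sample upper-quartile scaling —
each sample's values are divided by that sample's 75th percentile of `v`
over genes with `v > 0` and multiplied by the mean of those percentiles
across samples, so the output scale is cohort-comparable; (3) per-gene
median centering across samples.

Two conventions are fixed deliberately. First, **scaling precedes
centering**: median-centered values are signed, so a per-sample quartile
computed after centering would be near zero and unstable, and rescaling
after centering would destroy the zero-median guarantee that heatmap-style
views of centered expression rely on. Second, the **upper quartile is
computed on log values over positive entries only**, with the
linear-interpolation percentile definition; restricting to positive
entries is the standard upper-quartile convention and prevents
zero-inflated samples from collapsing the quartile. After step 3 every
gene's across-sample median is 0 (enforced to 1e−9 in tests), and after
step 2 every sample's positive-value upper quartile is identical.

A sample with all-zero counts has no defined upper quartile and is
rejected by name rather than silently patched.

## Signature scoring and group statistics

A signature score is the unweighted arithmetic mean of the normalized
values of the set's genes present in the matrix. Genes absent from the
matrix are dropped from their set and the drop fraction is logged; a set
with no present genes is dropped with a warning. The packaged default
collection contains 28 singleton immune-marker sets (checkpoint genes,
IL2 receptor chains, interferon-stimulated genes, T-cell markers) plus a
12-gene type I interferon module; multi-gene immune cell-type signatures
are user-supplied GMT input because their memberships are
publication-specific.

Group comparisons report the two-sided Wilcoxon rank-sum p (exact
enumeration when both groups have ≤ 10 samples and no ties, normal
approximation with tie correction otherwise), a pooled-variance t
statistic with the convention that positive means higher in responders,
the mean difference, and a display flag at p < 0.05. The exact and
asymptotic paths agree within 0.02 at group sizes of 10 (calibration
test).

The Teff/Myeloid quadrant call compares each sample's score to the cohort
median of that signature; ties go HIGH, deterministically.

Overrepresentation analysis is the one-sided hypergeometric upper tail
(overlap k, set size K within the universe, query n, universe N) with
Benjamini–Hochberg adjustment across sets. Hypergeometric ORA and BH were
chosen as the standard defaults for a gene-list-versus-gene-set volcano
analysis.

## Nearest-centroid response classifier

The classifier follows the classification-to-nearest-centroids family:

1. **Candidate filter (label-free, run once on the full matrix).** Keep
   genes with across-sample median ≥ the 0.25 quantile of gene medians
   and variance ≥ the 0.70 quantile of gene variances. Because it uses no
   response information, running it outside the cross-validation loop
   does not leak labels.
2. **Per-fold selection.** Inside each leave-one-out fold, two-class
   pooled-variance t statistics (denominator s_p·√(1/n₁+1/n₂) + s₀) are
   recomputed on the fold's training samples; the top m/2 positive-t and
   m/2 negative-t candidates are kept. Ties break by larger |t| then
   lexicographic gene ID. Balanced two-tail selection is the default
   because response classifiers of this kind carry both up- and
   down-regulated genes; an unbalanced top-|t| mode is available.
3. **Centroid fit and prediction.** Per-class per-gene means with pooled
   within-class SDs; a sample goes to the class minimizing
   Σ((x−c)/(s+s₀))² (or plain squared Euclidean on request). Prediction
   ties go to the first listed class.
4. **Gene-count choice.** LOOCV accuracy is computed for every even m in
   the grid (default 4–100 step 2, truncated to the candidate count); the
   smallest m attaining the maximum wins, and the final model refits
   selection and centroids on all samples at that m. The full CV trace is
   stored on the model.

LOOCV rather than a train/test split reflects the ~35-sample regime these
cohorts live in. s₀ defaults to 0; when any pooled SD is exactly 0 it
falls back to the median positive pooled SD (1.0 if none) so distances
stay finite.

The LOOCV loop uses an exact algebraic shortcut: within a fold the
centroids and pooled SDs do not depend on m, and balanced selections at
increasing m are prefixes of the up-/down-rankings, so all grid values are
evaluated with prefix sums of per-gene standardized squared deviations.
The shortcut is verified against the naive per-(fold, m) refit in the test
suite and is bypassed whenever its preconditions (standardized distance,
s₀ = 0, balanced even-m selection, no zero pooled SD) fail.

The reference workflow this mirrors reported filtering ~18k genes to
~3.5k candidates on its own (unreleased) cohort data; those counts
depend on the cohort and the exact "approximate" percentile cutoffs and
are context, not a reproducible contract.

### Subtype classifier

The fixed-panel subtype classifier (e.g. the 34-gene ccA/ccB renal
panel) restricts to the given gene list, median-centers each gene on a
stratified 2/3 training split (storing the offsets on the model so test
and future samples are centered identically), fits centroids, and reports
held-out accuracy. The split is resampled a bounded number of times if a
subtype is missing from the training side. The source description of this
classifier is ambiguous between "all available genes" and the 34-gene
panel; the implementation restricts to the panel.

## Outcome statistics

- **Response rates**: ORR = (CR+PR)/evaluable, disease control adds SD,
  clinical benefit counts the supplied flag (CR, PR, or SD ≥ 6 months).
  Stable-disease duration is not reconstructible from category labels, so
  the benefit flag is an input (the simulator plants it). Percentages are
  displayed rounded to the nearest whole percent, half away from zero.
- **Kaplan–Meier / log-rank / Cox** go through lifelines; Cox uses Efron
  tie handling, CIs are exp(β ± 1.96·SE). Constant covariates and
  zero-event inputs are rejected; convergence failures surface as
  structured errors.
- **Fisher exact** uses the two-sided probability-mass rule and reports
  the sample odds ratio ad/bc (∞ when bc = 0) — documented because the
  doubling rule and conditional-MLE odds ratio are common alternatives.
- **Kruskal–Wallis** is tie-corrected; a fully tied sample returns H = 0,
  p = 1 by convention (no rank information).
- **Logistic regression** (statsmodels MLE) flags likely separation by
  non-finite or exploding estimates/SEs instead of failing.

## Synthetic cohort generator

The generator emulates the statistical structure of a small immunotherapy
cohort, not any patient data:

- **Counts**: negative binomial with var = μ + αμ². Per-gene baseline
  means are log-normal (default ln-scale mean 4.0, SD 1.2 — median ≈ 55
  counts). Dispersion α defaults to 0.16, the conventional biological
  coefficient of variation of 0.4 for human clinical cohorts.
- **Programs**: disjoint gene lists drawn from genes at or above the
  median baseline expression (configurable quantile). Immune programs in
  bulk tumor are expressed genes; planting them in the near-zero tail
  would make them undetectable by construction. Responder samples have
  program means multiplied by 2^effect.
- **Clinical structure**: a 35-sample cohort with responder fraction
  0.37; responders split CR:PR = 1:12 and non-responders SD:PD = 6:16 by
  sample order (deterministic given labels); 2/6 of SD patients carry the
  clinical-benefit flag. These defaults mirror the published cohort
  shape.
- **Immune-high flag**: top half of samples by mean log2(1+count) over
  the first program's genes — the binary immune-classification call used
  for survival stratification.
- **Survival**: proportional-hazards Weibull (shape 1 = exponential
  default) with baseline median 60 months for OS and the immune-high
  hazard multiplied by exp(log HR) (default ln 2); PFS uses the same
  model with the baseline median scaled by 1/6, matching the
  order-of-magnitude gap between published PFS and OS medians. Censoring
  is an **independent** exponential time whose rate makes the expected
  censored fraction at baseline equal `censoring_rate`; thinning the
  event time itself was rejected as informative censoring that would bias
  Cox recovery.
- **Contrasting cohorts**: an 8-gene effector program at +1.0 log2 in
  responders of both cohorts, and a 6-gene myeloid program at +1.0 in the
  IL2-like cohort and −1.0 in the anti-PD-1-like cohort — the
  Teff/Myeloid structure used to contrast IL2 and checkpoint response.
- One `numpy` Generator seeded from the config drives everything;
  identical configs reproduce byte-identical outputs.

**What the simulator does not model**: batch effects, tumor purity,
gene–gene correlation beyond the planted programs, library-size
variation, and covariate-dependent censoring. Passing recovery tests
therefore demonstrate correctness of the estimators under the generative
assumptions, not performance on real tumors.

## Problem sizes in the test and acceptance runs

Recovery and calibration checks run at sizes where the answers are
statistically decidable yet quick: the classifier recovery cohort is
n = 35 × 2,000 genes with 20 up- and 20 down-regulated planted genes at
±1.0 log2 (LOOCV accuracy ≥ 0.9, ≥ 80% of planted genes recovered at
m = 40; the permutation-null baseline uses 20 label permutations); Cox
recovery uses n = 500 with a planted hazard ratio of 2 and 20% censoring;
log-rank type-I error uses 2,000 null replicates of n = 100; the
myeloid sign-flip detection rate uses 100 replicate cohort pairs. The
oracle-equivalence suites check 1,000 random nearest-centroid instances
against brute-force distance enumeration, Fisher p against full
fixed-margin enumeration, the exact Wilcoxon path against full
rank-assignment enumeration (group sizes ≤ 7), and hypergeometric ORA
against direct pmf summation.

## Known limitations

- The published 40 classifier genes cannot be re-derived (the underlying
  patient matrix is unreleased); the package reproduces the *procedure*
  and validates it on planted truth.
- The exact Wilcoxon path requires untied data; heavily tied small
  samples silently use the tie-corrected normal approximation.
- The permutation-null LOOCV baseline is reported at the grid-maximizing
  gene count, so it carries the optimism of that maximization (observed
  ≈ 0.03–0.08 above the 1/2 no-prior baseline); this mirrors how the
  procedure's accuracy is reported in practice.
- `adjusted_logistic` detects separation heuristically; penalized
  (Firth-type) estimation is out of scope.
- The subtype classifier assumes the fixed gene panel is fully present in
  the matrix and rejects otherwise rather than imputing.
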