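# Methods

`annak` implements a dyad-level idiosyncrasy analysis: do individuals
high on a trait differ *more from one another* than individuals low on
it? Under the Anna Karenina (AnnaK) model of individual differences, all
low scorers are alike while each high scorer is distinctive (or vice
versa), so the interesting quantity is not a group mean but the
inter-subject dissimilarity of every unordered pair (dyad), compared
across HH, HL, and LL dyad groups formed from a trait median split. The
package applies this to mentalizing: neural features of the mentalizing
network (MTN) recorded during movie watching, eye-gaze trajectories, and
embeddings of verbal interpretations of the characters' mental states,
with perspective-taking (PT, the IRI subscale, range 0-28) as the trait.

## Dissimilarity indices

Let subject *i* have an ROI time-series matrix (151 TRs x 6 MTN regions
in the reference setup). Per subject we compute:

- **Functional connectivity (FC).** Pearson correlation between each
  region pair, Fisher z-transformed (`z = arctanh r`). The matrix is
  symmetric; the diagonal is stored as 0 (self-correlation excluded) so
  all downstream sums use off-diagonals only. Correlations with
  `|r| >= 1 - 1e-7` are clamped into the open interval with a warning —
  this keeps z finite for numerically perfect correlations in short
  synthetic series and is recorded per edge.
- **Strength centrality.** Per region, the sum of its z-edges to all
  other regions (weighted degree).

Dyad-level indices:

| index | definition | range |
|---|---|---|
| time dynamics (per region) | 1 − Pearson r of the two subjects' regional series | [0, 2] |
| FC profile (global) | Euclidean distance between the vectorized 15 upper-triangle edges | ≥ 0 |
| FC per edge | \|z_i − z_j\| per edge | ≥ 0 |
| strength (global / per region) | Euclidean distance / \|s_i − s_j\| | ≥ 0 |
| gaze | 1 − (r_x + r_y)/2 on the valid-frame intersection | [0, 2] |
| semantic | 1 − cosine(v_i, v_j) of document embeddings | [0, 2] |

Edge vectorization is row-major over the strict upper triangle in
manifest ROI order. The ordering cannot affect Euclidean distances but
is fixed and documented so per-edge reports are stable. The squared
global distance decomposes exactly into the sum of squared per-edge
(per-region) distances; this Pythagorean identity is enforced by tests
at 1e-10.

**Gaze preprocessing.** Traces are frame-by-frame (7203 frames at 24 fps
on a 1280x790 frame in the reference setup); missing samples are NaN.
Dropout gaps strictly shorter than 75 ms are linearly interpolated from
the flanking samples; at 24 fps (41.7 ms/frame) that means single-frame
gaps, while runs of 2+ frames (>= 83 ms) are eye blinks and stay
missing. Both thresholds are configurable (`gap_ms`,
`max_interp_frames`). Samples outside the video frame are marked invalid
but keep their coordinates, which makes preprocessing idempotent. Dyad
correlations use the intersection of the two traces' valid frames,
computed after interpolation and invalidation; dyads whose intersection
covers less than 10% of frames (configurable) are rejected and flagged
rather than silently scored — the handling of such dyads has no
established convention, so they surface as explicit failures.

**Embeddings are inputs.** Real analyses consume document vectors from a
sentence-embedding model (768-dimensional in the reference setup). The
shipped `TermFrequencyEmbedder` is a deterministic synthetic stand-in
for tests only and is not semantically equivalent to such a model.

**Outlier exclusion.** Per index, each subject's mean dissimilarity to
all others is z-scored across subjects; subjects with |z| > 3 are
removed in a single pass (no re-iteration), before the dyad table is
built. Exclusions are per index: a subject excluded for strength still
contributes to the FC-profile analysis.

## Dyadic inference

Dyad observations are not independent — each subject sits in n−1 dyads.
The model follows the double-entry convention for indistinguishable
dyads: every unordered dyad contributes two rows with the member roles
swapped, and crossed random intercepts on the two member columns absorb
each participant's global tendency toward (dis)similarity in either
role. Fixed effects are the HH/HL/LL dyad-group factor plus, for each
screened confound, that covariate's own median-split dyad-group factor;
the continuous variant replaces the factor with the standardized dyad
mean trait and the covariates' dyad means. The dependent variable and
all continuous predictors are z-scored over unique dyads before
doubling, so coefficients are standardized. Estimation is REML (ML
available) via `statsmodels` MixedLM with a variance-component
formulation of the crossed intercepts; optimizer fallbacks (lbfgs →
bfgs → powell) and boundary variance components are recorded in the
result diagnostics, and a model that cannot be fitted raises with a
settings dump.

Two corrections give valid Wald inference:

1. **df = N − k**, with N the number of unique dyads (not doubled rows)
   and k the fixed-effect count. By default k counts only the focal
   predictor (k = 1), treating covariates as nuisance terms; `k="all"`
   counts every non-intercept design column.
2. **Double-entry covariance scaling.** Duplicating every row doubles
   the apparent Fisher information, so the naive fixed-effects
   covariance is ~2x too small. We scale it by 2 (SE x sqrt(2)). This is
   not cosmetic: in null simulations (below) the uncorrected contrast
   rejects at ~0.17 for a nominal 0.05, while the corrected test is
   calibrated (~0.05-0.07). `se_correction=False` reproduces the
   uncorrected covariance for comparison.

**Contrasts.** Pairwise HH−HL, HH−LL, HL−LL differences are computed on
marginal means averaged over covariate factor levels with equal weights
(observed-frequency weighting available), tested with Wald t at
df = N − k, and Benjamini–Hochberg adjusted across the contrast family.
When several dependent variables are analysed together the pipeline
additionally pools all contrasts into one BH family and reports both
adjustments, since family composition is an analysis-level choice; the
pooled family used is logged in the report.

**Covariate screening.** A candidate covariate is a confound if it
correlates with the trait (Pearson) or differs between the high/low
trait groups (two-sample t for continuous, chi-square for categorical)
at α = 0.05. Because the two arms are applied as a union on the same
data, the realized flag rate for an independent covariate is slightly
above α (between α and 2α); this conservative-inclusive behavior is
intentional for a screening step.

**Mantel tests.** Associations between two dissimilarity matrices use
the Pearson correlation of their condensed upper triangles, with a null
built by jointly permuting rows and columns of one matrix (subject-label
permutation, which preserves the within-matrix dependence). p includes
the identity permutation in the numerator and denominator
(p = (1 + #{r* ≥ r}) / (1 + n_perm)), so it is never 0; for n ≤ 6
subjects the full permutation group is enumerated and p is exact. The
default alternative is one-sided "greater" because the substantive
hypotheses are directional; two-sided and "less" are available. Before a
Mantel test the pipeline residualizes each index's dyad values on the
confound dyad means (OLS with intercept; residuals orthogonal to every
confound column). Reported df follows the r(n−2) convention on the
subject count.

**Network-specificity interaction.** To ask whether the dyad-group
pattern is specific to one network, the two networks' dissimilarities
(each standardized within network over unique dyads) are stacked long
with a network factor and modelled with group, network, and
group x network fixed effects plus the crossed member intercepts on
doubled rows. The interaction is Wald-F tested with the double-entry
covariance scaling and denominator df = N_long − k, where N_long counts
unique (dyad, network) observations and k counts all non-intercept
terms. This is a deliberately simple approximate-df choice: a
Satterthwaite or Kenward–Roger denominator is out of scope, and with
thousands of unique observations the F reference is insensitive to the
exact denominator. Random slopes for network are not included.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
so every stage runs — and can be calibrated — with no external data.

- **Traits** are integers drawn uniformly on [10, 28] (the PT subscale
  range observed in practice; the true distribution is not otherwise
  characterized, so uniform is the configurable default) through a
  Gaussian copula: the trait's latent normal score z₀ also drives the
  covariates, which are built as ρ·z₀ + √(1−ρ²)·ε to hit target trait
  correlations (defaults: fantasy and empathy at ρ = 0.4 — the
  covariates flagged in practice — plus uncorrelated age and a binary
  gender to exercise both screening arms).
- **Connectivity.** All subjects share a positive-definite block
  template correlation matrix. Subject i's FC is
  `tanh(template_z + σ·E)` with E symmetric zero-diagonal N(0,1) noise
  and σ = σ₀ + σ₁·trait_norm, i.e. idiosyncrasy is injected additively
  in Fisher-z space with SD linear in the normalized trait — the
  simplest monotone AnnaK structure. Defaults σ₀ = 0.10, σ₁ = 0.40 make
  the top-of-range deviation five times the baseline, a deliberately
  strong AnnaK regime. If the perturbed matrix loses positive
  semi-definiteness it is repaired by eigenvalue clipping and diagonal
  renormalization (`statsmodels.correlation_tools.corr_clipped`),
  deterministically. Movie time series are Gaussian draws with the
  subject's FC (151 TRs); rest series use σ₁ = 0 (intrinsic activity
  carries no AnnaK structure) with 180 TRs.
- **Gaze.** A deterministic Lissajous scan path around screen center is
  shared; each subject adds a smoothed Gaussian deviation (SD in pixels
  linear in trait, 40 + 120·trait_norm by default, smoothed over ~0.5 s)
  plus blink gaps (≥2 frames), single-frame dropouts, and off-screen
  samples at configurable per-frame rates, so preprocessing has
  realistic artifacts to remove.
- **Embeddings.** von Mises–Fisher draws around a shared unit direction
  with concentration κ = κ₀ − κ₁·trait_norm (defaults 2500 − 1500·t for
  768 dimensions): higher-trait subjects scatter more widely, raising
  pairwise cosine dissimilarity.
- **Null mode** forces every trait slope (σ₁, gaze slope, κ₁) to zero;
  inter-subject spread then exists but is trait-independent — the null
  hypothesis of the dyadic tests.
- **Reproducibility.** The global seed expands into per-subject child
  seeds (`SeedSequence(seed, spawn_key=(i,))`), so cohorts are
  bit-reproducible and subject i's data are unchanged when the cohort
  grows.

What the generator does *not* emulate: haemodynamics, autocorrelated
BOLD noise, head motion, fixation/saccade dynamics, semantic topic
structure, or measurement error in the trait. Passing tests therefore
show that the *statistical machinery* is correct and calibrated for
additive member-plus-dyad dependence, not that real fMRI or eye-tracking
data meet those assumptions.

## Calibration and power (simulation studies)

`annak.study.replicate_study` runs the full chain (cohort → FC →
dissimilarity → median split → dyad table → mixed models) on many
independent seeded cohorts. Problem sizes were chosen to give stable
Monte-Carlo estimates at desk scale: 300-1000 null cohorts of n = 20 for
type-I error, 100 AnnaK cohorts of n = 30 for power. With the defaults:

- the HH−LL contrast on null cohorts rejects at ~0.05-0.08 for nominal
  0.05 (pooled estimate ≈ 0.065 over several thousand replicates): close
  to nominal with a mild residual anticonservatism, because additive
  member effects only approximate the higher-order dependence of
  distance matrices;
- AnnaK cohorts yield a positive, FDR-significant HH−LL contrast and a
  positive continuous-trait slope in ≈100% of replicates, and recover
  the HH > HL > LL ordering of group means essentially always.

These rates are recomputed, not quoted, by `tests/test_acceptance.py`
and `scripts/acceptance.py`.

## Numerical and design choices

- Median split: high iff score > median; ties at the median go low
  (matching the questionnaire-cutoff convention "score ≤ cutoff = low").
- Dyad groups are unordered: (high, low) and (low, high) both code HL.
- Segment windows are 1-based and inclusive on both ends; the default
  movie windows (1-50, 51-110, 111-151) partition 151 TRs exactly.
- The within/outside-network seed contrast is generic over user-supplied
  region sets; no atlas ships with the package. A zero-variance contrast
  is reported as degenerate instead of producing a spurious t.
- `DissimMatrix` validation enforces symmetry, zero diagonal, and
  non-negativity; correlation-based indices are bounded by 2.
- Exhaustive Mantel enumeration switches on at n ≤ 6 (720 permutations);
  above that, seeded Monte-Carlo.
- Degenerate inputs fail loudly and early with the offending subject,
  ROI, or dyad named: constant regional series, zero embedding vectors,
  all-invalid gaze traces, all-equal trait scores.

## Known limitations

- The double-entry covariance scaling makes the dyad-group test
  approximately, not exactly, calibrated; with few subjects (< ~15) the
  df = N − k convention overstates the effective degrees of freedom and
  p-values for strong member-effect structures become optimistic.
- Outlier exclusion is single-pass by design; iterated exclusion would
  change retained sets.
- The interaction test's denominator df is a pragmatic approximation
  (see above).
- The gaze index is a global trajectory correlation; it does not model
  fixation events, saccade timing, or time warping.
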