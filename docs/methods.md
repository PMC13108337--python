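# Methods

## Model and procedure

The unit of analysis is one subject's T × R matrix of ROI-averaged BOLD
signal (rows: timepoints, columns: labeled ROIs; the label order fixes the
ROI indexing everywhere downstream). Two detectors run on the same edge
universe of m = R(R−1)/2 unordered ROI pairs:

**Static connectivity.** The whole-series correlation matrix (Pearson, or
Spearman computed as Pearson on average-rank-transformed columns) with
two-tailed p-values from t = r·√((n−2)/(1−r²)) on n−2 df, n = T. The test
assumes temporally independent samples; the synthetic generator's default
(white noise in time) matches that assumption, and an AR(1) option exists
precisely to probe what happens when it is violated. Fisher z = atanh(r) is
carried alongside for reporting and aggregation; no inferential step
consumes it. Bonferroni keeps an edge iff p·m < α, strictly.

**Jackknife connectivity.** T leave-one-timepoint-out iterations; each
recomputes the full correlation matrix on the remaining T−1 rows (n = T−1
in the p-value) and applies the *same* Bonferroni criterion at the same α.
The per-iteration criterion is deliberately the conservative choice: the
per-iteration test is a full multiple-comparison-corrected significance
call, not a relaxed screen. An edge's retention is the fraction of
significant iterations; `retain_edges` keeps it iff its significant-
iteration count is ≥ ⌈θ·T⌉. The ceiling-on-counts formulation avoids
float-equality traps (0.85 × 294 = 249.9…, cutoff 250). The implementation
recomputes every iteration from scratch — no incremental covariance
downdating — so it is definitionally the naive reference procedure; the
test suite additionally checks it against an independent per-pair
recomputation built on `scipy.stats.pearsonr`/`spearmanr`.

**Group level.** Subject networks (at θ) are aggregated two ways and the
criteria intersected: prevalence (edge present in ≥ ⌈subject_fraction·S⌉ of
S subjects) and a one-sample two-tailed t-test of the per-subject retention
fractions against `null_value`. `null_value` defaults to 0.05, reading
"chance-level retention" as the nominal significance level of a truly null
edge; it is a config parameter, not a constant, because that reading is a
modeling choice. No multiple-testing correction is applied to the group
t-tests by default, matching the per-edge α = 0.05 convention at this
stage.

**Method comparison.** Paired 2×2 detection table over the m pairs; exact
(binomial) McNemar on the discordant counts, two-sided as twice the smaller
tail, capped at 1, with b = c = 0 ⇒ p = 1. The exact form is the primary
one because one-sided discordance (c = 0) yields the closed form 2·0.5^b,
which is the regime these comparisons actually produce; a continuity-
corrected chi-square variant is available for completeness. Hemisphere
classification accepts both `lh_`/`rh_` and `lh-`/`rh-` prefixes, the two
dialects that occur in Desikan-Killiany label lists in the wild.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | edge-wise significance level before Bonferroni (unitless) |
| θ | 0.85 | retention threshold, fraction of T iterations (inclusive) |
| sweep θ | 0.70/0.80/0.85/0.90 | thresholds evaluated by the sweep |
| subject_fraction | 0.85 | cohort prevalence for a consensus edge |
| null_value | 0.05 | chance-level retention for the group t-test |
| noise_sd | 1.0 | marginal SD of synthetic signals (arbitrary units) |
| ar_coeff | 0.0 | AR(1) coefficient of synthetic innovations |

θ = 0.85 sits between stability stringency and network density: strong
edges are insensitive in the 0.70–0.90 range (the sweep verifies this on
synthetic cohorts), so the choice mostly governs how aggressively marginal
edges are pruned.

## The synthetic generator

Subjects are zero-mean multivariate normal draws whose correlation matrix
is the identity plus user-planted edges, scaled by `noise_sd`. The matrix
is validated for positive semi-definiteness before sampling (eigenvalue
check; an explicit `repair=True` projects to the nearest PSD correlation
matrix by eigenvalue clipping plus diagonal renormalization).
`disjoint_planted_edges` places edges on disjoint ROI pairs, which keeps
the target block-diagonal and hence positive definite for any |r| < 1 and
any edge count — the safe construction for large planted sets. Optional
outliers add `magnitude × noise_sd` to chosen ROIs at a single timepoint,
emulating a motion spike that manufactures spurious correlation. Per-subject
substreams come from `SeedSequence(master_seed, spawn_key=(subject_index,))`,
so cohorts are element-for-element reproducible and extending a cohort never
changes existing subjects.

What the generator does **not** emulate: hemodynamic-response convolution,
task block structure, spatially correlated noise, scanner drift, or
subject-level variability in the planted structure (all subjects share one
target matrix; only the noise differs). Passing tests therefore demonstrate
correctness of the estimators and thresholds under the stated sampling
model, not robustness to the full physiology of real BOLD data.

### The masked-edge fixture

`masked_edge_series` constructs the mechanism by which the jackknife can be
strictly more sensitive than the static test. A single adversarial
timepoint cannot do it: a lone suppressor is still present in T−1 of the T
leave-one-out subsets, so the edge would be significant in only one
iteration. Instead the fixture concentrates the pair's correlation signal
in a small minority of high-leverage timepoints (fewer than (1−θ)·T of
them) and dilutes it with anti-correlated low-amplitude timepoints
elsewhere; each dilution timepoint's cross-product is negative, so removing
*any one of them* strictly increases r. The dilution amplitude is then
bisected so the full-sample Bonferroni-adjusted p lands just above α while
every dilution-dropping iteration is individually significant, giving
retention (T−n_signal)/T ≥ θ. The calibration verifies its own
postconditions and raises rather than returning a fixture without the
property; multiple masked pairs use odd time-rolls of the pattern and are
checked for cross-pair leakage. The construction is deterministic given the
seed (which only drives the untouched ROIs).

## Numerical choices

- Correlations are computed with `numpy.corrcoef` and clipped to [−1, 1];
  a coefficient of exactly ±1 maps to p = 0 (the t-statistic diverges).
  Note that rank-identical columns generally yield r = 1 − 1 ulp through
  the normalization, matching `scipy.stats.spearmanr` bit for bit — the
  p = 0 convention fires only when the arithmetic is exact.
- Constant (zero-variance) columns make their correlations undefined:
  r = NaN, p = 1 (hence never significant, in any jackknife iteration),
  with a logged warning naming the ROI.
- Zero cross-subject variance in the group t-test is decided on the common
  value (detected via `ptp == 0`, not an SD threshold, because the mean of
  identical floats can carry rounding noise): p = 0 if it differs from the
  null value, p = 1 if it equals it, with a logged warning.
- Matrix and time-series TSVs are written with 17 significant digits and
  read with pandas' round-trip float parser, so serialize→parse is exact
  and pipeline reruns are byte-identical (the run manifest contains no
  timestamps for the same reason).
- Parallel jackknife execution (joblib, `n_jobs`) distributes iterations
  whose boolean significance matrices are summed; the result is identical
  to the serial run by construction.

## Problem sizes in the validation suite

The acceptance-style checks run at reduced but faithful sizes chosen to
exercise the same regimes as a full cortical analysis: the combinatorial
check at the full R = 68, T = 300; null calibration at 500 subjects of
R = 20, T = 100 (enough for a ±0.01 binomial SE on the family-wise error);
cohort recovery at 20 subjects, R = 68, T = 294 with 30 disjoint planted
edges at r = 0.6 over 5 master seeds. These sizes are the package's own
validation design.

## Known limitations

- The per-iteration Bonferroni-at-α criterion is one reading of "significant
  per iteration"; a looser per-iteration screen would trade specificity for
  sensitivity and is not implemented.
- Leave-one-out only; no leave-k-out or block bootstrap, and no
  sliding-window dynamics. With a single shared artifact spanning several
  timepoints, leave-one-out cannot isolate it.
- p-values assume temporal independence; with autocorrelated data
  (`ar_coeff > 0`) they are anticonservative for both detectors alike.
- Group inference is a plain one-sample t-test per edge; no mixed-effects
  or permutation machinery.
- BrainNet Viewer exports carry zero coordinates unless the user supplies
  real parcel centroids.
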