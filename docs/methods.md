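# Methods

This note documents the statistical model behind `thrombomr`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing results.

## Model and assumptions

Two-sample MR treats each independent SNP `j` as an instrumental variable:
its association with the exposure (log odds ratio `beta_X_j` with SE
`se_X_j`, from one GWAS) and with the outcome (`beta_Y_j`, `se_Y_j`, from a
second, non-overlapping GWAS) identify the causal effect `theta` of
exposure liability on outcome risk under the usual IV assumptions —
relevance (strong SNP-exposure association), independence from confounders,
and exclusion restriction (no effect on the outcome except through the
exposure). Effects are log odds per log-odds increase in exposure
liability; reports exponentiate to odds ratios. Horizontal pleiotropy
violates exclusion restriction; most of the machinery here exists to
detect it (Cochran's Q, Egger intercept, MR-PRESSO, funnel/leave-one-out
diagnostics) or to be robust to it (weighted median/mode).

## Estimators

* **IVW-MRE** (primary): origin-constrained weighted regression with
  weights `1/se_Y^2`. The multiplicative random-effects scale is
  `phi = Q/(n-1)`; the reported SE is the fixed-effect SE times
  `max(1, sqrt(phi))`. The floor (under-dispersion correction) prevents
  anti-conservative SEs when `Q < n-1`, which matters for small instrument
  counts. P-values are two-sided normal — the conventional choice for
  IVW; Egger uses t(n-2) instead because two parameters are estimated from
  typically few points.
* **Wald ratio** for single-instrument analyses (the pipeline falls back
  automatically at `n = 1`). First-order delta-method SE
  (`se_Y/|beta_X|`); exposure-side noise is ignored, which is adequate at
  the instrument strengths enforced here (F in the hundreds). Second-order
  weights are deliberately not the default; the first-order convention is
  standard two-sample practice.
* **MR-Egger**: SNPs are first orientated so `beta_X_j > 0` (both signs
  flipped together). Reorientation is on by default and toggleable
  (`reorient=False`); the intercept is only interpretable as directional
  pleiotropy relative to the exposure-increasing allele. The same
  multiplicative floor is applied with `n-2` denominator.
* **Weighted median**: ratio estimates ordered, weights
  `beta_X^2/se_Y^2` normalized; the estimate interpolates the weighted
  50th percentile over midpoint cumulative weights `S_j - w_j/2`. The SE
  is a parametric bootstrap (resampling `beta_X`, `beta_Y` from normals
  with their SEs; weights held fixed across resamples), seeded and
  deterministic.
* **Weighted mode**: argmax of a Gaussian-kernel density of the ratios
  with inverse-variance weights (first-order ratio SEs) and bandwidth
  `phi * 0.9 * min(sd, mad) * n^(-1/5)` (modified Silverman; `phi`
  defaults to 1). The argmax is located on a 1024-point grid and refined
  with bounded scalar minimization to ~1e-10; bootstrap SE as for the
  median.

## MR-PRESSO

The global statistic is the weighted sum over SNPs of squared
leave-one-out residuals `(beta_Y_j - theta_hat(-j) * beta_X_j)^2 / se_Y_j^2`,
where `theta_hat(-j)` is the *fixed-effect* IVW excluding SNP `j`
(fixed-effect inside PRESSO follows the construction of the resampling
test; the corrected estimate reported after outlier removal is the
package's primary IVW-MRE). The null distribution is built by drawing
`beta_X* ~ N(beta_X_j, se_X_j)` and `beta_Y* ~ N(theta_hat(-j) beta_X_j,
se_Y_j)` and recomputing the statistic `n_sim` times (vectorized);
Monte-Carlo p-values use the `(1 + #exceedances)/(n_sim + 1)` convention,
so the smallest attainable p is `1/(n_sim+1)`. Per-SNP outlier p-values
are Bonferroni-multiplied by the SNP count. **Granularity interplay**: a
flag at level `alpha` is only attainable when `n_snp/(n_sim+1) < alpha`;
with the default `n_sim = 1000` and `alpha = 0.05` this holds up to 50
SNPs. The distortion test compares the estimate shift caused by removing
the flagged outliers against shifts from removing equally many random
non-outliers (two-sided Monte-Carlo tail); it is unstable below four
instruments and the minimum instrument count for any PRESSO stage is
three.

## Liability-scale r² and Steiger filtering

For a binary trait the per-SNP variance explained is computed on the
liability scale. The default (`scale="logit"`) de-ascertains the sample
effect-allele frequency to a population frequency using the per-allele
odds ratio, the sample case fraction and the population prevalence `K`
(bisection on the monotone mixing equation), then takes
`r² = vg/(vg + pi²/3)` with `vg = 2p(1-p)beta²` on the standard logistic
liability. This matches the conversion used by the dominant
summary-statistics MR tooling and reproduces the familiar "a few dozen
strong instruments explain ~3% of liability variance" magnitude for a
large case-control GWAS. A probit-threshold variant (`scale="probit"`,
the classical liability-threshold ascertainment transformation with
factors `C` and `theta` from the threshold model) is provided for
comparison; it yields systematically smaller values.

Steiger filtering excludes a SNP iff `r²_outcome > r²_exposure` (plain
comparison; exclusion requires strictly more variance, so ties are kept).
A z-test variant on the difference of liability correlations is exposed
behind `z_test=True` but off by default — the plain comparison is the
documented behaviour this package standardizes on. SNPs lacking the
frequency or count data needed for the comparison are kept and flagged
`steiger_unfiltered` with a warning, never silently dropped. Prevalences
are supplied per trait in the run config; the bundled defaults are
registry-style placeholders meant to be overridden.

## Harmonization

Alignment is by rsID (the instrument tables this package consumes are
rsID-keyed); indels are dropped with a warning. Non-palindromic SNPs are
aligned by allele labels, treating complement-only matches as strand
flips. Palindromic SNPs (A/T, C/G) cannot be strand-resolved from labels:
under the default `infer_by_eaf` policy they are orientated by
allele-frequency concordance and dropped as ambiguous when either trait's
minor-allele frequency lies in `[0.42, 0.5]` (0.42 is the common
two-sample-MR convention for the ambiguity window, not an empirical
estimate) or when a frequency is missing. `drop_all` drops every
palindrome. Harmonization changes only signs and labels — the multiset of
absolute effects is invariant — and is idempotent.

## Synthetic data: what it emulates, and what it does not

The generator produces summary statistics directly on the log-odds scale:
per-SNP frequency `p ~ U(0.05, 0.95)`, true instrument effect
`gamma = 0.03 + |N(0, 0.035)|`, sampling SE `1/sqrt(2p(1-p) n_eff)` with
`n_eff = 4/(1/n_cases + 1/n_controls)`, outcome effect
`theta*gamma + pleiotropy (+ outlier offset)`. Defaults mirror the study
scale the package targets: exposure GWAS 71 771 / 1 059 740
(prevalence 0.002), outcome GWAS 9 055 / 7 203 (prevalence 0.01),
60 instruments — giving mean F around 250–400 and total exposure r² near
3%, the magnitudes typical of a modern thrombosis GWAS instrument set.
The effect allele is generated as the exposure-risk allele (`gamma > 0`),
the orientation under which a directional-pleiotropy mean is a meaningful
quantity for the Egger intercept. Outcome tables are emitted with
randomly swapped/complemented allele presentations so the harmonizer is
exercised end-to-end; a 10% fraction of palindromic SNPs is included by
default (set to 0 in scenarios where a specific SNP must survive
harmonization, e.g. the planted-outlier episode).

Not emulated: LD between instruments (tables represent the post-clumping
state), individual-level genotypes, sample overlap between the two GWAS,
allele-frequency differences between studies, population stratification,
and winner's-curse selection of instrument effects. Passing calibration
tests therefore demonstrates correctness of the estimators under the
stated sampling model, not robustness to those real-data complications.

The planted-outlier scenario adds an offset of `outlier_scale` (default
10) times the median outcome SE to designated SNPs, emulating a single
dominant pleiotropic variant whose removal restores the estimate. Note
the outlier's pull on the pooled estimate is only ~2 pooled-SE units at
the default configuration, so "removal moves the estimate toward the
truth" is asserted in aggregate across seeds; identification (maximal
leave-one-out shift, PRESSO flag) is asserted per run at the 95% level.

## Determinism

Every stochastic component (median/mode bootstraps, PRESSO resampling)
derives its seed from the single master seed recorded in the report via
`SeedSequence([master, pair_index, component])`, so reports are
byte-identical across runs with the same configuration. Report JSON uses
sorted keys; TSVs use a fixed `%.10g` float format.

## Problem sizes used in validation

The shipped test suite and acceptance script size their Monte-Carlo runs
as: 2000 replicates for type-I error, 1000 for CI coverage and
Egger-intercept recovery, 200 seeded runs for the outlier episode, and
PRESSO at `n_sim = 1000`. These sizes give Monte-Carlo standard errors
well inside the asserted tolerances (e.g. ±0.5% on a 5% rejection rate)
while keeping a full run in the tens of seconds.

## Known limitations

* No LD clumping from genotype reference panels; the LD matrix is an
  input. No proxy-SNP lookup: unavailable SNPs are handled by
  intersection.
* No multivariable MR, SIMEX-corrected Egger, robust/penalized IVW or
  contamination-mixture estimators.
* The distortion test's null (random inlier subsets of the same size) is
  a pragmatic parameterization; below four instruments it is not
  reported.
* Plotting is intentionally left to the caller: forest/funnel/leave-one-
  out content is emitted as tables.
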