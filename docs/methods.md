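# Methods

`metamr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, the standard sensitivity suite around it, and LD
score regression (LDSC), together with a synthetic-data generator that
gives every procedure a known ground truth.  This note records the
models, the defaults and why they were chosen, and what the validation
experiments do and do not demonstrate.

## Causal model and estimators

For instrument *j* the summary data are the exposure association
(b_Xj, se_Xj) and the outcome association (b_Yj, se_Yj), harmonized to a
common effect allele.  Under the instrumental-variable assumptions the
outcome effect decomposes as Γ_j = θ·γ_j + α_j, where θ is the causal
effect (log-odds per SD of exposure for a binary outcome), γ_j the true
exposure effect and α_j a direct (horizontally pleiotropic) path that is
zero for a valid instrument.

* **Wald ratio** — θ̂_j = b_Yj/b_Xj with first-order delta SE
  se_Yj/|b_Xj|.  A second-order correction adding
  b_Yj²·se_Xj²/b_Xj⁴ is available behind a flag; first order is the
  default because it is what the IVW algebra weights by.
* **IVW, multiplicative random effects** — the weighted regression of
  b_Y on b_X through the origin with weights 1/se_Y², equivalently the
  precision-weighted mean of Wald ratios.  The SE is scaled by
  φ = max(1, Q/(J−1)); flooring at 1 means heterogeneity can only widen
  the interval, never narrow it.  P-values use the normal reference.
* **MR-Egger** — the same regression with a free intercept after
  orienting all rows to b_X ≥ 0.  The intercept estimates average
  directional pleiotropy; slope and intercept use the t reference with
  J−2 df (chosen for small-J robustness) and a dispersion floor at 1.
* **Weighted median** — the 0.5 point of the weight-CDF of ordered Wald
  ratios with linear interpolation between cumulative-weight midpoints;
  consistent while valid instruments carry >50% of the weight.  Its SE
  comes from a parametric bootstrap (default 1000 draws of b_X and b_Y
  from their sampling normals; the seed is a required argument — no
  hidden global RNG state).
* **Power** — for a binary outcome with case fraction K, sample size N
  and instrument variance-explained R², the IVW SE is asymptotically
  1/√(N·R²·K(1−K)); two-sided power at level α follows from the normal
  shift.  This is a fixed-effect approximation: with few instruments the
  random-effects floor makes the realized test slightly conservative
  (about 3 points at J=50), which is why the calibration experiment uses
  many strong instruments (J=300).

## Instrument selection

Per exposure: keep SNPs with p < 1e-5; greedy LD clumping (smallest p
first, ties broken lexicographically by SNP id) removing neighbours with
r² ≥ 0.01 within ±500 kb on the same chromosome; per-SNP variance
explained r² = 2·eaf(1−eaf)·beta² when the allele frequency is present
(exposures standardized), else z²/(z²+n−2), with the formula used logged
per SNP; F = r²(n−2)/(1−r²) and instruments with F ≤ 10 dropped
(strictly); SNPs associated with the outcome at p < 1e-5 pruned;
optional removal of instruments annotated to user-designated confounder
traits in a local annotation table (case-insensitive substring match);
finally, exposures with fewer than 4 instruments after harmonization are
excluded (inclusive: exactly 4 passes).  Every removal is logged exactly
once with its stage and reason.

Harmonization matches on SNP id only.  Swapped allele labels flip the
outcome sign; strand flips are resolved by complementing outcome alleles
before comparison.  Palindromic (A/T, C/G) SNPs are kept only when both
frequencies are present, the exposure frequency is outside 0.5 ± 0.08
(configurable band), and the two frequencies agree on a strand; frequency
disagreement triggers a sign/frequency flip, ambiguity drops the SNP.

## Sensitivity suite and verdict

Cochran's Q with J−1 df on the Wald ratios; the Egger intercept test;
MR-PRESSO (observed residual sum of squares around leave-one-out IVW
predictions, null distribution from 1000 seeded parametric replicates,
per-SNP outlier p-values Bonferroni-adjusted over J, distortion test
against random same-size removals, all empirical p-values with the
+1/(n_sim+1) continuity correction); radial MR whose first-order slope
is algebraically the IVW estimate, with per-SNP Q contributions compared
to the χ²(1) quantile at α/J; leave-one-out IVW with stability defined
as sign preservation plus containment of the full estimate in every LOO
95% CI (a testable operationalization of "no marked alteration by a
single SNP"; the rule is pluggable); and the Steiger test comparing
aggregate instrument R² in exposure versus outcome through the
two-sample Fisher-z statistic.

The composite verdict is *supported* only when the IVW p-value is below
α, Q, Egger-intercept and PRESSO-global p-values are all above α, the
leave-one-out is stable, and the Steiger direction is exposure→outcome;
the first failing criterion names the verdict (not_significant,
heterogeneous_or_pleiotropic, unstable, wrong_direction).

The metabolome screen reports both raw IVW p-values and
Benjamini–Hochberg q-values; the verdict uses raw p by default (the
convention of hypothesis-generating metabolome screens) and can be
switched to q.  With hundreds of null exposures at raw p < .05 some
false positives are expected by construction; the q-column is the guard.
Reverse MR is orchestration, not a new estimator: roles are swapped,
instruments re-selected from the former outcome at identical thresholds,
and "no reverse effect" declared when the reverse IVW p exceeds α.

## LD score regression

χ²_j is regressed on x_j = N_j·ℓ_j/M with a free intercept; the slope is
h².  Weights combine the heteroskedasticity correction
1/(2(1 + h²x + (intercept−1))²) — iterated twice from an unweighted fit,
with h² clipped to [0,1] inside the weights only — and the 1/max(ℓ,1)
overcounting correction.  Statistics above chisq_max = max(80, 0.001·N)
are excluded.  SEs come from a delete-one block jackknife over 200
contiguous blocks (per-block X'WX/X'Wy sufficient statistics make the
jackknife exact and cheap).  Cross-trait, z1·z2 is regressed on
√(N1N2)·ℓ/M with a free intercept absorbing sample overlap;
rg = gencov/√(h²₁h²₂), and the jackknife re-derives all three
regressions per deleted block so the SE propagates through the ratio.
Non-positive heritability yields a flagged NA, never a silent omission.
M is the total polygenic SNP count and may exceed the scored panel; h²
is invariant to jointly rescaling ℓ and M.

## Synthetic data

The generator emulates a metabolite-on-disease study entirely at the
summary level: eaf ~ Uniform(maf_range); per-SNP target r² uniform over
`instrument_r2_range` with γ = √(r²/2p(1−p)) (the effect allele is taken
as the exposure-increasing allele, as metabolite GWAS convention
reports); α per `pleiotropy_mode` (none / balanced / directional on an
`invalid_fraction` subset / a single outlier offset by 10× its outcome
SE); observed betas drawn with se_X = 1/√(2N_X p(1−p)) and
se_Y = 1/√(2N_Y p(1−p)K(1−K)).  The LD matrix is block-diagonal and is
consumed by clumping only — sampling noise across SNPs is independent.
A screen-level wrapper gives each exposure its own SNP panel and stacks
the per-panel outcome rows.  Everything is a pure function of
(config, seed).

Named presets define the validation conditions:

* **clean** — J=50, θ=0.3, N_X=7824, N_Y=377277, K=2836/377277
  (≈0.75%), per-SNP r² ~ U(0.01%, 3%).  The deliberately heterogeneous
  instrument strengths put MR-Egger in its valid regime: Egger is
  consistent only as I²_GX = var(γ)/(var(γ)+E[se_X²]) → 1, and this
  range yields I²_GX ≈ 0.95 at N_X=7824, leaving a residual attenuation
  of about −0.015 on θ=0.3 (visible in the recovery experiment; IVW and
  the weighted median are unbiased to Monte-Carlo error).
* **balanced_pleiotropy** — 30% invalid instruments, α ~ N(0, 0.05):
  heterogeneity without directional bias.
* **directional_pleiotropy** — 40% invalid, α ~ N(0.1, 0.05), on a
  balanced (K=0.3) well-powered outcome so that contamination rather
  than sampling noise dominates the IVW/weighted-median contrast.
* **one_outlier** — J=20 with one planted pleiotropic SNP at 10× its SE.
* **half_invalid** — the weighted-median breakdown boundary (50%).
* **ldsc_null / ldsc_rg05** — 10 000-SNP panels sampled from M=10⁶
  polygenic SNPs, Gamma(4, 25) LD scores clipped at 1, h²=(0.3, 0.2),
  rg 0 or 0.5, N=50 000 per trait.

What the generator does **not** emulate: LD-correlated sampling noise,
real allele-frequency spectra and LD-score/MAF dependence, population
stratification, sample overlap between exposure and outcome, or
binary-trait liability-scale subtleties (case-control betas are drawn
directly on the log-odds scale).  Passing tests therefore demonstrate
internal statistical correctness of the estimators and their
calibration under the stated generative model, not robustness to those
real-data complications.

## Numerical choices and validation conditions

Degenerate inputs: a zero exposure effect is a hard error for Wald
ratios; all-outlier PRESSO flags are an error; LD scores with zero
variance are unidentifiable; empty harmonization (no shared SNPs) is an
error; per-exposure failures inside a screen are isolated into a
"failed" row.  Clumping ties break lexicographically, making every
pipeline byte-reproducible under fixed seeds; per-exposure substreams
are derived as (seed·1000003 + index) mod 2³¹−1.

Validation problem sizes (chosen to characterize each property well
while remaining desk-scale): 500 replicates for estimator bias/coverage,
1000 for IVW type-I error and for the power comparison, 200 for the
contamination contrast, 100 each for PRESSO detection and LDSC recovery,
1000 for Steiger calibration.  The Steiger calibration runs at weak
aggregate R² (J=10, R²≈0.02) because the Fisher-z reference is an
asymptotic small-correlation approximation; at R²≈0.75 its variance
formula understates the sampling variance several-fold and the test is
anticonservative — a documented limitation of aggregate-R² Steiger
testing, not of the implementation.

## Known limitations

No multivariable MR, mode-based estimators, or partitioned LDSC; LD is
always an input, never computed from genotypes; positions are carried
but matching is by SNP id only (no liftover); the confounder screen is a
local-table join, so its completeness is bounded by the annotation table
supplied.
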