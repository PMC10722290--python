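# Methods

This note documents the statistical model behind `mrpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the design was open.

## Setting

Two-sample summary-statistic Mendelian randomization: per-SNP association
estimates for an exposure (continuous, in SD units) come from one GWAS and
for a binary outcome (log-odds scale) from another, non-overlapping GWAS.
Instruments are assumed relevant (associated with the exposure), exchangeable
(independent of confounders) and excludable (affecting the outcome only
through the exposure); each estimator relaxes the third assumption in its own
way. All associations are treated as log-linear, per-allele, and biallelic;
indels and multi-allelic records are rejected at parse time.

## Instrument selection

The filter chain runs in a fixed order, each stage audited with counts and
removed rsIDs so initial − Σ removals = final always reconciles:

1. **Relevance**: keep SNPs with exposure p < `p_instrument`
   (default 1e-5, the threshold typically used for molecular/microbiome
   exposures where genome-wide 5e-8 leaves too few instruments).
2. **Independence**: greedy LD clumping — visit SNPs by ascending p (ties by
   position then rsID for reproducibility); reject a SNP only if some
   previously accepted SNP on the same chromosome is both within
   `clump_kb` (default 10,000 kb, center-to-center) **and** has
   r² ≥ `clump_r2` (default 0.001). LD is consumed, never computed: callers
   supply a sparse pairwise r² table and absent pairs count as r² = 0.
3. **Outcome availability**: SNPs missing from the outcome set are replaced
   by the highest-r² proxy with r² ≥ 0.8 (ties by base-pair distance, then
   rsID); SNPs with no qualifying proxy are dropped and reported, not
   errored.
4. **Harmonization** (below).
5. **Strength**: F = β²/σ² per SNP; F < 10 marks a weak instrument (the
   conventional bound) and is removed.
6. **Directionality**: per-SNP Steiger filter — a SNP explaining more
   outcome than exposure variance is removed.
7. **Exchangeability**: SNPs associated with a confounder trait (default
   set: smoking, alcohol consumption, obesity) at p < 5e-8 in an offline
   annotation table are removed. The annotation table is an input; no live
   service is queried.
8. **Outliers**: MR-PRESSO outliers (below) are removed before the final
   estimates.

Where the narrative order of confounder screening versus outlier removal is
ambiguous in practice, this package fixes confounders-then-PRESSO and
records the order in the report metadata.

## Harmonization

Outcome records are mapped onto the exposure's effect-allele frame: identical
allele pairs pass through; swapped pairs negate the outcome beta and reflect
the frequency; strand-complemented pairs (A↔T, C↔G applied to both alleles)
are resolved and then aligned. Palindromic SNPs (A/T or G/C) cannot be
oriented from alleles alone: they are dropped when the exposure effect-allele
frequency falls inside the configurable ambiguity window or when either
frequency is missing, and otherwise oriented by frequency concordance
(discordant minor/major sides flip the outcome effect).

The default window is **[0.01, 0.30]**, deliberately kept as configuration:
it is one published convention, and a deliberately asymmetric one — note
that an eaf of 0.15 falls inside it while its mirror 0.85 does not, so the
palindrome disposition is not invariant to which allele a source calls the
effect allele. The `drop_all_palindromic` preset sidesteps the issue by
excluding every palindrome; users who prefer the symmetric ~0.42–0.58
"intermediate frequency" convention can set the window accordingly.
Non-palindromic SNPs with missing frequencies are kept (alleles suffice).

## Estimators

With ratio r_j = β̂_Yj/β̂_Xj and first-order SE σ_Yj/|β̂_Xj|:

- **IVW**: β̂ = Σ w_j r_j / Σ w_j, w_j = β̂²_Xj/σ²_Yj. Fixed-effect
  SE (Σ w_j)^{-1/2}; the multiplicative random-effects (headline) variant
  multiplies by √max(1, Q/(J−1)) — heterogeneity widens, never narrows, the
  interval. Normal reference distribution. J = 1 reduces exactly to the Wald
  ratio.
- **MR-Egger**: WLS of β̂_Y on β̂_X with intercept, weights 1/σ²_Y, after
  re-signing so every β̂_X ≥ 0. Reported SEs use the max(1, Q/(J−2))
  inflation; p-values use t(J−2). I²_GX (the weighted I² of the exposure
  effects) quantifies NOME; below 0.90 the slope is flagged as attenuated.
  SIMEX-style dilution correction is out of scope — the flag is the contract.
- **Egger intercept test**: the pleiotropy *hypothesis test* uses the plain
  WLS residual scale rather than the truncated one. The truncation exists to
  keep the reported effect interval from shrinking below its fixed-effect
  width; applied to the intercept test it makes the null rejection rate
  ≈3.6% instead of the nominal 5% at J = 30. With the exact scale the t(J−2)
  test is exactly calibrated, which is what a pleiotropy screen should be.
- **Weighted median**: sort ratios, place each at its centred normalized
  cumulative weight (cumsum − w/2), interpolate at 0.5. Consistent while
  valid instruments hold >50% of weight; the planted-invalid simulations in
  the test suite document recovery at 40% invalid weight and breakdown at
  60%.
- **Weighted mode**: argmax of the inverse-variance-weighted gaussian kernel
  density over the ratios; bandwidth = φ · 0.9 · min(sd, 1.4826·MAD) ·
  J^{−1/5} with φ = 1 by default (φ and the bootstrap count are declared
  configuration — no published value is being matched). The argmax is seeded
  from the density evaluated at the data points, so a single wild ratio
  cannot starve the dense cluster of grid resolution.
- **Bootstrap SEs** (median and mode): parametric — redraw both effect
  vectors from N(β̂, σ²), recompute the point estimate, take the SD over
  `n_boot` draws (default 1000, explicit seed required). `n_boot=0` skips
  the bootstrap for simulation studies needing only point estimates.
- **MR-RAPS**: maximize the profile likelihood in which each standardized
  residual (β̂_Yj − β·β̂_Xj)/√(σ²_Yj + β²σ²_Xj + τ²) is standard normal;
  τ² ≥ 0 absorbs balanced pleiotropy and is fixed at 0 when overdispersion
  is off. Nelder–Mead on (β, √τ²) with tolerance 1e-8, initialized at the
  IVW estimate; SE from the observed information (central finite
  differences of the profile likelihood). With error-free exposure effects
  and τ² = 0 the score equation reduces algebraically to fixed-effect IVW —
  the test suite checks this to 1e-6.

CI level is 95% (z = 1.959964) throughout, configurable via `alpha`.

## Sensitivity suite

- **Cochran's Q**: Σ w_j (r_j − β̂_FE)² with w_j = 1/se²_ratio,j, df = J−1
  (IVW version); the weighted residual sum about the fitted Egger line,
  df = J−2 (Egger version). p is the upper chi-square tail; p < 0.05 is
  read as heterogeneity, and the pipeline's headline method is the
  multiplicative random-effects IVW precisely so heterogeneity is absorbed
  into the SE rather than ignored.
- **MR-PRESSO**: observed RSS = Σ (β̂_Yj − β̂_{−j}β̂_Xj)²/σ²_Yj with
  β̂_{−j} the leave-one-out IVW estimate; compared against `n_sim`
  (default 1000) parametric simulations under the no-pleiotropy model in
  which both effect vectors are redrawn around the leave-one-out fit.
  Empirical p-values are raw exceedance fractions — a residual beyond every
  simulation yields p = 0, which is what allows a per-SNP p to clear the
  Bonferroni bar α/J (with (k+1)/(n+1) smoothing the floor 1/(n_sim+1)
  exceeds 0.05/J already at J = 50, n_sim = 1000, and no outlier could ever
  be declared). Outliers are removed and the corrected estimate is the IVW
  over the survivors; the distortion test compares the resulting shift
  against removals of random same-size subsets. Seed-reproducible by
  construction; J ≥ 4 and n_sim ≥ 100 are enforced.
- **MR-Steiger**: per-SNP squared trait correlation from the z-score,
  r² = z²/(z² + n − 2), summed per side; direction is confirmed (TRUE) only
  if the exposure side strictly dominates — an exact tie reports FALSE with
  p ≈ 1. The p-value compares the two aggregate correlations via Fisher's
  z transform (a declared choice; nothing is attributed to any published
  per-taxon p-values). Binary-outcome r² stays on the observed scale;
  liability-scale conversion is a known omission.
- **Leave-one-out**: J re-estimates (multiplicative random-effects IVW)
  plus the all-SNP row; omissions that flip the sign or move p across α are
  flagged.

## Power

Two-sided power of the IVW Wald test for a binary outcome:
power = 1 − Φ(z_{1−α/2} − |δ|) + Φ(−z_{1−α/2} − |δ|) with
δ = ln(OR per SD) · √(N · R² · K(1−K)), K the case fraction. At OR = 1 this
returns exactly α. Under 740 cases in 372,756 subjects, K(1−K) ≈ 0.00198
collapses the noncentrality: any OR within a few tenths of a percent of 1
gives power ≈ α, i.e. 5% — the test size, not real power.

The "adjusted p" column of the main table applies a declared method
(`none` by default, Bonferroni or Benjamini–Hochberg available) across
exposures, with the method name stamped in the report metadata, because
headline tables that print "adjusted p" without naming the adjustment
cannot be reproduced otherwise.

## Synthetic data

`simulate_pair` draws, per SNP: a MAF in `maf_range` (default 0.05–0.5) and
an allele pair (palindromic for a configurable fraction); a true exposure
effect γ_j ~ N(0, `exposure_effect_sd`²); an observed exposure effect with
sampling SE 1/√(2·maf(1−maf)·n_exp); and an observed outcome effect
N(β·γ_j + α_j, σ²_Yj) where σ_Yj uses the case/control effective sample
size n_eff = 4/(1/n_case + 1/n_control) via var(log-OR) ≈
4/(2·maf(1−maf)·n_eff), so the extreme 740/372,016 imbalance of the
motivating design is reproducible in miniature. The direct effect α_j is 0
for valid instruments and N(`pleiotropy_mean`, `pleiotropy_sd`²) for the
invalid fraction, optionally correlated with γ_j to violate InSIDE.
Directional pleiotropy is applied with the sign of γ_j (i.e. per
exposure-raising allele): defined symmetrically it would cancel under the
Egger orientation and the intercept would be unrecoverable by construction.
Default sample sizes (n_exp 18,340; 740 cases / 372,016 controls) mirror the
motivating microbiome-exposure, rare-outcome design. All randomness flows
through one `numpy` generator seeded from `SimConfig.seed`.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: LD between instruments (instruments are
generated independent; LD enters only through user-supplied tables),
sample overlap between the two GWAS, liability-scale versus observed-scale
effects, allele-frequency differences between cohorts, population
stratification, and winner's-curse bias from selecting instruments in the
same sample they were estimated in.

## Numerical conventions and degenerate inputs

- Exact-fit Egger regressions (relative weighted residual < 1e-24) report
  zero SEs and a degenerate p (1 for a zero coefficient, else 0).
- Wald ratios are undefined at β̂_X = 0 and raise; bootstrap redraws that
  hit exactly zero are nudged to the smallest positive float.
- Chi-square, normal and t tails come from scipy; the test suite verifies
  the Q-statistic tail against an independently implemented regularized
  incomplete gamma function.
- Empirical (simulation) p-values in MR-PRESSO are raw fractions, above.
- Clumping tie-breaks: ascending p, then position, then rsID.
- All file outputs are TSV/JSON with fixed column orders; rerunning with the
  same config and seed is byte-identical (tested).

## Problem sizes used by the test suite

Null calibration uses 2,000 replicates (J = 30); parameter recovery 500
replicates at J = 200; overdispersion recovery 120 replicates; MR-PRESSO
planted-outlier and clean-data studies 100 seeded runs each at J = 50 with
n_sim = 500 (the pipeline default stays at 1000); Steiger forward
simulations 200 runs. These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping the default test run fast.

## Known limitations

No multivariable MR, contamination-mixture or Bayesian model-averaging
estimators; no Radial-MR or Rucker model selection; no SIMEX correction for
NOME violations (flag only); no liability-scale Steiger r²; no VCF input or
genome-build liftover; LD must be supplied, never computed from genotypes.
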