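# Methods

## The generative model

All validation rests on a seeded linear structural-equation system over
k independent biallelic SNPs in Hardy-Weinberg equilibrium (dosages
g_ij ~ Binomial(2, p_j)), an unobserved standard-normal confounder U,
and Gaussian residuals:

    X  = c·S + c_x·U + ε_x                      S = Σ_j w_j g_ij
    Y  = θ·X + Σ_j α_j g_ij + d·Σ_b b_b g_ib + c_y·U + ε_y
    X2 = θ_rev·Y + c·S + c_x·U + ε

X is the continuous exposure (childhood-BMI analogue), Y the SD-scaled
outcome (a disordered-eating pattern score), X2 a follow-up exposure
measurement through which reverse causation (θ_rev) can act.  The
components and their defaults:

* **Panel.** k = 96 SNPs, effect-allele frequencies uniform on
  (0.05, 0.5), external weights |N(0, 0.1²)| — oriented non-negative so
  the score counts exposure-increasing alleles (a sign flip relabels
  the effect allele and reflects the frequency).  k = 96 and the score's
  target R² = 0.03 match the instrument panel and strength typical of
  adult-BMI scores applied to childhood BMI; SD-scaled outcomes with
  unit residual noise match how latent eating-pattern scores are
  reported.
* **Variance targeting.** c is solved in closed form so the true score
  explains exactly `target_r2` of Var(X): with V_S = Σ w_j² 2p_j(1−p_j),
  c = sqrt(r²(c_x² + σ_x²) / ((1−r²)V_S)).  A zero-variance panel with
  r² > 0 is an explicit error.
* **Pleiotropy.** A `prop_invalid` fraction of panel SNPs receives
  direct outcome effects α_j ~ N(μ_α, σ_α²) — directional when μ_α ≠ 0,
  balanced when μ_α = 0, independent of the weights (so the InSIDE
  condition MR-Egger requires holds by construction).
* **Background polygenicity.** `k_background` extra SNPs with no score
  weight give the outcome its own genetic component; the scale d is
  solved against the exact population variance of the remaining outcome
  terms (including the U- and shared-SNP covariance cross-terms) so the
  background explains `background_h2` of Var(Y).  This is the
  architecture the reverse-direction split-sample design needs: the
  outcome must be heritable through SNPs that are *not* exposure
  instruments.  No study reports the eating-pattern architecture, so the
  defaults used in the replicate studies (48 background SNPs, h² = 0.2)
  are conventional polygenic-trait choices, not literature estimates.
* **Covariates.** sex ~ Bernoulli(0.5) (0 = male), age ~ N(13.8, 0.3²),
  the confounder U itself, and an energy-intake proxy 0.3·X + N(0,1),
  supporting the three nested observational adjustment sets
  (age-only / plus-confounders / fully-adjusted).
* **Options.** Fractional imputed-style dosages (truncated Gaussian
  perturbation, clipped to [0,2]) and MCAR missingness are off by
  default.  One integer seed drives everything; each operation draws
  from a fixed seed-derived substream, so identical configurations give
  byte-identical cohorts.

What the generator does **not** emulate: linkage disequilibrium (the
design assumes independent SNPs), population stratification,
non-linear or interaction effects, genotyping/imputation error
structure, and informative missingness.  Passing tests therefore
demonstrate estimator correctness under the stated structural model,
not robustness to those real-data features.

## Estimators

**Weighted allelic score.** S_i = k (Σ w_j g_ij)/(Σ w_j), on [0, 2k].
Weights must be non-negative with positive sum; positive rescaling
cancels.  Missing dosages error by default; optional per-SNP mean
imputation with 2·eaf.  Instrument characterisation reports both the
score-only R² (the conventionally tabulated strength measure) and the
incremental R² over covariates.  The confounder screen regresses each
candidate on the score and flags p < α (default α = 0.05 — the
"strongly associated" threshold is not standardised, so it is
configurable); flagged covariates are the set a downstream re-analysis
adjusts for.

**Two-stage least squares.** Stage 1: X on [1, S, C]; stage 2: Y on
[1, X̂, C].  The residual variance uses residuals against the observed
exposure (proper 2SLS covariance); classical homoskedastic SEs by
default with an HC0 sandwich option, since the originating analyses do
not state a variance estimator.  First-stage partial F and incremental
R² are always reported; F < 10 logs a weak-instrument warning but never
fails (instrument strength is reported separately, not gated).
Sex-stratified analyses refit from scratch within each stratum.
Complete-case analysis on the union of model variables.

**Wu-Hausman.** Control-function form: residuals r̂ from the first
stage enter the outcome regression Y ~ X + r̂ + C; the two-sided p of
the r̂ coefficient tests exposure endogeneity and is uniform under
exogeneity (verified by KS test over 500 replicates).

**Harmonization.** Inner join on SNP id; outcome effects aligned to the
exposure's effect allele directly or via strand complement, flipping
the sign and reflecting EAF as needed.  Palindromic (A/T, G/C) SNPs:
default policy drops them when either side's EAF is within the
ambiguity band (min(eaf, 1−eaf) ≥ 0.42, configurable) and otherwise
aligns by minor-allele side; a strict policy drops all palindromes.
Every action (kept/flipped/dropped, with reason) is logged per SNP;
harmonization is idempotent.

**IVW.** Fixed-effect weighted regression through the origin with
first-order weights 1/σ_Yj² (exposure-side uncertainty ignored, the
standard first-order choice); a multiplicative random-effects option
inflates the SE by sqrt(Q/(k−1)) when Q exceeds its df.  Cochran's
Q = Σ w_j β_Xj²(θ̂_j − β̂)² on k−1 df.

**MR-Egger.** SNPs oriented so every β_Xj ≥ 0 (both betas flipped),
which the intercept's directional-pleiotropy interpretation requires;
weighted regression with free intercept; Rucker's Q′ on k−2 df; the
residual dispersion multiplier is floored at 1; CIs use a t
distribution on k−2 df by default (small-k conservatism), normal
optionally.

**Weighted median.** Wald ratios ordered ascending; normalized
inverse-variance weights (1/ratio-SE²); cumulative midpoints
p_j = Σ_{k≤j} w̃_k − w̃_j/2; linear interpolation at 0.5.  SE from a
parametric bootstrap (resampling β_Xj, β_Yj from their stated normal
uncertainties), default 1,000 draws, seeded.

**Leave-one-out.** Re-fits IVW or Egger excluding each SNP; ranks SNPs
by |change in estimate| and by contribution to the heterogeneity
statistic (the contributions sum exactly to Q) — a concrete procedure
for naming the SNPs driving a pleiotropic signal.

**Split-sample cross-fit.** Balanced random A/B split (deterministic in
the seed).  Per direction: per-SNP scan of the trait in the scan half
(no covariates by default — the original covariate set is unstated),
selection at p ≤ threshold minus the exclusion list, weights = in-sample
betas oriented to the trait-increasing allele (no shrinkage), score in
the *other* half, 2SLS there.  Function default threshold 1e-5 stays in
the genome-wide tradition; the replicate studies use 0.05 because with
~50 causal background SNPs and n/2 = 2,500 a 1e-5 threshold has
near-zero selection power (per-SNP non-centrality ≈ (n/2)·h²/k_bg ≈ 10)
— a panel-size calculation made before any study was run.  The two
direction estimates are combined by fixed-effect inverse-variance
meta-analysis (the combination rule is a design choice recorded in the
output metadata); F < 1 in the estimation half flags the estimate
prominently rather than dropping it.

## Replicate-study design points

The studies in `mrkit.experiments` (shared by the test suite and
`scripts/acceptance.py`) use: coverage — 200 replicates of n = 5,000,
k = 96, θ = 0.3, confounder loadings 0.5; calibrations — 500 replicates
(Wu-Hausman at n = 1,000 individual-level; Cochran's Q and the Egger
intercept at the summary level with known SNP-exposure effects, where
their null distributions are exact); pleiotropy — 200 replicates at
k = 20 with two 20,000-sample cohorts for the slope comparisons and
summary-level replicates for intercept recovery; weighted median —
k = 96 with 40% invalid instruments; split-sample — 100 replicates of
n = 5,000 with 96 exposure + 48 background SNPs.  These sizes keep each
study's Monte-Carlo error several-fold smaller than the margins being
asserted while completing in minutes on one CPU.

## Known limitations and numerical notes

* **Weak-per-SNP-instrument dilution (NOME violation).**  Summary-level
  estimators regress estimated outcome effects on *estimated* exposure
  effects.  When per-SNP instrument strength is low — unavoidable when
  96 SNPs share R² = 0.03 at desk-scale n — all slopes attenuate by
  roughly ncp/(ncp+1) per SNP, and the β_Xj ≥ 0 orientation occasionally
  flips noise-signed SNPs, correlating direct effects with instrument
  strength and biasing the Egger intercept toward zero.  This is why
  intercept-recovery and Q/intercept calibration are demonstrated at the
  summary level (known β_Xj), and why the single-draw two-sample
  recovery uses 100,000-sample cohorts.
* **Weighted-median breakdown.**  With strength-proportional weights a
  40%-by-count invalid minority can carry more than half the
  inverse-variance weight; on small heavy-tailed panels (k = 20 with
  half-normal² weight shares) this happens in roughly 10-15% of
  replicates, in which the median's consistency guarantee lapses.  On
  the 96-SNP panel the weighted median beats IVW's absolute bias in
  ~98% of replicates; at k = 20 the honest margin is ~85-93%.
* **Split-sample winner's curse.**  Because score weights come from the
  independent half, the cross-fit 2SLS *estimate* is consistent (no
  attenuation toward the null; measured mean 3.998 ± 0.003 against a
  true 4.0); what the winner's curse attenuates is *instrument
  strength* — the score's out-of-half trait R² falls systematically
  below its in-half value (mean attenuation ≈ 0.025 at h² = 0.2,
  >10 MC SEs) — reducing power, with any residual finite-sample bias
  pointing toward OLS, not zero.  Both R² values are reported per
  direction.
* Ties in the weighted median are resolved by `numpy.interp` on the
  cumulative-midpoint grid; degenerate inputs (constant instrument,
  zero residual variance, zero selected SNPs, k below an estimator's
  minimum) raise explicit errors naming the condition; monomorphic SNPs
  are excluded from scans with a logged warning; dosage validation
  reports the offending row and SNP.
* Egger requires k ≥ 3, leave-one-out Egger k ≥ 4, the weighted median
  k ≥ 2 and n_boot ≥ 100.
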