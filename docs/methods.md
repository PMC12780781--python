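# Methods

## The generating model and its assumptions

`lifemr` studies a two-period lifecourse exposure. The synthetic cohort is
drawn from

- genotypes: J independent biallelic SNPs, column j ~ Binomial(2, f_j)
  (Hardy–Weinberg, no linkage disequilibrium, no relatedness or population
  stratification);
- early exposure: X₁ = G α₁ + c₁ U + ε₁, ε₁ ~ N(0, σ₁²);
- late exposure: X₂ = θ X₁ + G α₂ + c₂ U + ε₂, ε₂ ~ N(0, σ₂²);
- outcome: Y ~ Bernoulli(β₀ + ψ₁ X₁ + ψ₂ X₂ + c_Y U), risks clamped into
  (10⁻⁶, 1 − 10⁻⁶);
- recall-style recoding: each exposure is ranked and cut into an ordinal
  thinner / average / plumper variable at fixed proportions, with stable
  original-order tie-breaking.

The model is linear throughout, has no interaction between the exposure at
the two periods, and a single time-constant confounder U — the assumptions
under which the additive structural mean model identifies period effects as
risk differences are thus true by construction. These are strong idealisations:
passing tests here show the estimators do what they claim *under their own
assumptions*, not that real recall data, LD-structured genomes, logistic-like
risk, or time-varying confounding would be equally kind.

The clamped fraction is reported on every simulated cohort because clamping
is exactly where risk-difference identification degrades; it warns above 1%
(error in strict mode). The default parameterisation keeps it near 10⁻⁴.

## Default parameters

| parameter | default | units / rationale |
|---|---|---|
| n_individuals | 20 000 | large enough for stable scans, small enough for Monte-Carlo replication on one CPU |
| J | 80 (40 early + 40 late) | disjoint period-specific supports by default |
| f_j | U(0.05, 0.5) | common variants |
| per-allele effects | ±U(0.06, 0.12) exposure SD | scaled so per-SNP discovery F ≈ 30–80 at n = 20 000, matching the power a biobank-scale scan has for real adiposity variants; random sign because effect-allele orientation is arbitrary |
| θ (tracking) | 0.6 | strong tracking of early into late exposure |
| c₁, c₂, c_Y | 0.3, 0.3, 0.05 | shared confounding of exposures and outcome |
| σ₁, σ₂ | 1.0 | unit residual exposure SD |
| β₀ | 0.45 | a common outcome; keeps the linear risk interior to (0,1) given ψ₂ = 0.10 |
| ψ₁, ψ₂ | −0.02, 0.10 | protective early / adverse late controlled period effects — the constellation where the univariable vs controlled contrast is most instructive |
| tier proportions | (0.3, 0.5, 0.2) | a plausible thinner/average/plumper recall split (the real survey proportions are not published) |

## Estimators

**Univariable SMM g-estimation.** ψ̂ solves Σ(z_i − z̄)(y_i − ψ x_i) = 0,
i.e. the Wald ratio cov(z,y)/cov(z,x). With instruments that act on the
early exposure only, its probability limit is ψ₁ + θψ₂ (the period effect
including tracking-mediated pathways); in general it is
ψ₁ + ψ₂ (θ + w′Dα₂ / w′Dα₁) for score weights w and D = diag(2f(1−f)) —
the pipeline's `true_target` column uses this plug-in formula, which reduces
to the tracking identity for period-specific scores.

**Multivariable SMM.** With one score per period, ψ̂ = S_ZX⁻¹ s_ZY in sample
cross-covariances (just-identified). With more instruments than exposures
the exposures are projected on all instruments first; the result is
numerically identical to two-stage least squares (verified against an
independently coded 2SLS oracle to 10⁻¹⁰ relative error). S_ZX condition
numbers above 10¹⁰ raise an error ("instruments do not separate exposures").

**Estimand regimes.** The same number is read as a point, period, or
lifetime effect depending only on when the instruments are assumed to act;
the multivariable estimate is a controlled period effect. The package
carries the interpretation as a registry-backed metadata label
(`EstimandRegime`) precisely so that no code path ever changes the formula
with the label. No separate point-effect estimator is provided: estimating
it would need instruments acting at a literal time point, an assumption we
do not wish to encourage, so the regime label exists without a dedicated
code path.

**Inference.** Default is the estimating-equation sandwich: with
e_i = y_i − X_i′ψ̂ and g_i = (Z_i − Z̄)(e_i − ē),
A = n⁻¹Σ(Z_i − Z̄)X_i′, B = n⁻¹Σ g_i g_i′, Var(ψ̂) = A⁻¹BA⁻ᵀ/n, and 95% CIs
use the normal quantile 1.959964. The residuals in B are centred because the
moment is a covariance with an estimated instrument mean; the uncentred
variant inflates B by ē²Var(Z) and empirically over-covers (≈98% instead of
95% on binary outcomes with non-trivial prevalence). A nonparametric
case-resampling bootstrap (percentile CIs, seeded, error if >10% of
replicates fail) is the alternative; on well-behaved data the two agree
within ~15%.

**Instrument-strength diagnostics.** Univariable fits report the first-stage
F. Multivariable fits report a conditional F per exposure: the exposure is
residualized on the instrument-predicted components of the other exposures,
then the F of that residual on the instruments is formed with
Sanderson–Windmeijer-style degrees of freedom (m − k + 1 numerator terms).

**Association scans.** Per-SNP OLS of the trait on allele count plus
covariates, computed by Frisch–Waugh residualization (identical estimates,
classical SEs and t-based p-values with n − C − 2 df to a per-SNP joint
fit, verified against statsmodels). Binary traits are scanned on the linear
probability scale so SMM and IVW estimands share risk-difference units.
Monomorphic SNPs are flagged and barred from instrument candidacy. A mixed
model is unnecessary here because simulated cohorts are unrelated and
unstratified.

**Instrument tiers.** All tiers require p ≤ 5×10⁻⁸ with the target period;
`low-medium`, `medium-high` and `high` additionally require the other-period
p to exceed 5×10⁻⁸, a Bonferroni-corrected 0.05, and nominal 0.05
respectively. The Bonferroni denominator pools the period-specific variant
counts of both periods; this pooled convention is applied to both exposures'
selections. Exclusion is inclusive at the threshold ("associated at
p ≤ t" ⇒ excluded), so retention demands p strictly above it. Weights are
the discovery betas (an unweighted score is a caller choice by passing unit
weights). Note one substantive consequence of tracking: an early-acting SNP
is genuinely associated with the late exposure through θ, so with θ > 0 the
strictest early-period tier legitimately empties as discovery power grows —
period-specific instruments are scarce by the biology, not by a bug. Exact
high-tier recovery of the true supports holds for the late period, and for
both periods when θ = 0.

**IVW.** Univariable: zero-intercept regression of SNP-outcome on
SNP-exposure betas weighted by 1/se_y²; multivariable: the analogous WLS on
the exposure-beta matrix. Cochran's Q with df = J − K; standard errors carry
a multiplicative random-effects scale max(1, √(Q/df)) — the common
summary-MR default, fixed here since the choice is otherwise open.
Harmonization inner-joins on SNP id, flips the sign where effect/other
alleles are swapped, and drops mismatched allele pairs with a count.

## Pipeline and study designs

`run_analysis` chains simulate → scan → select → score → estimate for every
requested tier and framework, and emits one row per (exposure period, tier,
framework) with the estimate, sandwich CI, instrument diagnostics, regime
label, and the true target value implied by the generating truth. The
`one-sample` design (default) uses the full cohort for discovery and
estimation, accepting the overlap bias that entails (toward the confounded
observational association, visible with weak instruments); `split-sample`
halves the cohort into a discovery half (selection + weights) and an
estimation half. Empty tier selections are reported per tier and the run
continues. Full runs are byte-deterministic given the truth's seed.

`mediation_scenario` replicates the attenuation signature over Monte-Carlo
replicates: with ψ₁ ≤ 0 < ψ₂ and θ > 0, the univariable early-period
estimate is positive (targeting ψ₁ + θψ₂) while the controlled early
estimate collapses to ψ₁.

## Numerical choices and degenerate inputs

- Relevance guard: |Σ(z−z̄)x| ≤ 10⁻¹² · n · SD(z) · SD(x) raises a
  relevance error (constant instruments, null first stages).
- Tier recoding needs n ≥ 3; ties broken by stable original order so a
  constant vector still yields the exact floor(n·p) block sizes.
- Risk clamp ε = 10⁻⁶; clamp-fraction ceiling 1% (warning; error in strict
  mode).
- Covariates, when present, are residualized out of z, x and y before
  g-estimation (Frisch–Waugh), the same adjustment the scans apply.
- Bootstrap requires ≥100 replicates; seeded `default_rng` throughout; all
  simulation seeds fit in int32.

## Problem sizes used in the shipped experiments

Monte-Carlo experiments in the test-suite and in `scripts/acceptance.py` use
200 replicate cohorts of n = 20 000 with 100 SNPs for parameter-recovery and
mediation checks, 1000 replicates of n = 5000 for CI coverage, and single
cohorts of n = 30 000–50 000 for selection/consistency properties — sizes at
which the Monte-Carlo error bands in the assertions are meaningful while a
full run stays in the minutes range on one core.

## Known limitations

- No LD, no relatedness, no stratification, no selection into the cohort —
  the generator cannot probe robustness to any of these.
- Additive (risk-difference) SMMs only; multiplicative and time-to-event
  variants, weak-instrument-robust confidence sets, MR-Egger/median/mode
  pleiotropy methods are out of scope.
- The linear-probability outcome can leave (0,1) for extreme covariate
  combinations; the clamp report is the guard rail.
- Only two periods are modelled; effects of unmodelled periods load onto the
  modelled ones exactly as the estimand definitions predict, and nothing in
  the data can flag that.
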