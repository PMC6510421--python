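# Methods

## The estimation problem

Fibrinogen is a hemostatic factor whose observational association with
coronary heart disease (CHD) and myocardial infarction (MI) may be
confounded (e.g. by adiposity and inflammation) or reflect reverse
causation. Mendelian randomization treats genetic variants associated
with fibrinogen as instrumental variables: because alleles are assorted
at conception, a valid instrument is independent of confounders and
affects the outcome only through fibrinogen. `fibromr` implements the
full analysis stack around that idea — instrument construction,
one-sample survival estimation, meta-analysis, and a battery of
two-sample estimators whose differing pleiotropy assumptions make them a
sensitivity analysis — plus the synthetic data generator used to
validate all of it against known truth.

## Generative model of the synthetic data

Each simulated cohort draws, per individual i and variant j:

```
G_ij ~ Binomial(2, p_j)                          (Hardy-Weinberg dosages)
U_i  ~ N(0, 1)                                   (unobserved confounder)
F_i  = c0 + Σ_j β_j G_ij + γ_U U_i + a_age (age_i − 60)
          + a_sex sex_i + ε_i,   ε_i ~ N(0, σ_F²)
h_i  = λ0 exp(θ F_i + δ_U U_i + Σ_j α_j G_ij)    (constant hazard)
```

with exponential event times and administrative censoring at `c_max`
years. The exponential (constant-baseline-hazard) law was chosen because
its proportional-hazards and accelerated-failure-time parameterizations
are analytically interconvertible (AFT coefficient = −PH log-HR), which
both the interval-censored stage-2 fit and its tests exploit. Because U
raises both fibrinogen and the hazard, the naive Cox regression of the
outcome on measured fibrinogen is biased upward while the instrumented
estimate is not — the test suite asserts this contrast directly.

Defaults describe one fixed set of study conditions at desk scale,
chosen to echo published cohort descriptors: 30 variants with per-allele
effects β_j ∈ [0.02, 0.08] g/L and effect-allele frequencies
p_j ∈ [0.1, 0.5]; fibrinogen intercept 2.6 g/L and residual SD
σ_F = 0.6 g/L (cohort means then land near 3.2 ± 0.7 g/L);
γ_U = δ_U = 0.3; λ0 = 0.005/person-year with 12-year follow-up, giving
~13–15 % cumulative incidence; small age/sex effects
(0.01 g/L·year⁻¹, −0.1 g/L for males) so residualization is non-trivial;
n = 5,000 per cohort × 6 cohorts for recovery runs and θ = 0.25
log-hazard per g/L where a non-null effect is needed. Two-sample
standard errors use the standard GWAS approximation
`se = s / sqrt(2 p (1−p) n)` with s = σ_F for the exposure
(n = 120,000) and s = 1 for the standardized log-odds outcome
(n = 184,305, i.e. 60,801 cases + 123,504 controls). These values are
the package's fixed reference conditions, not tuning knobs.

Pleiotropy modes set the direct effects α_j: `none` (all zero),
`balanced` (N(0, 0.05)), `directional` (N(0.05, 0.02), drawn
independently of β_j so the InSIDE condition holds by construction), and
`outliers` (all zero except `n_outliers` = 2 variants given
10 × the typical variant-level outcome effect, alternating sign). The α
stream is seeded separately from cohort and summary noise so
individual-level and summary-level simulations of one config share the
same truth.

The generator also provides a Gaussian-copula construction coupling one
variant's dosage to BMI at a requested Spearman correlation (calibrated
by bisection with common random numbers), used to exercise the
risk-factor screen; and a converter to interval-censored outcomes that
replaces each event time by a (t − w/2, t + w/2] examination window.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium between
instrument variants (LD enters only as user-supplied r² tables),
case-control ascertainment of the outcome GWAS beyond the log-odds
parameterization, population stratification, assay differences between
cohorts, non-proportional hazards, and competing risks.

## Instrument construction

Filters only set independent QC flags (`low_imputation`,
`rf_correlated`, `chd_ld`, `ld_pruned`, `missing_in_cohort`), so they
are idempotent and order-free; a variant scores iff its flag set is
empty. All thresholds are strict inequalities exactly as conventionally
printed: MACH quality < 0.3 or IMPUTE quality < 0.4; |Spearman ρ| > 0.10
against any of BMI, LDL, HDL, hypertension, type-2 diabetes or smoking
in any cohort (binary traits coded 0/1, smoking ordinal
never < former < current; the screen uses |ρ|, the conservative reading
of an unsigned published cutoff); r² > 0.20 with any supplied CHD locus;
r² > 0.70 for pruning. Pruning keeps, per connected LD component, the
variant from the largest source scan, breaking ties by larger
|published β| and then lexicographic id — the tie-break is this
package's deterministic choice where convention is silent. Missing
per-individual dosages within an available variant are mean-imputed
(2 × within-cohort effect-allele frequency), preserving the score scale.
The score is the unweighted sum of aligned dosages (alignment reflects
dosages, d → 2 − d, for variants with negative published β); an
optional β-weighted score exists but is not the default, since the
reference procedure sums aligned genotypes. The per-cohort rescaling
divides by half the observed range, so one rescaled unit spans 50 % of
the range and score-based effect sizes become comparable to
single-variant ones.

## One-sample estimation

Stage 1 regresses OLS residuals of fibrinogen on age and sex against
the instrument; the weak-instrument F statistic is the single-regressor
identity (coef/se)². Stage 2 is a Cox partial-likelihood fit (Efron tie
handling, via lifelines) of the incident outcome on the stage-1 fitted
values; since those are in g/L, the coefficient is the causal log-HR per
1 g/L. The default stage-2 model is unadjusted — residualization has
already removed age and sex from the exposure — with an `adjust` option
adding them, and the reported SE is the naive model-based Cox SE
(classical two-stage predictor substitution). With allele-score
instruments the first-stage F is in the hundreds and stage-1 uncertainty
is negligible; a seeded nonparametric bootstrap over both stages is
available when it is not. The estimate is invariant to rescaling the
instrument by any c ≠ 0.

For interval-censored cohorts, stage 2 maximizes the exponential AFT
log-likelihood — events in (l, r] contribute log(S(l) − S(r)), censored
individuals −l·e^(−η) — by BFGS with a numerical-Hessian covariance
(statsmodels `approx_hess`), computed via the numerically stable
`log1p(−exp(−Δ))` form; the reported log-HR is minus the AFT
coefficient, the exact identity for the exponential distribution, so
such cohorts pool directly with Cox-based ones.

## Meta-analysis

Fixed-effects pooling is the inverse-variance closed form; Cochran's Q
is referred to χ²(k−1). The random-effects variant uses
DerSimonian-Laird τ² truncated at zero. Combined analyses pool all
per-cohort estimates directly; for fixed effects this provably equals
pooling the two arm-level pooled results, asserted as a test property.
CIs use the normal multiplier 1.96 and P-values are two-sided on the log
scale.

## Two-sample estimators

Numerical recipes are fixed so that two implementations produce
identical numbers:

* **Harmonization** matches on variant id, flips the outcome effect
  sign when alleles are recorded on the opposite allele, drops variants
  with mismatching allele sets (counted), and keeps palindromic A/T and
  C/G variants by default — no strand inference from frequencies is
  attempted; a `drop_palindromic` option removes them.
* **IVW**: closed-form zero-intercept WLS with weights 1/se²ₒᵤₜ; SE
  inflated by max(1, √(Q/(k−1))) — multiplicative overdispersion bounded
  below by 1, the mainstream convention, conservative under
  heterogeneity. A single variant falls back to the Wald ratio
  (delta-method SE = seₒᵤₜ/|β̂|).
* **MR-Egger**: pairs oriented so every β̂ > 0 (both effects flipped
  together), then WLS with intercept; the covariance is scaled by
  max(1, residual scale). The intercept estimates mean directional
  pleiotropy; the slope is the adjusted causal effect. Egger needs
  spread in β̂ — a panel of identical exposure effects is singular by
  construction and is rejected rather than answered.
* **Weighted median**: ratio estimates weighted by inverse first-order
  delta variance (se²ₒᵤₜ/β̂²; a second-order option adds the exposure
  term), sorted; the estimate interpolates the ratio at the 50 % point
  of the mid-point cumulative weights, so with equal weights over
  {1, 2, 10} it returns exactly 2. SE by seeded parametric bootstrap
  (default 1,000 draws of β̂, Γ̂ from their SEs).
* **Weighted mode (MBE)**: normal-kernel density of the ratios with
  bandwidth h = φ·h₀, h₀ = 0.9·min(sd, MAD/0.6745)·k^(−1/5) (modified
  Silverman rule), maximized by a 512-point grid search refined by
  bounded scalar optimization; φ = 1 by default. The bootstrap SE is the
  normal-consistent MAD of the bootstrap modes rather than their SD,
  following the reference mode-estimator recipe: the bootstrap mode
  occasionally jumps to a secondary density peak and a plain SD
  overstates the spread. Bootstrap modes are located on per-draw grids
  spanning each draw's 2nd–98th percentile ratio range, so a single
  near-zero exposure draw cannot coarsen the search. If all ratios
  coincide the bandwidth degenerates to zero and the common ratio is
  returned directly.
* **MR-PRESSO**: observed RSS = Σ wⱼ(Γ̂ⱼ − θ̂₋ⱼβ̂ⱼ)² with leave-one-out
  IVW slopes θ̂₋ⱼ and w = 1/se²ₒᵤₜ; the null distribution comes from
  `n_sim` parametric simulations of (β̂, Γ̂) under the no-pleiotropy
  leave-one-out fit, recomputing the leave-one-out slopes per
  simulation. The global P and per-variant outlier Ps are empirical
  exceedances with the +1 correction, so the smallest attainable
  per-variant P is 1/(n_sim+1); with the Bonferroni comparison
  p·k < 0.05 this means n_sim must exceed 20·k − 1 for any variant to be
  flaggable (the default n_sim = 1,000 suffices for k ≤ 50). The
  corrected estimate is plain IVW on non-outliers, bit-identical to IVW
  when nothing is flagged; flagging every variant is an error. The
  distortion P — the observed corrected-vs-full shift compared with
  removals of random subsets of the same size — has no canonical
  closed form and is implemented as this approximate randomization test.

Sign and unit equivariance (negating all Γ̂ negates every estimate;
scaling all β̂ by c scales estimates by 1/c) hold exactly and are
asserted on randomized instances.

## Consistency checks and pipeline

The package carries the published per-cohort sample sizes and event
counts of the eleven cohorts its design is modelled on; summing them per
outcome and arm reproduces the reported analysis totals (CHD discovery
3,147/15,427; CHD replication 1,482/34,209; MI discovery 1,711/18,798;
MI replication 687/33,288), and the Bonferroni helper reproduces the
six-test cutoff 0.05/6 ≈ 0.008. `run_pipeline` chains
simulate → build-score → 2SC → meta → two-sample MR → risk-factor
screen, writing every table as TSV ("NA" missing values, full double
precision, bit-identical round-trips) plus a manifest with the config
hash and seeds; rerunning a config reproduces every artifact
byte-for-byte.

## Numerical and testing choices

All randomness flows from one seed through per-purpose
`SeedSequence` spawn keys; no global generator state. Simulation sizes
in the test suite are the package's chosen reference scales: 500
replicates for calibration claims (null rejection within [0.02, 0.08] at
nominal 0.05), 100 replicates of 6 × 5,000 participants for coverage of
θ = 0.25, 100 replicates for MR-PRESSO outlier recovery. Closed-form
estimators are checked against independent hand-written least-squares
oracles at 1e−10; the interval-censored fit against an exponential-PH
maximum-likelihood oracle at optimizer tolerance.

## Known limitations

Naive 2SC standard errors ignore stage-1 uncertainty (negligible at
F ≈ 400, optional bootstrap otherwise); the Cox estimand is mildly
non-collapsible over residual exposure variation, visible as a small
(< 5 %) attenuation at the simulated event fractions; MR-PRESSO's
outlier test inherits the reference method's anti-conservatism when the
leave-one-out slopes are themselves contaminated; the MBE bootstrap is
slightly conservative under strong, homogeneous instruments; no
multivariable MR, Steiger filtering, LD-aware IVW, competing risks, or
time-varying covariates.
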