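# Methods

## The model

For each joint (hip, knee, ankle) the package fits a function-on-scalar
additive model to mass-normalised joint-power waveforms observed on a
discrete gait-cycle grid *t* (percent of cycle, 0–100 for hip and knee;
25–75 for the ankle, whose power is essentially zero in early stance and
mid-to-late swing):

    y_ij(t) = β₀(t) + sex_ij β_sex + f_age(age_ij, t) + f_speed(speed_ij, t)
              + f_strlen(l_ij, t) + f_ht(h_ij, t)
              + f_age,speed(age_ij, speed_ij, t) + b_j(t) + ε_ij(t)

for participant *i* in study *j*.  β₀(t) is a time-varying intercept, β_sex
a time-constant sex offset (male = 1, female = 0, so β_sex is male minus
female), the f(·, t) are smooth surfaces non-linear in both the covariate
and cycle time, f_age,speed is a trivariate smooth capturing the non-linear
age × speed interaction over the cycle, b_j(t) are study-level intercept
curves, and ε is iid Gaussian with variance σ² — independence across cycle
points within a curve is an explicit model assumption, not an afterthought.

### Bases, penalties, identifiability

* Every smooth direction uses cubic B-splines on clamped, equally spaced
  knots with a 2nd-order difference penalty on the coefficients.
* Bivariate terms are tensor products of a covariate-margin basis
  (dimension `k_cov`, default 8) and the cycle-time basis (`k_time`,
  default 20 full-cycle / 12 ankle), penalized anisotropically:
  λ_x (S_x ⊗ I) + λ_t (I ⊗ S_t).  The trivariate term uses marginal
  dimensions (`k_age`, `k_speed`, `k_time3`) = (6, 5, 8) with three penalty
  components.
* Identifiability: each covariate margin (including both covariate margins
  of the trivariate term) carries a sum-to-zero constraint over the
  *observed* covariate values, absorbed into the basis by a null-space
  reparameterisation.  Without these constraints the intercept and the
  smooths are confounded.  Consequence: the fitted β₀(t) estimates the
  population curve at the sample-average of each smooth effect.
* Study curves b_j(t) are time-basis blocks, one per study, under a single
  shared ridge penalty λ_b — the penalized-regression form of a functional
  random intercept; λ_b plays the role of σ²/τ².
* Stride frequency is refused as a covariate whenever speed and stride
  length are both present: speed / stride length *is* stride frequency, so
  the design would be perfectly collinear.

### Estimation

Coefficients solve the penalized normal equations
(XᵀX + Σ_k λ_k S_k) β = Xᵀy.  Because every curve of one joint lives on the
same cycle grid, XᵀX is assembled in product form — the block between terms
m and n is kron(Z_mᵀZ_n, B_mᵀB_n) — so the stacked design (n·T rows) is
never materialised; fitting cost is dominated by the Cholesky of the
p × p penalized system per candidate λ.

Smoothing parameters are selected by exact profiled Gaussian REML,

    V(ρ) = (n − M_p) log r(ρ) + log|XᵀX + S_λ| − log|S_λ|₊ ,

with ρ = log λ, r the penalized residual sum of squares, M_p the total
penalty null-space dimension, and |·|₊ the pseudo-determinant.  V is
minimised by L-BFGS-B with analytic gradients (dr/dρ_k = λ_k βᵀS_kβ by the
envelope theorem; the log-determinant terms via H⁻¹ and per-block
pseudo-inverses).  Two robustness measures matter in practice:

* **Initialisation of the study ridge.**  The REML score is flat as any
  full-rank penalty's λ grows (the limit is a well-defined smaller model),
  and the generic trace-ratio start sits inside that flat shoulder, where a
  quasi-Newton run can terminate with the study curves spuriously shrunk to
  zero — and, downstream, a sex-effect SE blind to between-study
  confounding.  The ridge is therefore initialised from a method-of-moments
  estimate of the between-study curve variance.
* **Coordinate-probe polish.**  After convergence each ρ_k is probed at
  ±2, ±4, ±8; any strict improvement restarts the optimizer.  The null
  t-test calibration checked by the test suite depends on this: without it
  the flat-shoulder terminations leave the null t-statistic visibly
  over-dispersed.

A GCV coordinate grid search is available as the fallback selection method.
σ² is the unpenalized residual sum of squares over n − edf, with
edf = tr[(XᵀX + S_λ)⁻¹XᵀX].

### Inference

The posterior covariance of the stacked coefficients is
V_b = σ²(XᵀX + S_λ)⁻¹ (for the mixed-model blocks this coincides with the
Henderson joint covariance, so the sex-effect SE accounts for between-study
variance *given* λ).  Because conditioning on the selected λ understates
uncertainty, a first-order smoothing-parameter-uncertainty correction
V_c = V_b + J V_ρ Jᵀ is available (and used by default in the reporting
layer), with J_k = −λ_k H⁻¹S_k β̂ and V_ρ the inverse curvature of the REML
score, eigenvalue-floored in flat directions.

The sex effect is tested with t = β̂_sex / SE against a t reference on
n − edf degrees of freedom.  Confidence intervals for derived peak values
(the discrete power indices of predicted curves) are obtained by simulating
whole curves from N(β̂, V_c) and re-extracting the index from each draw
(2.5/97.5 percentiles); the delta method is avoided because the argmax
functional is not differentiable.

## Discrete power indices

The nine canonical peaks (A1, A2 ankle; K1–K4 knee; H1–H3 hip) are
extrema over fixed cycle-point windows encoding standard gait-phase
boundaries (e.g. A2: positive maximum over 40–65%, the pre-swing push-off
burst; K4: negative minimum over 85–100%, terminal-swing hamstring
absorption).  Published descriptions name only the phases, so the numeric
windows are this package's single largest interpretive choice; they are
fully overridable per label via configuration.  Ties break to the earliest
cycle point; an extremum below 0.01 W/kg in magnitude is flagged `absent`
(H1 in particular is not always present), and an extremum contradicting the
expected sign is flagged `wrong_sign`.

## Synthetic cohort

The generator emulates the statistical structure of a pooled multi-study
lifespan cohort with known ground truth:

* **Ages** are decade-stratified (round-robin over decades 1–9 within the
  configured range, default 3–91 y) so that children and the oldest old are
  never underrepresented and recovery tests across the lifespan are
  well-posed.
* **Anthropometry**: height and stride length follow piecewise-linear
  age-growth curves anchored at per-decade reference means (1.04 m height
  and 0.88 m stride in the 1st decade, 1.75/1.47 in the 3rd, declining to
  1.64/1.26 in the 9th), flat within a decade with 1-year ramps across
  boundaries — so the decade *means* match the anchors — plus Gaussian
  jitter (SD 0.05 m height, 0.08 m stride).  Body mass is BMI · height²
  with truncated-normal BMI.  Walking speed is truncated-normal,
  mean 1.2 m/s, SD 0.2, support [0.5, 2.0].
* **Waveforms** are built exactly as the model assumes: a per-joint
  template (sums of Gaussian bumps placed so each index window carries its
  canonical sign — e.g. a +2.3 W/kg push-off bump at 55% of the cycle,
  width 6, for the ankle), plus rank-one covariate effects
  amp · (g(x) − c) · ψ(t) acting through the joint's propulsion-burst shape
  ψ, a constant sex offset (defaults −0.026 ankle, −0.019 hip,
  +0.012 knee W/kg, male minus female), study curves drawn as random
  B-spline coefficients (zero mean, scale `study_sd`, default 0.1 W/kg) and
  iid Gaussian noise (`noise_sd`, default 0.15 W/kg — the residual scale is
  a free choice and fully configurable).
* The default age profile of the ankle effect peaks at 25 years
  (amplitude 0.2 W/kg, Gaussian width 22 y), so the true A2-vs-decade
  trajectory culminates in the 3rd decade; the hip profile is a saturating
  tanh, rising to a plateau in mid-life.  The speed effect is monotone
  increasing over the observed range.  Effect profiles are centred
  (numerically) over the covariate sampling distribution, mirroring the
  model's sum-to-zero conventions.

What the generator does **not** emulate: within-curve correlated noise,
stride-to-stride variability, asymmetry between limbs, treadmill-vs-
overground differences beyond the study intercept, or marker-level
processing artifacts.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to the misspecifications real pooled data contain.

## Validation experiments and problem sizes

Replicated experiments (module `gaitpower.validation`) use a compact model
spec (`k_time`=16, `k_cov`=6, trivariate (5, 4, 8)) on the ankle; the
calibration experiments raise `k_time` to 20 so that the spline
approximation error of the narrow push-off burst sits well below the
pointwise SE.  Sample sizes follow the
property being tested: n=400 with noise 0.1 for scalar recovery and power,
n=200 for calibration and the null t-test, n ∈ {100, 300, 900} for
consistency of the speed surface.  Coverage experiments switch the study
heterogeneity off and compare β₀(t) against the template plus the
per-replicate sample mean of the true effects — the exact estimand under
sum-to-zero-over-observed-values constraints.

## Known limitations

* **Peak-interval coverage at curvature maxima.**  Pointwise Bayesian
  intervals for penalized smooths are well calibrated on average across the
  function but under-cover where penalization bias concentrates.  The
  derived A2-peak intervals inherit this: at the decades where the true age
  profile has maximal curvature (3rd–4th), simulated coverage drops to
  well below half the nominal level, and to roughly 80–85% averaged over
  all nine decades, even with the smoothing-uncertainty correction (the
  calibration experiment in `gaitpower.validation` measures this directly).  An independent cross-check fitting the
  same data with a mature GAM implementation (mgcv `bam` with `ti()`
  tensor smooths, fREML) shows the same or larger attenuation of the
  predicted peak, i.e. this is a property of anisotropic penalized tensor
  smoothing at this signal-to-noise, not of this implementation.
* The sex t-test propagates between-study variance only through the ridge
  at the *selected* λ_b; with very few, strongly heterogeneous studies the
  test over-rejects (no Kenward–Roger-type small-sample correction is
  implemented).
* The iid-error assumption makes the reported SEs optimistic for real gait
  data, where residuals are strongly correlated along the cycle.
* Study curves are penalized fixed-effect curves (mixed-model equivalence);
  subject-level random curves are out of scope.
* Exact numeric agreement with any particular published fit is not a goal:
  basis dimensions, penalty orders and the selection criterion of published
  analyses are rarely reported, and the estimates depend on them.
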