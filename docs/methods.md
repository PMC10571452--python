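# Methods

## Setting

A cohort of hospitalised pneumonia patients is followed from admission
(t = 0) with pulse rate (PR, beats/min) and body temperature (BT, °C)
measured every six hours up to the 102-hour visit (at most 17 visits per
outcome), and the event of interest is recovery (status 1) versus
censoring (status 0).  Twelve categorical baseline covariates (sex, age
group, residence, toilet type, income, drinking-water source, household
size, presenting symptom, comorbidity, danger signs, occupation, severity)
are dummy-coded with the first category as reference; visit time is the
only continuous regressor and always enters in hours.

## Model

Longitudinal sub-model for outcome k of subject i:
y_ik(t) = x_i'β_k + b_ik0 + b_ik1 t + ε_ik(t), ε_ik ~ N(0, σ_k²), with
b_i = (b_i10, b_i11, b_i20, b_i21) ~ N(0, D) shared across outcomes; the
off-diagonal blocks of D induce the PR–BT dependence.  The model-implied
marginal correlation between the outcomes at time t is

ρ(t) = z(t)'D₁₂z(t) / √[(z(t)'D₁₁z(t)+σ₁²)(z(t)'D₂₂z(t)+σ₂²)],  z(t) = (1, t),

and an empirical per-visit correlation is reported alongside it.

Survival sub-model: h_i(t) = h₀(t) exp(γ'w_i + association), with
piecewise-constant h₀ and one of three association structures — the
current (noise-free) biomarker values Σα_k m_ik(t); current values plus
subject-specific slopes; or the random slopes b_ik1 directly.  The
structures are mutually exclusive by construction (a single enum selects
one), which is the identifiability guard against double-counting the
latent signal.

## Estimation

All fits are maximum likelihood (not REML): the joint model needs one
coherent likelihood, and separate-versus-joint comparisons use the same
objective.  D is parameterised by its log-Cholesky factor, residual SDs
and hazard rates on the log scale, so the search is unconstrained; box
bounds at ±8 on the log scales keep line searches out of numerically
degenerate territory, and invalid evaluations near boundaries return a
large penalty rather than aborting.

The joint likelihood per subject is the 4-dimensional integral of
(longitudinal Gaussian density) × h^δ exp(−Λ) × N(b; 0, D).  Since the
Gaussian longitudinal factor times the prior equals the marginal
longitudinal density times the Gaussian posterior of b, the integral is
computed exactly as  marginal × E_posterior[survival term], and the
expectation uses a product Gauss–Hermite rule (default 7 nodes per active
dimension, corner nodes pruned below a 1e−10 relative weight and the
remaining weights renormalised to 1) centred at each subject's posterior.
This is adaptive quadrature by construction, exact when the association is
zero; only the dimensions the hazard actually depends on are integrated
(2 for shared random effects, 4 for the current-value structures).
Because trajectories are affine in time, the cumulative hazard on each
node is the closed form Σ_p λ_p e^A (e^{C t₂} − e^{C t₁})/C with the
C → 0 limit handled by expm1.  The baseline hazard is piecewise-constant
with cutpoints at event-time quantiles (5 pieces by default); a parametric
Weibull baseline is deliberately not offered because it would forfeit the
closed-form cumulative hazard that both the likelihood and the event-time
simulator rely on.

For the current-value structures the biomarker enters the hazard centred
at the observed outcome means (or an explicit `assoc_center`).  This is a
pure reparameterisation — α is unchanged, only the meaning of the baseline
rates shifts to "hazard at an average biomarker level" — but without it a
pulse-rate association of −0.05 would force baseline rates of order
e^{5.5} to compensate for α·110, creating a needle-shaped likelihood
valley.

Optimisation is L-BFGS-B started from the separate fits (bivariate LMM
with β profiled out by GLS; piecewise-exponential PH with rates profiled
in closed form) and α = 0, with central finite-difference gradients
evaluated as one batched vectorised call; convergence uses relative
log-likelihood change 1e−11 (machine-factr units) and gradient tolerance
1e−5 with at most 1000 iterations, and non-convergence is flagged on the
fit rather than raised.  Standard errors come from the inverse observed
information (central-difference Hessian); a non-positive-definite Hessian
flags them unreliable.  β, γ and α standard errors are on the natural
scale; variance components are reported without standard errors.  The fit
is deterministic given data and spec — randomness only enters through the
simulator.

AIC = −2ℓ + 2p and BIC = −2ℓ + p log(n subjects).  The reported
decomposition evaluates the conditional survival log-likelihood at the
empirical-Bayes random effects with the survival-side parameter count and
assigns the remainder to the longitudinal side, so the parts sum to the
total exactly; it is a standard conditional split, not a claim about any
particular refinement of these criteria.

Dynamic predictions P(T ≥ t+Δ | T ≥ t, history to t) are empirical-Bayes
plug-ins: posterior mean of b from the history up to t, then the ratio of
plug-in survival functions.

Kaplan–Meier estimation, the k-sample log-rank test and the Cox partial
likelihood (Efron ties by default — the 6-hour grid produces ties —
Breslow selectable) are delegated to lifelines behind this package's
surfaces; tests check them against hand product-limit calculations and a
brute-force O−E/hypergeometric-variance implementation.  Tied censoring
at an event time keeps the censored subjects at risk for that event.
Mean survival is reported as the restricted mean up to the largest
observed time.

## Synthetic cohort generator

The generator draws covariates from configurable category frequencies
(defaults: the observed marginal frequencies of the 214-patient cohort),
random effects from N(0, D), trajectories on the 6-hour grid with
independent Gaussian noise, and event times by exact inversion of the
closed-form cumulative hazard (piece-walking root isolation), applying
administrative censoring at 102 h (optional independent uniform dropout).
Longitudinal records after the observed event/censoring time are removed,
so the generator satisfies the truncation invariant by construction.  The
same seed yields bit-identical cohorts.

Default true parameters are the study's reported estimates: fixed effects
(e.g. PR intercept 117.92, visit-time slopes −0.4236 bpm/h and −0.0119
°C/h), survival coefficients, association (−0.4268, −0.2931) on the
random slopes, and residual variances 13.4975 / 0.4963 read as variances
(σ₁ ≈ 3.67 bpm, σ₂ ≈ 0.70 °C) — the alternative reading as SDs remains a
config knob.  The reported 4×4 random-effects covariance is slightly
indefinite (smallest eigenvalue −0.27); the default projects it to the
nearest PSD matrix (eigenvalue clip, floored at 1e−6), which moves no
entry by more than ~0.14.  The baseline hazard default is three pieces
(cuts 48 h, 78 h) with rates calibrated by solving E[exp(−e^A H₀(t))] =
S(t) under the default frailty distribution so that the marginal survival
hits S(66) = 0.5 and S(102) = 0.145: median recovery ≈ 66 h and ≈85.5%
recovered, matching the study's reported medians; the steep final rate is
what the heavy between-subject frailty implies.

Caveat discovered while validating: with the near-singular default D, the
BT random slope is almost a linear combination of the other three random
effects, which leaves the shared-random-effects association weakly
identified (a likelihood ridge trades α against entries of D).
Single-dataset α estimates under these defaults are therefore unstable
even though their signs are robust; parameter-recovery experiments use a
well-conditioned covariance instead (see below).  What the generator does
not emulate: informative visit processes, measurement-error in visit
times, non-linear trajectories, interval censoring — so passing recovery
tests demonstrate correctness of the estimator under the stated model,
not robustness to those violations.

## Problem sizes used in tests and the acceptance script

Parameter-recovery experiments use a deliberately compact configuration
(one binary covariate; intercept+time fixed effects; well-conditioned D;
current-value association α = (−0.05, −0.5) centred at (110, 38); ~80% of
subjects recovering): 30 replicates of n = 120 subjects with 3 quadrature
nodes per dimension in the test suite, 12 replicates in the acceptance
script, and Monte-Carlo likelihood checks with 6×10⁴ importance-sampling
draws on 5-subject instances.  These sizes give Monte-Carlo standard
errors small enough for the bias and coverage checks while keeping a full
run in the minutes range; quadrature at 3 nodes was verified against 5
and 9 nodes to move the association estimates by < 0.001.

## Known limitations

* Two longitudinal outcomes only (the random-effect layout is fixed at
  intercept+slope × 2 outcomes).
* Piecewise-constant baseline hazard only; no Weibull/spline baselines.
* No MCMC/Bayesian estimation, cure fractions, competing risks, interval
  censoring, or serial within-subject correlation beyond the random
  effects.
* Finite-difference observed information: standard errors for strongly
  boundary-constrained variance components are unreliable (and flagged).
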