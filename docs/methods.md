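# Methods

## Structural and statistical model

Drug disposition is one-compartment with first-order elimination; doses are
zero-order infusions. The concentration at time *t* is the superposition of
per-infusion contributions in closed form: during an infusion of rate R₀
started at t₀, (R₀/CL)(1 − e^(−kₑ(t−t₀))); after it ends at t₀+T,
(R₀/CL)(1 − e^(−kₑT)) e^(−kₑ(t−t₀−T)), with kₑ = CL/Vd. The closed form is
exact for linear kinetics; the test suite checks it against an independent
ODE integration. No absorption phase, peripheral compartment or nonlinear
elimination is modeled.

Between-subject variability is exponential (lognormal) on clearance and
volume with a diagonal covariance: CL_i = CL_typ(x_i)·e^(η_CL),
Vd_i = Vd_typ(x_i)·e^(η_Vd), η ~ N(0, diag(ω²_CL, ω²_Vd)). Residual error
is proportional by default (additive and combined are available):
y = f·(1+ε), ε ~ N(0, σ²). The final covariate model is

    Vd_typ = θ_Vd · (WT/12)^θ1
    CL_typ = θ_CL · KF^θ2 · (WT/12)^θ3

with weight centered at the cohort median of 12 kg and KF = eGFR/120 the
kidney-function ratio. The package also ships the seven standard candidate
parameterizations of size/maturation on clearance (fixed ¾ allometry,
estimated weight or body-surface-area exponents, a sigmoid age-maturation
factor, and weight-, age- or BSA-dependent exponents) for model comparison.
BSA-based candidates normalize by the cohort median BSA of 0.55 m²; the
intravenous route makes bioavailability identically 1, so clearances are
reported as CL rather than CL/F.

### Key parameters (defaults are the published final estimates)

| parameter | meaning | default | units |
|---|---|---|---|
| θ_Vd | typical volume at 12 kg | 11.35 | L |
| θ_CL | typical clearance at 12 kg, KF = 1 | 5.23 | L/h |
| θ1 | weight exponent on Vd | 0.80 | – |
| θ2 | KF exponent on CL | 0.92 | – |
| θ3 | weight exponent on CL | 1.02 | – |
| ω_CL, ω_Vd | SD of η (reported ×100 as %) | 0.129, 0.6578 | – |
| σ | proportional residual SD | 0.0823 | – |
| LLOQ | assay quantification limit | 0.1 | µg/mL |

## Likelihood and estimation

The marginal −2 log-likelihood of each subject is approximated by a Laplace
expansion at the conditional (empirical-Bayes) mode η̂ of the joint
−2 log-likelihood g(η), with the residual variance evaluated at the
conditional prediction (interaction). The per-subject objective is

    OFV_i = data(η̂) + log|Ω| + η̂ᵀΩ⁻¹η̂ + log|AᵀV⁻¹A + Ω⁻¹|

where A is the analytic gradient of the predictions with respect to η and V
the conditional residual covariance — a first-order-conditional (FOCE-I)
style objective. Two exactness identities anchor the approximation and are
enforced by tests: with ω² = 0 the objective equals the exact fixed-effect
−2 log-likelihood to 1e-8, and for an effectively Gaussian integrand (tiny
ω) it matches brute-force numerical integration of the marginal to 1e-4.
The named conditional-estimation scheme of the original analysis platform
is not reproduced iteration-for-iteration; any consistent FOCE-I
approximation validated by those identities is considered equivalent.

Below-quantification (BLQ) records are treated as left-censored at the
LLOQ: each contributes −2 log Φ((LLOQ − f)/√v). This choice is load-bearing
for the synthetic study conditions: with ω_Vd ≈ 66%, roughly 5% of realized
concentrations fall below 0.1 µg/mL under any plausible opportunistic
sampling window, and simply excluding them truncates the error distribution
and inflates the volume estimate by ~13% (median over replicate fits).
Exclusion remains available (`ModelSpec.blq="exclude"`) for data known to
be complete.

### Inner problem (conditional modes)

All subjects' 2-dimensional modes are found simultaneously by a batched
damped Newton iteration. Predictions and their first and second derivatives
with respect to η are analytic (closed-form differentiation of the
superposition expression); the Hessian combines the Gauss-Newton term with
the exact prediction curvature, without which the iteration oscillates
across the curved likelihood valleys that single-observation subjects
produce. Safeguards, each of which exists because its absence was observed
to fail:

- Levenberg-Marquardt damping, increased fourfold on any backtracked step
  and relaxed on clean steps;
- per-iteration step capped at one log-unit, because uncapped Newton steps
  can jump across likelihood barriers into a pathological
  "never-eliminated" basin (predictions ~0, astronomically bad but locally
  stationary);
- η bounded at ±10 log-units (beyond any sane conditional mode);
- a deterministic probe grid along the volume axis (±1.5, ±3 × ω_Vd) for
  subjects with ≤ 2 observations, with a fresh descent from any probe that
  beats the current mode — sparse subjects' conditional objectives are
  genuinely multimodal because one observation constrains only a curve in
  (η_CL, η_Vd) space;
- convergence at gradient ∞-norm < 1e-6 or a vanishing accepted move.

Modes are warm-started across objective evaluations during optimization.
Because a few single-sample subjects have near-tied secondary modes, the
warm-tracked objective is path-dependent by O(1) likelihood units; all
*reported* quantities (OFV, empirical-Bayes estimates, residuals) are
therefore recomputed by a cold-start evaluation at the final parameters,
which is reproducible from the parameters alone.

### Outer problem

Fixed effects constrained positive, and all variance-component standard
deviations, are estimated on the log scale. Optimization proceeds in two
stages: L-BFGS-B with numerical gradients (approach), then up to four
Nelder-Mead polish cycles (terminating when a cycle gains < 0.05 OFV
units). The polish stage exists because conditional-mode switches leave
small kinks in the surface on which finite-difference quasi-Newton steps
stall — and, near the optimum, wander. Up to three seeded perturbed
restarts run if the approach stage reports failure; the best point found is
returned, flagged. Standard errors come from the inverse finite-difference
Hessian of the OFV on the natural scale (covariance 2H⁻¹), reported as
100·SE/estimate; a non-positive-definite Hessian yields missing SEs with a
warning rather than fabricated values.

AIC = OFV + 2p and BIC = OFV + p·ln(n) count p as fixed effects plus
variance components and take n as the number of concentration records.

## Covariate selection

Continuous covariates enter as power terms centered at the cohort median,
categorical ones as exponential terms (one parameter each, df = 1).
Pairs with |Pearson r| > 0.5 are never in the model simultaneously.
Forward inclusion requires an OFV drop ≥ 3.84 (χ²₁ at 5%), backward
retention an OFV rise ≥ 6.63 (χ²₁ at 1%). Ties break toward the larger
drop, then lexicographic label; candidate fits are warm-started from the
parent model's estimates. Under null covariates the realized
false-inclusion rate of the 3.84 threshold is ~5-8% in the package's own
calibration test, consistent with the χ²₁ reference.

## Model validation

- **Bootstrap**: subjects resampled with replacement to the original count
  (records travel with their subject, no stratification), each replicate
  refitted warm-started; medians and 2.5/97.5 percentiles over converged
  replicates; bias% = 100·(bootstrap median − estimate)/estimate. A
  convergence fraction below 80% flags the result.
- **VPC**: concentrations simulated on the observed design; observed
  2.5/50/97.5 percentiles compared with the 95% interval of the same
  percentiles across replicates, on six equal-count bins of time after the
  last dose (opportunistic sampling makes fixed-width bins unstable); bins
  under 5 observations merge with a neighbor.
- **NPDE**: per subject, observed and simulated vectors are decorrelated by
  the Cholesky factor of the empirical simulation covariance; the rank of
  each decorrelated observation is inverse-normal transformed. Calibration
  is tested by Wilcoxon signed-rank (location), a two-sided χ² variance
  test, Shapiro-Wilk (normality), and a global Bonferroni combination
  (3 × min p, capped at 1) — the global combination is this package's
  choice, as is the χ² form of the variance test.

## Dose optimization

Virtual patients are sampled per stratum: KF fixed or uniform on the
stratum interval (the within-stratum distribution is this package's
choice), weight fixed or drawn from the cohort-like truncated lognormal,
η_CL ~ N(0, ω²_CL). Steady-state exposure uses the linear-kinetics identity
AUC₀₋₂₄ = daily dose / CL, which makes the result independent of volume
variability (enforced by test); a first-day trapezoidal alternative exists
behind a flag, and with a 1.5-h half-life the two differ by under 2%.
"Steady state" for profile-based metrics means ≥ 10 elimination half-lives
or 7 days, whichever is sooner. PTA is the fraction of patients with
AUC₀₋₂₄ ≥ 40 µg·h/mL; a regimen is acceptable at PTA ≥ 80%; the minimal
acceptable dose is searched on a 0.5 mg/kg/d grid from 5 to 40 with common
random numbers across doses (making PTA monotone in dose, so the minimal
attaining dose is well defined). The open-ended "above normal" KF stratum
is bounded at 129.13/120 ≈ 1.08, the cohort maximum. Monte Carlo dose
results agree with the closed-form lognormal-quantile solution
(dose* = 40·CL_typ·e^(z₀.₈ω)/WT) within one grid step.

## Synthetic cohorts

The generator emulates the study's published summaries, not its raw data:

- weight: truncated lognormal, median 12 kg, log-SD 0.55, range 2.5-55 kg
  (reproducing mean ≈ 13.7, SD ≈ 8);
- age: truncated lognormal, median 2.46 y, log-SD 0.66, range 0.10-12.83;
- height: growth-like power law on weight (90 cm at 12 kg, exponent 0.45)
  with 5% lognormal noise, clipped to 44-161 cm — making the weight-height
  correlation exceed the 0.5 screening threshold, so the correlation screen
  has a true positive to find;
- eGFR: deterministic allocation of the 12/80/11/0/1 renal-class mix
  (elevated/normal/mild/moderate/severe, scaled for other cohort sizes),
  uniform within class bands; serum creatinine back-calculated from eGFR
  and height with a bedside-Schwartz-style constant;
- sex: Bernoulli at the study's 54:50 ratio.

Dosing is 5 mg/kg q12h as 1-h infusions for 3-7 days. Sampling times are
uniform on (0.5 h after an infusion start, 12 h) on a random treatment day,
with per-subject counts in {1, 2, 3} allocated to hit the target total
(138 at n = 104) exactly. A candidate time is redrawn (bounded retries)
when the subject's *typical* (η-free) profile is below 3× the LLOQ there —
an acceptance rule on the realized concentration would make the design
informative about the random effects and was measured to bias the volume
estimate by 18-35%. Realized concentrations below the LLOQ are kept,
flagged, and handled by the censored likelihood. Truncated-lognormal
distribution families are a modeling choice; matching the published
mean/SD/median/range summaries is the fidelity criterion.

The packaged reference dataset uses a fixed seed (20210118) so that two
generations are bit-identical. The generator's core guarantee — fitting the
true model structure to 20 regenerated sparse replicates recovers all five
fixed effects with |median relative bias| < 10% — is enforced in the test
suite (measured medians: ~4% on clearance, ~2% on volume).

What the generator does **not** emulate: time-varying covariates or renal
function, drug accumulation under dose adjustments, correlated η_CL/η_Vd,
assay batch effects, the hepatic/hematological covariates of the real
record (BUN, bilirubin, transaminases — only their renal counterparts enter
the model), or any exposure-toxicity relationship. Passing tests therefore
demonstrate internal consistency of the estimation and simulation pipeline
under the stated hierarchy, not robustness to the messiness of real
critically-ill-patient data.

## Problem sizes in the shipped tests

Unit tests run on 15-40-subject cohorts; the end-to-end recovery check uses
the full 104-subject design with 20 replicates; Monte Carlo dose checks use
10,000 virtual patients per cell; bootstrap behavior is exercised at 10-15
replicates (the production default is 1,000); VPC/NPDE checks use 300-1,000
simulation replicates. These sizes are chosen so the whole suite completes
in a few minutes while every statistical assertion retains comfortable
margins over its Monte Carlo noise.

## Known limitations

- The estimation objective is a Laplace/FOCE-I approximation; with 1-3
  samples per subject, variance components (especially ω_CL and σ) carry
  substantial small-sample noise, and σ tends to absorb unexplained
  between-subject variability.
- The weight-exponent θ1 on volume is the least stable fixed effect under
  the sparse design (replicate spread ±25-40%), mirroring its large
  published standard error.
- A two-compartment structural alternative is deliberately out of scope;
  the model interface (typical-value callables on a Subject) does not
  preclude adding one.
- eGFR is consumed as an input; the pediatric estimating formula used
  upstream of it is not reimplemented (a pass-through calculator hook
  exists for users who want to plug one in).
- External (out-of-cohort) validation is not addressed.
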