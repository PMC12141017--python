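# Methods

## Scope and models

The package models a prospective trial of nafamostat mesylate given as a
continuous infusion (started at 15 mg/h, no bolus) into the ECMO drainage
limb of 24 intensive-care patients, with drug concentration sampled from
two sites — the patient's central venous catheter and the ECMO circuit —
and aPTT as the pharmacodynamic endpoint. Each sampling site is fitted as
its own self-contained two-compartment model; the two sites are never
linked mechanistically (the circuit "individual" and the systemic
"individual" get independent random effects), mirroring the way the two
datasets were analysed independently.

### Structural PK

Two-compartment, constant-rate infusion into the central compartment,
linear elimination. Parameters: CL (L/h), V1 (L), Q (L/h), V2 (L). The
analytic biexponential solution is used everywhere (estimation inner
loops, Monte Carlo); arbitrary piecewise-constant dosing is handled by
superposing one infusion term per rate step change. An adaptive ODE
integration of the mass-balance equations exists only as an independent
oracle in the test suite, which requires agreement to a relative 1e−6
over 1,000 random parameter sets.

Units: times in hours internally (input files may declare minutes),
rates in mg/h at the interface and μg/h internally, so concentrations are
natively μg/L with volumes in litres. Half-lives are reported in minutes.

Covariate model: gas flow rate (L/min) acts multiplicatively as
`exp(coef · (gasflow − 3.75))` — on V2 in the patient model
(coef −0.852) and on CL in the ECMO model (coef 0.0999). The centering
constant 3.75 L/min equals the population median gas flow and is stored
as data in the model fixtures, not hard-coded.

Secondary parameters follow from the micro constants: Vss = V1 + V2;
t½α = ln2/α, t½β = ln2/β. β is computed as (k10·k21)/α rather than
(s−√disc)/2 to avoid catastrophic cancellation when the roots are far
apart. Recomputing from the rounded published estimates gives a patient
t½α of ≈0.51 min whereas the source prints 0.54 min (presumably computed
from unrounded estimates); the package reports the recomputed value and
this discrepancy is deliberately not reconciled. The other three
half-lives (patient β 19.7 min, ECMO α 1.2 min, ECMO β 51.4 min) agree
with the printed values at their printed rounding.

### Structural PD

Indirect-response (turnover) model: aPTT produced at zero-order rate Kin
(s/h) and lost at first-order rate Kout (1/h), with the loss process
inhibited by drug via Imax·Cp/(IC50+Cp). Kout is the derived quantity
Kin/Base — the parameterisation estimates Kin and the baseline aPTT, not
Kout. The initial condition is the individual's (IIV-perturbed) baseline,
never the first observed value: predose observations are data.

The model implies a response ceiling Base/(1−Imax): with the ECMO-site
estimates (Base 33.0 s, Imax 0.436) the circuit aPTT can never exceed
≈58.5 s and the *typical* circuit subject sits below the 40 s lower
target bound at all plausible rates (36.7 s at 15 mg/h, 39.5 s at
30 mg/h). Simulated target attainment at the circuit is therefore
modest regardless of titration policy; only between-subject variability
puts individual subjects in range. This is a property of the published
parameter set, not of the implementation.

### Random effects and residual error

IIV is lognormal, θᵢ = θ·exp(ηᵢ), η ~ N(0, ω²), independent across
parameters (diagonal Ω — no correlations are reported). ω magnitudes are
reported as percent = 100·√ω²; ω fixed at 0 means no IIV on that
parameter. Imax draws use the same lognormal convention; the rare draw
pushing Imax above 1 is rejected and redrawn. Residual error is
proportional for concentrations (σ 28.7% patient, 30.9% ECMO) and
additive for aPTT (σ 2.83 s / 3.43 s); simulated observations that come
out negative are redrawn once and then floored at zero. σ = 0 is allowed
in simulation (the observation equals the prediction) but never offered
as a free parameter in estimation.

BLQ handling: concentrations below the 0.5 μg/L assay LLOQ are flagged
and discarded before estimation (M1 method). Under this design BLQ
records are essentially the predose samples.

## Estimation

The marginal likelihood is approximated subject-by-subject by a Laplace
expansion at the conditional mode η̂ with residual variance evaluated at
the conditional predictions (interaction). The objective is

    OFV = Σᵢ { Σⱼ [log v + r²/v] + η̂ᵀΩ⁻¹η̂ + log det Ω + log det Cᵢ },
    Cᵢ = GᵢᵀVᵢ⁻¹Gᵢ + Ω⁻¹,  Gᵢ = ∂fᵢ/∂η |η̂ (forward differences),

with n·log 2π dropped so that only ΔOFV between nested models is
interpretable. The test suite restores the constants and checks the
approximation against adaptive quadrature on one-η problems across
ω ∈ {0.1, 0.3, 0.6} (agreement within 0.5, and within 0.1 on a mild toy).

Numerical organisation: the inner MAP problems of *all* subjects are
solved simultaneously by a damped Gauss-Newton iteration vectorised over
subjects (the Hessian approximation 2GᵀV⁻¹G + 2Ω⁻¹ is positive definite,
so the damped step always descends), warm-started across outer
iterations. The inner iteration stops when the largest gradient component
falls below an absolute threshold (1e−3 by default, 1e−2 in the reduced
"fast" budget); the induced OFV error is quadratic in that threshold and
negligible against the outer tolerances. The outer problem is minimised
by Nelder-Mead on transformed parameters — log for positive parameters
(structural, ω², σ), logit for Imax, identity for covariate coefficients.
Standard errors come from the central finite-difference Hessian of OFV/2
at the optimum; ω² standard errors are reported with the SD-scale
convention RSE% = 100·SE(ω²)/ω²/2.

Sequential PK→PD fitting uses the IPP approach: each subject's PK
parameters are frozen at their EBE-implied individual values (covariate-
adjusted typical values × exp(η̂), or ground-truth individual values in
recovery experiments) and only PD parameters are estimated from the aPTT
records. Because the PK side is frozen, each subject's concentration
time-course is precomputed once per fit.

PD integration inside estimation and Monte Carlo uses an
exponential-midpoint scheme on a fixed non-uniform grid (dense over the
distribution phase): the turnover equation is linear in aPTT given Cp(t),
so freezing the loss rate at its per-step midpoint gives the exact update
for that step; the scheme is unconditionally stable and second-order. The
user-facing `integrate_pkpd` integrates the same equation with an
adaptive solver at rtol 1e−8 with the concentration evaluated exactly
(never interpolated) and serves as the accuracy reference; the fast path
agrees with it to ≲5e−4 relative on the simulation grids used.

Model selection: ΔOFV against chi-square quantiles (3.84 df1/p0.05,
5.99 df2/p0.05, 6.63 df1/p0.01, 10.8 df1/p0.001). Covariate search does
stepwise forward selection at p<0.01 and backward elimination at p<0.001,
with covariates entering as exp(coef·(cov − dataset median)). The
bootstrap resamples subjects with replacement (no stratification), refits
each replicate warm-started at the point estimates, and reports medians
and percentile 95% CIs over converged replicates.

## Synthetic-trial generator

The generator emulates the trial design: 24 subjects; PK samples predose
and at 3, 6, 30, 120, 300, 480 min from both sites; aPTT at predose, 240
and 480 min; infusion started at 15 mg/h. Gas flow rate is drawn from a
lognormal matched to the reported mean 4.31 / SD 2.39 L/min truncated to
[0.5, 12] (implied median ≈3.77 against the reported 3.75); ECMO type is
VA with probability 13/24; the remaining covariates are drawn from the
reported summaries and carry no effects — they exist as candidate
covariates for the search machinery. A per-sample dropout probability
(default 0.04) reproduces the reported attrition from 168 planned to
≈162 analysed concentration records per site; the identity of the lost
records is unknowable, so dropout is random. The titration policy
(±5 mg/h at the 240-min aPTT draw keyed on the ECMO-circuit value, floor
5 mg/h, target 40–80 s) is an invented stand-in — the trial reports that
titration occurred but not its rule — and is labelled synthetic-only.
The generator returns the full ground truth (ηs, individual parameters,
dose segments) so recovery experiments can condition on it and any run
can be replayed exactly from its seed.

What passing tests on generated data do *not* show: the generator has no
model misspecification, no circuit–patient coupling, no drug
discontinuation errors (the trial retained some records documented as
post-discontinuation), and no extra clinical aPTT draws beyond the
planned schedule. Recovery and calibration results therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to the ways real ICU data deviate from it.

## Problem sizes and experiment design

Replicate experiments use these sizes as the package's standing choices:
20 seeded 24-subject studies for parameter recovery (CL judged against
the published bootstrap 95% CIs: 137–242 L/h patient, 73.1–98.9 L/h
ECMO; Imax within ±0.15, consistent with its 21.8% RSE); CWRES
calibration on ≥500 observations (90 subjects); pcVPC self-consistency
with 200 replicates; bootstrap consistency with 200 replicates (the
trial's own analysis used 2,000 — the CLI default); covariate-search
operating characteristics at n=100 subjects with 10 replicates per arm.
Replicate fits run a reduced optimiser budget (Nelder-Mead ≤300
evaluations, inner gradient threshold 1e−2, no standard errors)
warm-started from the published values or the point fit, which the
stability and nesting tests show is adequate at these designs.

## Known limitations and open points

- Conditional estimation shows the expected finite-sample biases at this
  design when IIV is very large and fixed: under the ECMO fixture
  (ω_V1 62.8% and ω_Q 134%, both fixed) the typical V1 recovers with a
  ~+24% median bias even at 100 subjects with dense sampling, and the
  10-replicate median bias of Q straddles 10%; removing those two IIV
  terms brings all four structural parameters within ~6%. CWRES likewise
  carries a small systematic negative mean (~−0.06) from the first-order
  linearisation with proportional error. Both are properties of the
  estimation problem, measured and tested, not removed.

- The published simulation figure reports median steady-state
  concentrations of ≈88 μg/L (patient) and ≈600 μg/L (ECMO) at 30 mg/h,
  but rate/CL from the published clearances gives 158.7 and 352 μg/L;
  each printed aPTT median (39 s / 43 s) is consistent with a different
  one of these concentration scales. The settings producing 88/600 are
  not recoverable from the published material. This package reports the
  internally consistent values; of the simulation medians, only the
  patient-side aPTT (39 s) is treated as a reproduction target.
- Absolute OFV values from the original analysis are not published, so
  only ΔOFV behaviour and recovery properties are checkable.
- Whether ω_Kin in the ECMO PD model (75.8%) was estimated or fixed is
  ambiguous in the source table; the fixture treats it as estimated.
- No SAEM or full-Laplace alternatives, no Ω correlations, no
  inter-occasion variability, no bolus dosing or absorption models, and
  no effect-compartment PD alternative beyond OFV comparison hooks.
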