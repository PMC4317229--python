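# Methods

## Structural model

Drug disposition is described by a two-compartment model with first-order
subcutaneous absorption and target-mediated drug disposition (TMDD): the
antibody binds the α4β7 integrin on circulating T cells with very high
affinity (K_d in the tens of pmol/L), and the drug–receptor complex is
internalized. At high concentration the receptor pool is saturated and
elimination is dominated by the linear clearance CL; at low concentration
(below roughly 1 µg/mL ≈ 7 nmol/L for a 144 kDa IgG) the target-mediated
route dominates and kinetics become strongly nonlinear.

The default variant is the quasi-equilibrium (QE) approximation with a
constant total receptor pool. States are the depot amount A (nmol), the
total central concentration C_tot (nmol/L) and the peripheral amount
A_T (nmol):

    dA/dt     = −K_A · A
    dC_tot/dt = K_A·F1·A/V_c − (CL/V_c)·C_f − K12·C_f + K21·A_T/V_c
                − K_int·(C_tot − C_f)
    dA_T/dt   = K12·C_f·V_c − K21·A_T

with the free concentration C_f the positive root of the binding
quadratic C_f² + (R_tot + K_d − C_tot)·C_f − K_d·C_tot = 0. The root is
evaluated in a cancellation-free form on both branches. Free drug drives
the linear clearance and the peripheral exchange; complex internalization
removes the bound fraction at rate K_int·(C_tot − C_f). Holding R_tot
constant is equivalent to receptor turnover with k_deg = K_int and
k_syn = K_int·R_tot; a full kinetic variant (explicit k_on/k_off, receptor
synthesis and degradation) is implemented and used as a convergence oracle
— at fixed K_d = k_off/k_on its trajectories approach the QE solution as
k_on → ∞. The quasi-steady-state (QSS) approximation is the same code path
with K_ss in place of K_d. A two-compartment model with parallel linear
and Michaelis–Menten elimination is provided as the empirical comparator,
and R_tot = 0 gives the plain linear model.

The *observed* (reported) concentration is the free concentration C_f,
matching what a free-analyte immunoassay measures and what the exposure
predictions require; at an IV bolus the peak free concentration is
Dose/V_c minus the receptor-bound mass.

## Parameters

Typical cynomolgus values shipped with the package (units as used
internally: nmol/L, days, mL):

| parameter | value | meaning |
|---|---|---|
| K_A | 0.846 /day | first-order SC absorption |
| CL | 12.9 mL/day | linear clearance |
| V_c | 116 mL | central volume |
| K12, K21 | 0.617, 0.877 /day | distribution rate constants |
| K_d | 0.013 nmol/L (fixed) | in vitro binding EC50, monkey T cells |
| R_tot | 9.18 nmol/L | total receptor concentration |
| K_int | 0.0215 /day | complex internalization (t½ ≈ 32 d) |
| F1 | 1.0 (fixed) | SC bioavailability |

Between-animal variability (lognormal, CV scale): CL 44.1%, V_c 46.1%,
R_tot 180%, with corr(ln CL, ln V_c) = 0.642. Residual error is
proportional (20.1% CV) plus additive (1.11 nmol/L).

The human set scales CL, V_c, K12 and K21 allometrically on the 70/2.8 kg
weight ratio (exponents 0.75, 1, −0.25, −0.25) and keeps K_A, F1, R_tot
and K_int species-invariant. The human K_d is a genuinely open choice: the
in vitro binding potency against *human* primary T cells is 0.031 nmol/L
while the monkey value is 0.013 nmol/L. The package defaults to
0.031 nmol/L for human prediction — a check of the low-dose exposure
arithmetic shows the 0.7 mg SC AUC (~0.99 µg·h/mL) and Cmax
(~0.0009 µg/mL) are only consistent with that choice — and exposes the
alternative through `translate.kd_sensitivity`, since at doses far below
target saturation the predicted free-drug AUC is roughly proportional to
K_d. At clinically relevant doses (≥ 7 mg) the choice is immaterial.

## Simulation

Dose events are handled by integration restarts (LSODA, rtol 1e−8,
atol 1e−10 nmol/L): IV boluses increment the central concentration,
SC doses the depot. Output grids are dense (20 points/day in the first
week, 2/day after, refined after each dose) plus all requested
observation times. Single-dose human runs default to an 18-month horizon
so that crossings of the lowest occupancy thresholds are captured;
"months" of coverage use 30.4375 days/month. AUC is trapezoidal on the
dense grid (day-based, reported ×24 in µg·h/mL); AUC to infinity extends
the last point using a log-linear fit over the terminal tail (last 10% of
the simulated span or the last five positive points, whichever is
longer). A batched solver stacks individuals sharing a dose/observation
schedule into one ODE system, which makes population simulation and
estimation tractable on a single CPU.

## Synthetic monkey program

The generator reproduces the structure of a five-study preclinical
program: two single-dose PK/PD studies (0.01–9 mg/kg, IV and SC), a
two-dose and two GLP repeat-dose toxicology studies (0.5–80 mg/kg SC/IV,
weekly dosing up to 24 doses), 119 treated animals (73 male, 46 female),
body weights lognormal around 2.8 kg truncated to the observed 2.1–6.4 kg
range. The true per-study sampling schedules are not public; the packaged
schedules are stand-ins (dense first-dose sampling, trough sampling
during repeated dosing, a washout tail) calibrated once to give ~1,730
observations in total. Assay censoring uses the study-specific LLOQ
(2 ng/mL for the PK/PD and non-GLP studies, 20 ng/mL for the GLP studies),
with the strictly-below rule; censored rows are dropped from the
modelling view (M1 handling) since no likelihood treatment of
below-limit data is attempted.

ADA contamination is empirical, not mechanistic: a dose-dependent
fraction of animals (0.8 below 5 mg/kg, 0.5 at 5–20 mg/kg, none at
80 mg/kg) switches to an elevated linear clearance at an onset time drawn
uniformly on days 14–28. The clearance multiplier defaults to 2.2: with
the packaged designs this reproduces an excluded-data fraction of ~5–9%
under the two-step exclusion filter (ADA positivity, then observed value
more than 3-fold below the model expectation — a reproducible surrogate
for visual curation). Notably the excluded fraction is not monotone in
the multiplier: stronger ADA pushes post-onset points below the GLP LLOQ,
where they leave the excludable pool as censored rows.

What the generator does *not* emulate: assay batch effects, time-varying
ADA titres, immune-complex reservoirs, covariate effects (sex, study) and
target-expression differences — so passing recovery tests demonstrate
internal consistency of the estimation machinery under the assumed
variability structure, not robustness to real-data pathologies.

## Estimation

Typical values are estimated by naive-pooled maximum likelihood: all
quantifiable, non-excluded observations enter a normal likelihood with
proportional + additive variance, structural parameters are estimated on
the log scale (box constraints ±12 log units, L-BFGS-B), K_d is fixed by
default and F1 always. Standard errors come from the inverse observed
information via central finite differences when requested. During fitting
the ODE tolerances are relaxed to rtol 1e−6 / atol 1e−8.

Between-animal variability is estimated by an iterated two-stage scheme.
Each sweep (i) computes per-individual MAP etas under the current Omega
prior by damped Newton iterations whose finite-difference gradients and
Hessians are evaluated with batched ODE solves (the penalized objective
is separable across individuals, so one dataset pass perturbs every
individual's eta simultaneously); (ii) applies the EM-type update
Omega ← mean(η̂η̂ᵀ + H⁻¹), H being the Hessian of each individual's
penalized objective — the Laplace-type conditional approximation, whose
H⁻¹ term restores the variance removed by shrinkage (individuals whose
data carry no information on an eta contribute their prior variance);
and (iii) re-estimates the typical values and residual sigmas
conditional on the etas. Step (iii) matters: naive pooling under strongly
skewed lognormal variability absorbs the between-animal spread into the
proportional error and biases the conditional etas, and one conditional
theta refit removes most of that bias in the eta-bearing parameters.
This is deliberately simpler than a full marginal-likelihood (FOCE-like)
estimator: the scientific claims live in the recovered estimates, and on
the synthetic program the scheme recovers the typical CL and V_c and the
CL/V_c variability within the tolerances exercised by the test suite.
Remaining caveats: weakly identified parameters (R_tot under 180% CV)
can drift toward a flat likelihood valley in the pooled stage and are
not reliably restored by the refit, so the R_tot point estimate from
this pipeline should not be over-interpreted — mirroring the general
identifiability caveat that R_tot and K_d cannot be estimated
simultaneously from these designs.

The PD model is the inhibitory Emax form E = E₀(1 − E_max·C/(EC₅₀+C)) —
free-receptor fluorescence decreases with drug, and the maximal effect is
a fraction of baseline — fit by least squares; occupancy thresholds use
ECp = EC₅₀·p/(100−p).

## Dose selection arithmetic

Safety margins divide the monkey NOAEL exposures at 80 mg/kg (Cmax
4850 µg/mL, AUC 485,000 µg·h/mL) by the predicted human exposures; raw
ratios are retained alongside 3-significant-figure roundings. The FDA
maximum recommended starting dose is provided both via body-surface-area
exponent scaling (NOAEL·(BW_a/BW_h)^(1−0.67)/10 → 2.98 mg/kg for 3 vs
60 kg) and via the standard Km factors (80·12/37/10 → 2.59 mg/kg); the
two bracket the conventional value and neither is forced to match any
particular rounding. Multiple-dose exposure uses the AUC within the third
dosing interval of a Q4W×3 schedule. The MABEL flag marks candidate doses
whose predicted Cmax stays at or below the EC10 of receptor occupancy.

## Numerical and test-scale choices

* Binding quadratic: evaluated branch-stably; property-tested to satisfy
  its defining polynomial to 1e−10 relative.
* Terminal-slope fits require at least three positive concentrations; a
  non-positive terminal slope raises an explicit infinite-AUC error.
* Exposure-margin division by a zero prediction returns an infinite
  margin flag rather than raising.
* Test problem sizes: the parameter-recovery test uses the full synthetic
  program (119 animals, one fixed seed) with the pooled stage capped at
  60 optimizer iterations and the mixed stage at 2 sweeps on (CL, V_c);
  the VPC check uses 400 replicates of the single-dose PK/PD design. The
  exclusion-fraction calibration is checked as a mean over a handful of
  seeds.
* All generator randomness flows from one integer seed through a single
  `numpy` Generator; datasets are bit-reproducible given (designs, seed).

## Limitations

* No mechanistic ADA or immune-complex model; the clearance-switch model
  cannot reproduce transient or titre-dependent effects.
* No covariates, no urinary/biliary partitioning, no infusion dosing.
* The mixed-effects stage conditions on pooled typical values rather than
  jointly maximizing a marginal likelihood; omega estimates for very
  large variabilities (R_tot) carry the sampling and shrinkage caveats
  discussed above.
* Human predictions inherit the species-invariance assumptions for K_A,
  F1, R_tot and K_int; the K_d ambiguity is surfaced rather than
  resolved.
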