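# Methods

## Structural and statistical model

Maternal disposition is a one-compartment model with first-order
absorption, parameterised by the apparent oral quantities Ka (1/h),
CL/F (L/h) and Vc/F (L). Bioavailability is not identifiable from
oral-only data, so no explicit F parameter exists; all clearances and
volumes are apparent. Breast milk is an effect compartment:
`dCmilk/dt = Kcb (Rcb·Cplasma − Cmilk)`. This is the only dimensional
reading under which the milk state is a concentration, no mass is
removed from plasma, and Rcb is exactly the steady-state AUC ratio
milk:plasma — the package asserts that identity to 1e-6 in its tests.

All within-study dosing is treated as at steady state (the earliest
sample in the emulated design is taken at day 7 postpartum, far beyond
five half-lives of ~6.6 h). Steady state is computed by analytic
superposition: every term `c·exp(−λt)` of the single-dose solution is
scaled by `1/(1−exp(−λτ))`. An ODE integrator over an explicit dose
train exists purely as an independent oracle; the closed forms agree
with it to 1e-6 relative on log-uniform parameter draws spanning a
decade around the typical values.

Coincident rate constants (Ka = ke, Kcb = ke, Kcb = Ka) are removable
singularities of the closed form; the implementation perturbs the
coinciding rate by 1e-8 relative rather than branching to L'Hôpital
limits. The accuracy cost is ~1e-7 relative, verified against the ODE
oracle.

Between-subject variability is exponential (log-normal) on CL, Vc and
Rcb; Ka and Kcb carry none (the absorption data are too sparse to
support it — 21 of 35 mothers have no absorption-phase samples — and
equilibration-rate variability is not estimable from the design). The
CL–Vc covariance is free; Rcb's random effect is independent. IIV is
reported as 100·sqrt(omega_kk) %CV. For the generator's default
CL–Vc dependence a correlation of 0.42 is used; reading the published
"42% CV" as 100·sqrt(cov) would imply a correlation above 1 and is
therefore rejected. Residual error is proportional with separate
plasma and milk magnitudes; the residual SD is floored at 1e-6 mg/L so
likelihoods stay finite near zero predictions. Units are mg, L, h and
mg/L internally; ng/mL appears only at the I/O boundary (×1000).

## Estimation

The objective is OFV = −2 log of the Laplace-approximated marginal
likelihood, including the full Gaussian constant (only differences
between nested fits are meaningful). Per subject, the conditional mode
of the random effects is found by a vectorised damped Gauss–Newton
search using the analytic gradient and the PSD first-order (FOCE-I
information) Hessian of the joint −2·log-density; the exact
finite-difference Hessian at the mode supplies the Laplace determinant.
Interaction is inherent: the residual SD is evaluated at the
η-dependent prediction.

The joint density can be multimodal in η for subjects with sparse or
discordant records. The inner search therefore always starts at the
prior mean (making the profiled objective a deterministic function of
the population parameters — a warm start across outer iterations would
make it history-dependent and derail line searches) and then probes a
fixed stencil of η offsets (±1.5, ±3 per coordinate), re-descending
wherever a probe beats the found mode. This approximates the
global-mode Laplace objective and removes spurious value cliffs that
otherwise stall the outer optimizer.

Outer optimisation runs on transformed parameters (log for θ and σ,
log-Cholesky for the CL–Vc block) with L-BFGS-B using central-difference
gradients, a Powell direction-set rescue whenever the returned point has
a clearly nonzero gradient (the objective retains kinks where the inner
mode switches basins), and a final polish; convergence is declared when
the maximum gradient component is below 1 OFV unit per unit of
transformed parameter. Standard errors come from the central
finite-difference Hessian of the OFV (covariance = 2·H⁻¹) with a
delta-method map to the natural scale; a non-positive-definite Hessian
withholds SEs with an explanatory status. Finite-difference helpers are
implemented in-package.

BLQ records are excluded from the likelihood by default (M1); an M3
option adds the censored contribution Φ((LLOQ−f)/sd) per BLQ record
(implemented analytically in the mode search as well — the censored
normal log-likelihood is concave in the prediction). Infant summaries
always impute LLOQ/2, matching field practice for descriptive
statistics.

Model building follows the conventional thresholds: likelihood-ratio
test significance at ΔOFV ≥ 3.84 (df 1, α = 0.05) quoted at the
conventional two decimals, so a drop of exactly 3.84 counts; stepwise
covariate modelling uses forward inclusion at 3.84 and backward
elimination retaining a covariate only if its removal costs ≥ 6.63
(α = 0.01). Candidate relations are linear, exponential or power,
centred on the dataset median. The nonparametric bootstrap resamples
whole subjects with replacement (default n = 1000) and reports
percentile intervals; failed fits are excluded and counted, with a
warning above 20%.

## Synthetic-study generator

The generator emulates the study design: 35 mothers (10 on 150 mg q12h,
25 on 300 mg q24h), 14 morning dosers sampled at 0/1/2/4/8 h (plasma)
and 0/2/4/8 h (milk), 21 evening dosers (necessarily q24h — their
sampling times of 12/16/20 h exceed a 12-h interval) sampled in both
matrices, two visits per mother in windows of day 7–43 and 36–84
postpartum, LLOQ censoring at 5 (plasma) and 16.6 ng/mL (milk), and a
7% uniform missingness rate chosen to match the observed ~248 of 266
scheduled plasma records. Evening dose times are exact by default, with
an optional ±30-min jitter knob for stress testing.

Covariates are drawn independently per mother by pushing a Beta(2,2)
variate through a piecewise-linear quantile map onto
[low, median] / [median, high] of the published cohort summaries; this
reproduces each printed median and range exactly (the medians are not
range midpoints, so a plain scaled Beta cannot). This is a documented
stand-in for the unknown joint covariate distribution: it carries no
correlation between covariates and no covariate–parameter relations, so
passing recovery tests demonstrate estimator correctness under the
design, not robustness to real-world covariate structure.

Infant concentrations are simulated as a constant individual steady
state from the forward exposure chain with 30% proportional noise,
reflecting the near-flat infant profiles the design can support; no
feed-by-feed kinetics are attempted (feeding times and volumes are
unobservable in this setting).

## Infant exposure

ConcAve = daily dose/(CL·24) (exactly AUC0–24/24 at steady state, and
independent of Ka and Vc); ConcMilk = Rcb·ConcAve;
Dose_infant = ConcMilk · 0.15 L/kg/day; RID% compares with the maternal
weight-normalised dose; infant CL/F uses allometric weight scaling
(exponent 0.75, 7-kg reference) and sigmoidal maturation (TM50 0.25
years, Hill 1.47), with postnatal age converted at 365.25 days/year;
Css = Dose/(CL·24 h). The "% of recommended dose" reference is
8 mg/kg/day (4 mg/kg twice daily, infants ≥ 4 weeks); the neonatal
4 mg/kg/day reference is selectable. Cohort summaries are computed per
mother–infant pair from empirical Bayes estimates and then summarised —
never from typical values.

## Diagnostics

CWRES uses the FOCE linearisation at the empirical Bayes mode
(marginal mean f(η̂) − J η̂, covariance JΩJᵀ + diag(sd²) with sd at the
conditional prediction); subjects with a singular covariance are
flagged and excluded from summaries. The pcVPC corrects each record by
(bin-median population prediction / record population prediction), bins
at 0–1–3–6–10–14–18–24 h (matching the nominal sampling times; empty
bins are merged with a neighbour and logged), and draws 90% confidence
bands of the 5th/50th/95th percentiles from simulated replicates
(default n_sim = 500). Plasma and milk are evaluated separately.

## Problem sizes and replication choices

Simulation-based checks run at sizes chosen to keep the full suite
practical on a single core: parameter-recovery uses 5 seeded
simulate-and-refit replicates of the full 35-mother design with initial
estimates drawn log-uniformly within ×[0.5, 2] of the generating values
(a basin-robustness demonstration, not a warm start); the
stepwise-covariate type-I check uses 50 replicates of a reduced
8-mother, plasma-only, one-visit design; VPC self-calibration uses 200
simulated studies; the bootstrap demonstration uses small resample
counts (the production default stays n = 1000). The acceptance script
reports medians over 7 replicate fits.

## Known limitations

- Recovery of the typical Vc is intrinsically noisy: with 76.4% CV
  between-subject variability, the typical-value estimate at n = 35 has
  a sampling SD of at least 0.764/√35 ≈ 13% even with perfect
  individual-level knowledge. Replicate-level Vc errors of ±20% are
  expected and observed; the replicate median is stable.
- The Laplace approximation is not bit-compatible with any specific
  NONMEM configuration; OFV values are internally consistent but not
  directly comparable across implementations.
- The generator's covariate model is marginal (no joint structure), so
  covariate-selection operating characteristics on synthetic data need
  not transfer to the real cohort.
- Evening-group self-reported dosing-time error is off by default; the
  jitter knob only uniformly shifts a visit's times within the interval.
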