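# Methods

This note documents the models, algorithms and numerical choices behind
`meropk`, in the spirit of a statistical-methods appendix: what is computed,
under which assumptions, and where the implementation had to make choices the
problem statement leaves open.

## Structural model

Meropenem disposition is described by a linear mammillary two-compartment
model with zero-order (constant-rate) IV infusion input:

    dA1/dt = in(t) − (k10 + k12)·A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2,            C(t) = A1/Vc

with micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp. All concentrations
are mg/L, times hours, volumes L, clearances L/h. The hybrid rate constants
α > β > 0 satisfy α+β = k10+k12+k21 and α·β = k10·k21; derived quantities are
t½α = ln2/α, t½β = ln2/β and Vss = Vc + Vp.

Everything is evaluated **analytically** through the eigen-decomposition:
single-dose concentrations as a two-exponential convolution of the infusion,
multiple dosing by superposition, and steady state by the geometric
accumulation factor e^{−λτ}/(1−e^{−λτ}) applied per eigen-term. Numerical ODE
integration exists only as an independent oracle in the test suite (stiff
LSODA at rtol 1e-10, with a mass-balance check at 1e-8). The analytic route
is exact, which removes any convergence-tolerance ambiguity from "steady
state" and makes 1000-subject Monte Carlo runs take milliseconds.

Parameter sets whose hybrid constants coincide (|α−β|/α < 1e-12) are rejected
at construction: the repeated-eigenvalue branch is unreachable for
physiological values and rejecting it avoids a separate limiting form.

## Population model

Fixed effects follow the final covariate model for adults on ECMO:

    CL = θ1·(1 + θ2·(CRCL − 49.7))    Vc = θ3·(1 + θ4·(LPM − 3.7))

with Q and Vp covariate-free. Defaults are the published estimates
(θ1 = 7.35 L/h, θ2 = 0.0104 per ml/min, θ3 = 17.3 L, θ4 = 0.337 per L/min,
Q = 14.5 L/h, Vp = 12.8 L). The centering constants 49.7 ml/min and
3.7 L/min are model *data*, not hard-coded: fits re-center internally on the
dataset medians (an exact reparameterisation, see below) and report on
whatever reference the caller requests.

Between-subject variability is log-normal, P_i = P_typ·exp(η_P), with
independent η on CL, Vc and Vp (no ω is reported for Q, so Q carries no
random effect; the η covariance is diagonal because no correlations are
reported). ω values are log-scale SDs; the "%" display convention is 100·ω
(39.6% ↔ ω = 0.396), not 100·sqrt(exp(ω²)−1).

Residual error is combined additive + proportional,
y = ipred·(1+ε_prop) + ε_add, with σ_add = 0.370 mg/L and σ_prop = 0.0473.

The linear covariate model extrapolates to non-physiological values — Vc
crosses zero at an ECMO flow of 0.733 L/min — so covariates outside the
admissible region raise a hard error rather than being clipped: silent
clipping would bias downstream simulations toward the boundary.

## Synthetic cohort generator

The generator reproduces the study design: 30 subjects (10 on continuous
renal replacement therapy), one 1000 mg dose infused over 3 h (one subject
receives 500 mg), and seven samples per subject on one of three fixed
schemes (predose, 3.33, 3.67, 4 h, plus three scheme-specific later times up
to 14 h), assigned cyclically for reproducibility. Covariates are drawn from
independent log-normal marginals parameterised by the reported medians and
interquartile ranges, separately for the CRRT and non-CRRT strata (CRCL
medians 43.4 / 69.6 ml/min; flow medians 3.83 / 3.62 L/min); log-normal
quartiles are symmetric about the median on the log scale, so the median is
matched exactly and the IQR through its ratio. Flow draws below 0.8 L/min
are resampled to stay inside the admissible region. Demographics (age,
weight, height, sex, serum creatinine) are carried for covariate-search
exercises; serum creatinine is back-solved from the Cockcroft–Gault formula
so the demographic fields are mutually consistent.

Observations below the 1 mg/L assay quantitation limit are flagged
(`BLQ = 1`) but retained by default; a switch censors them instead. Negative
simulated concentrations are truncated at zero. Predose samples are recorded
as exactly zero — there is no drug on board in a single-dose design.

What the generator does **not** emulate: assay drift, sampling-time
deviations, a mechanistic CRRT elimination pathway (the analysis found no
CRRT effect), or any dependence between covariates beyond the CRRT
stratification. Passing tests therefore demonstrate correctness of the
machinery under the stated design, not robustness to real-data artifacts.

## FOCE-I estimation

The marginal likelihood is approximated by first-order conditional
estimation with interaction. Per subject, the inner problem minimises the
conditional objective

    q(η) = Σ_j [(y_j − f_j(η))²/R_j(η) + log R_j(η)] + η'Ω⁻¹η,

with R_j = σ_add² + (σ_prop·f_j)² evaluated at the *individual* predictions
(the interaction term). At the mode η̂ the model is linearised
(G = ∂f/∂η) and the subject contributes

    OFV_i = n_i·log 2π + log|C_i| + r_i'C_i⁻¹r_i,
    C_i = G Ω G' + R(η̂),  r_i = y − f(η̂) + G η̂.

The 2π terms are included, so the additive constant differs from NONMEM's
convention; all model comparisons are internal differences, where the
constant cancels. Predose rows (prediction identically zero) are excluded
from the likelihood: the synthetic design records them as exact zeros, and
exact-zero residuals would make the additive-error likelihood unbounded as
σ_add → 0. Rows with MDV = 1 are ignored; BLQ rows are used by default and
dropped when censoring is on.

**Inner optimisation.** A damped Newton iteration runs for all subjects
simultaneously on stacked arrays: central-difference Jacobians (evaluated in
one vectorised kernel call for all perturbations), the full curvature of q
in the predictions (interaction terms included, floored at a fraction of the
Gauss–Newton value to stay positive definite), a trust region of 2 eta
units, and a backtracking line search. Subjects are accepted when the
gradient target (1e-8) or a negligible undamped Newton step is reached; the
few subjects the batched phase leaves short of their mode — typically those
with near-quantitation-limit tails, where q bends into a curved valley — are
polished individually by a small damped-Newton routine with exact
gradients-given-Jacobian. Final acceptance is by the undamped-Newton-step
estimate of the remaining mode error (a raw gradient norm is
scale-dependent and sits on the finite-difference noise floor for
high-concentration subjects).

**Outer optimisation.** L-BFGS-B on transformed parameters: logs for the
positive parameters (typical values, ωs, σs), natural scale for covariate
slopes, which are additionally scaled by the covariate SD and boxed inside
the admissibility interval (1 + slope·(x − ref) > 0 over the observed
covariate range) so line searches never cross into the penalised region.
Covariate effects are re-centered internally at the cohort medians — an
exact reparameterisation that decorrelates base typical values from slopes —
and transformed back on report. The inner mode search starts from
per-subject etas frozen for the duration of each outer iteration and
refreshed in the optimiser callback: the conditional objective can be
multimodal for sparse subjects, and a start that varied call-by-call would
make the objective path-dependent, poisoning finite-difference gradients.
Reported objective values are always recomputed with a cold (η = 0) start so
that OFVs from different fits are comparable. The default iteration cap is
60 outer iterations; an "abnormal" line-search exit at the FD noise floor
still counts as converged when the remaining gradient is small.

Standard errors come from the inverse finite-difference Hessian of the OFV
on the natural scale (covariance 2·H⁻¹ since OFV = −2 log L); a singular
Hessian reports RSEs as unavailable rather than failing the fit.
Eta-shrinkage is 100·(1 − SD(EBE)/ω), clipped to [0, 100].

**Covariate search.** Stepwise forward selection (ΔOFV ≥ 6.63, p < 0.01,
1 df) and backward elimination (retention requires ΔOFV > 10.8, p < 0.001).
Each forward round first scores every remaining candidate by optimising its
slope alone with all other parameters fixed — a cheap lower bound on the
refit improvement — and then confirms only the top-ranked candidate with a
full refit against the threshold. Fits inside the search are cached by model
structure and capped at 40 outer iterations. Ties break by candidate order.

**Bootstrap.** Nonparametric: subjects resampled with replacement, each
replicate refit warm-started at the point estimates, percentiles 2.5/50/97.5
over converged replicates, with the non-convergence rate reported.

## Diagnostics

CWRES follow the FOCE linearisation: CWRES = L⁻¹(y − f(η̂) + Gη̂) with
C = GΩG' + R = LL'. Under a correct model they are approximately standard
normal, which the suite checks on simulated data.

The pcVPC simulates replicate datasets under the original design, bins by
nominal sampling time (the design has ≤ 10 distinct nominal times, so
data-driven binning is unnecessary), and corrects both observed and
simulated values within each bin:

    pcY  = Y · PRED_bin / PRED          (prediction correction)
    pvcY = PRED_bin + (pcY − PRED_bin) · W_bin / W   (variability correction)

where PRED_bin and W_bin are bin medians of the population prediction and of
the approximate marginal SD W = sqrt((G₀ΩG₀' + R)_jj) at η = 0. Predose bins
(PRED = 0) are left uncorrected. The "80% prediction interval" is the
10th–90th percentile band of the pooled corrected simulations per bin; the
summary statistic is the fraction of corrected observations inside it,
expected near 0.8 (slightly above, because the predose zeros are always
inside).

## PTA simulation

Virtual patients get a CRCL drawn uniformly within the renal-function group
(groups are half-open intervals (low, high]), the ECMO flow fixed at
3.7 L/min unless the flow itself is being varied, typical parameters from
the covariate model, and log-normal BSV on CL, Vc and Vp. No residual
(assay) error is applied: the targets concern true free concentrations.
Profiles are the analytic steady-state solution on a one-minute grid; the
free fraction is 0.98 (configurable). fT>MIC is the fraction of one dosing
interval with free concentration above MIC (or 4×MIC), with crossing times
refined by linear interpolation between grid points (error well below
0.1 percentage points); by periodicity this equals the 24-hour fraction for
q8h/q12h/q24h regimens. 100%-of-interval targets are evaluated exactly as
"free trough above threshold". Regimen grids reuse one set of random draws
per renal group (common random numbers), so contrasts between regimens,
MICs and flows are paired. PTA ≥ 90% marks a regimen optimal.

The MIC frequency distribution for the renal-policy simulation is external
user-supplied data (two-column CSV); the package ships no susceptibility
histogram.

## Problem sizes in the test suite

The simulation experiments run at the study design (30 subjects × 7
samples) over 20 seeds for parameter recovery and covariate-selection
operating characteristics; the likelihood-ratio power check reuses the same
runs. Scaled-down versions are used where the full published sizes are
simulation conveniences rather than design quantities: bootstrap checks use
tens rather than 2000 replicates, the type-I-error experiment uses 8 null
cohorts of 12 subjects, PTA claims use n = 1000 virtual subjects over three
seeds (Monte-Carlo SE near PTA 0.9 is about one percentage point), and the
pcVPC uses 400–500 replicate datasets instead of 1000.

## Known limitations

- FOCE-I is an approximation; on one-subject toy problems it tracks exact
  quadrature within 0.1 OFV units (tested), but no SAEM/Bayesian alternative
  is provided.
- The per-seed scatter of covariate-slope estimates at the 30-subject design
  is large (RSEs of roughly 20–45%), and the flow-on-Vc likelihood-ratio
  signal sits near the forward-selection threshold, so single-seed selection
  results vary; the suite documents this rather than hiding it.
- The 40% fT>MIC claim for 1 g q8h (0.5 h infusion) at MIC 4 mg/L in the
  90–130 ml/min group evaluates to a PTA of ≈ 88–89% under the published
  parameters — "close to 90%" — and is reported as computed.
- Only the lower efficacy bound is simulated; toxicity ceilings are out of
  scope, as are nonlinear elimination, three-compartment kinetics and oral
  absorption.
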