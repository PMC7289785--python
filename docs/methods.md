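# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `pulsepkpd`. Units throughout: time h, hormone concentration
ng/mL, drug concentration µg/L, dose mg, cumulative exposure mg·h/L. Clock
times are normalized so that 0 = 6 a.m.; every design doses at 8 a.m.
(normalized 2 h), with the second daily b.i.d. dose 8 h later.

## Growth hormone model

GH plasma concentration obeys `dC/dt = S(t) − k_el·C` with secretion

    S(t) = baseline·k_el + Σ_j mass_j · F(Ce(T_j)) · φ(t; T_j, width)

where `φ` is a unit-mass Gaussian density at pulse time `T_j` with SD
`width`, and `F(Ce) = 1 + Emax·Ce^γ/(EC50^γ + Ce^γ)` (Emax ∈ [−1, 0], γ fixed
to 1) is evaluated at the effect-site concentration at the pulse centre —
a pulse is treated as a single secretion decision, so the factor scales the
whole pulse mass. A pointwise rate-scaling alternative is available
(`effect_on="rate"`), in which case the ODE route is used. The effect site
lags plasma first-order: `dCe/dt = k_e0(Cp − Ce)`.

Interpretation of the published table values: "Baseline" (0.056 ng/mL) is
the steady-state baseline *concentration* (basal secretion rate =
baseline × k_el); "Amplitude" (1.69 ng/mL) is the typical pulse *mass*
(time-integrated secretion per unit volume), so the Gaussian height is
`mass/(width·√(2π))` — invariant to width and identical to the
deconvolution's event-mass convention.

Because the plasma equation is linear, the response to each pulse has the
closed form

    C_j(t) = mass_j · ½·erfcx(b)·exp(−u²/2w²),  b = (k_el w² − u)/(w√2),

with `u = t − T_j` (erfcx is the scaled complementary error function; for
`b < −20` the expression reduces to the pure exponential tail and is
evaluated as such to avoid overflow). The default GH evaluation is this
superposition — exact up to floating point — and an adaptive-ODE route
(`method="ode"`, LSODA, rtol 1e-8/atol 1e-10 by default) exists as an
independent cross-check; the two agree to <1e-9 ng/mL on trial grids.

## Prolactin model

A pool (precursor) model:

    dP/dt = k_s·(1 − I(t)) − k_r_eff(t)·P
    dC/dt = k_r_eff(t)·P − k_el·C
    k_r_eff(t) = k_r · (1 + DIU24(t) + DIU12(t)) · F(Cp(t))

with two additive circadian cosines about the mesor
(`DIU = amp·cos(2π(t−phase)/period)`, periods 24 h and 12 h, phases on the
normalized clock), a *direct* plasma-drug Emax factor on release (the GH
effect runs through an effect compartment, the PRL effect does not — an
asymmetry of the underlying analysis), and a synthesis decline driven by
cumulative exposure: `I = x·slope/(1 + x·slope)` with `x` the trapezoidal
integral of plasma concentration since the first dose, converted to mg·h/L.
The sum |amp24| + |amp12| must stay below 1 so the release rate remains
positive; inner optimizer excursions are floored at 1e-6.

Initial conditions are the mesor steady state (`P = k_s/k_r`,
`C = k_s/k_el`) followed by a 24 h run-in before the first retained output.
Note the pool turnover time is `1/k_r ≈ 90 h`: the run-in settles the fast
plasma compartment's circadian phase, while the pool stays near its mean —
which also means drug-induced suppression is a plasma-timescale transient
(the observed ~8 h suppression-and-return), not a new steady state, and
`k_r` itself is essentially uninformed by 12 h windows (it is held at its
nominal value in the placebo-stage fits; the paper's own RSE for it is 30%).

Given a tabulated drug input the system is linear with time-varying
coefficients. The default integrator is exact for piecewise-linear inputs
on a uniform grid (step 0.05 h in simulation, 0.1 h inside estimation): an
integrating-factor cumulative-trapezoid for the pool (its exponent stays
O(k_r·horizon) ≈ 4, so no overflow) and a constant-coefficient exponential
recursion (an IIR filter) for plasma. It matches an adaptive LSODA solution
to ~1e-4 relative; the residual error CV is 22%, so the discretization is
irrelevant statistically and the grid path is ~100× faster, which is what
makes the mixed-effects inner loops affordable.

## Virtual trials

The generator reproduces the phase-1 design: cohorts of 8 (6 active, 2
placebo); single doses of 0.1/0.4/0.8/1.2/1.5 mg; 13-day multiple dosing at
1.2 mg q.d., 0.8 and 1.0 mg b.i.d. (doses 8 h then 16 h apart); hormone
sampling at 20-min intervals from −2 h to +12 h on day 1 (single dose, with
the 15/30/60-min post-dose PK points *replacing* the grid in the first
hour) and from −1 h to +11 h on days 7 and 12 (multiple dose). GH
observations below the 0.05 ng/mL LLOQ are substituted by the LLOQ and
flagged, exactly as the source analysis did (roughly 20% of placebo GH
samples fall below it at the published parameters); PRL is never censored.
Observations carry proportional error `y = f·(1+ε)`.

Inter-pulse intervals follow a log-normal renewal process with
`μ = log(74 min)` and `σ = (log 160 − log 44)/(2·0.6745) ≈ 0.957`,
reproducing the published placebo median and quartiles exactly; the implied
95th percentile (~357 min) is heavier than the reported 293 min — the
renewal law is calibrated to the central statistics only. Pulses are
generated from 2 h before each sampling window.

Per-subject random effects are log-normal at the published variances,
including per-pulse amplitude variability (ω² = 3.46, i.e. CV ≈ 555%) and
between-occasion effects on GH width and elimination rate (one draw per
sampling day). PRL circadian-amplitude draws are redrawn until
|amp24|+|amp12| < 0.95 (a truncation of the log-normal law needed to keep
the release rate positive). Covariates (age, weight, height, derived BMI
and lean body mass) are independent truncated normals — sufficient because
no covariate effects exist in the generating model.

The drug PK is a two-compartment model with first-order absorption and
combined linear + Michaelis–Menten elimination. The compound's published PK
parameters are not reproduced here; the shipped defaults (ka 1/h, Vc 100 L,
Vp 150 L, Q 10 L/h, CL 40 L/h, Vmax 150 µg/h, Km 1 µg/L, 30%/20% CV on
CL/Vc) are *illustrative*, chosen so that the studied dose range straddles
both EC50s (0.1 mg peaks at ~0.4 µg/L, below the GH EC50 of 0.609; 1.5 mg
at ~6 µg/L, deep in saturation) and so that individual concentration–time
profiles differ between subjects, as the real analysis's individual
post-hoc PK profiles did. Any quantitative PK claim requires study-specific
configuration.

Seeding: one master seed spawns an independent substream per subject
(`SeedSequence([seed, k])`), so subject k's data are invariant to roster
size.

## Deconvolution

Each uniform profile is fit by weighted least squares (weights
`1/max(y, LLOQ)`, matching proportional error) to
`C(t) = B + Σ m_j·K(t−T_j; w, k_el)` with a shared width and elimination
rate, starting from the documented initial values (width = half the 20-min
sampling interval, half-life 15 min). The insert–test–remove loop:

* a candidate location is the largest 3-point-smoothed positive weighted
  residual, skipped when below a noise floor (max(0.06, min(0.8·RMS, 0.4))
  of the weighted residuals) — residual dust on noise-free profiles is not
  worth a refit;
* after refitting, the candidate is kept if its mass passes a one-sided
  t-test against its asymptotic SE at α = 0.05, **or** if a partial F-test
  (2 df: mass and location, held to α/2 because many candidates are
  probed) on the weighted sum-of-squares drop passes. The F-route is
  essential: for a pulse centred near or before the window edge, mass and
  location are collinear and the mass SE explodes even when the event is
  overwhelming — without it, whole profiles fail;
* the residual variance feeding both tests is estimated from uncensored
  observations only: LLOQ-substituted stretches are exactly constant and
  otherwise bias the variance (and every test) toward zero, manufacturing
  spurious events in flat regions;
* events whose t-test fails are removed unless the F-test on their removal
  is significant; the loop stops when a full cycle changes nothing, when an
  insert/remove oscillation is detected, or after 50 cycles.

Gap augmentation inserts one flagged, mass-less event at the midpoint of
every inter-pulse gap longer than 300 min — once per original gap, never
recursively, for placebo and treated profiles alike (no selection bias);
augmented events exist so that downstream estimation can see fully
suppressed pulse locations, and are excluded from interval statistics.

Operating characteristics are evaluated against *detectable* pulses: centre
inside the observed window (tail-only pulses cannot be localized), mass at
least 10× the basal secretion per sampling interval, and peak increment at
least 3 local noise SDs (under proportional error, a small pulse on a large
neighbour's tail is swamped by the neighbour's noise). Matching tolerance
is 0.5 h (1.5 sampling intervals). At the published placebo parameters with
~16% noise this yields sensitivity ≳ 0.92, <1 spurious event per profile,
and median elimination-rate error ~2%.

## Mixed-effects estimation

The objective is −2·log of a Laplace approximation of each subject's
marginal likelihood at the posterior mode of the random effects, with
interaction (residual variance uses the individual prediction):

    OFV_i = h(η̂) + log det(H/2) − q·log 2π,
    h(η) = Σ[(y−f)²/v + log 2πv] + ηᵀΩ⁻¹η + log det 2πΩ,
    H = 2 JᵀWJ + 2 Ω⁻¹  (Gauss–Newton curvature, W = 1/v).

For a linear model with additive error this is exact (verified against the
closed form to 1e-6). The contract is parameter recovery, not OFV parity
with any particular estimation software.

Inner problem: damped Newton with the Gauss–Newton Hessian; the GH
Jacobian is fully analytic (the model is linear in each pulse mass, and
the width/elimination kernel partials have closed forms); PRL uses forward
differences over its three random effects. Steps are capped at 3 prior SDs
per move and iterates boxed at ±10 prior SDs — random effects for weakly
informed pulses (edge of the sampling window) otherwise run away along
near-flat likelihood directions. Inner gradient tolerance is 5e-3 (in
prior-SD units) during outer search and 1e-5 for final empirical Bayes
estimates; the covariance step re-solves at 1e-8 because a stale posterior
mode biases finite-difference curvature.

Outer problem: Nelder–Mead on transformed parameters (log for positive
parameters and variances, a logit-type map for Emax ∈ (−1, 0), identity
for phase shifts), with an explicit initial simplex of 0.15-steps on the
transformed scale (the scipy default perturbs coordinates that start at
exactly zero by only 2.5e-4, which collapses below the function tolerance
and stalls the search). Warm-started inner modes are carried across outer
evaluations; OFV reproducibility is ~1e-3.

Sequential protocol: stage 1 estimates system parameters and variances on
placebo subjects with drug parameters fixed; stage 2 freezes all
placebo-stage estimates (including variances and the residual error, per
the analysis's description) and frees the drug parameters on the full data
set. For PRL a final joint refinement then frees every parameter the
published table reports (the table is one joint fit), using the staged
estimates as warm starts — freezing circadian amplitudes estimated from
the placebo third of the subjects would otherwise propagate their sampling
error into the drug parameters. LLOQ-substituted GH values are treated as
ordinary observations (substituted-value likelihood), as in the source
analysis; a censored (M3-type) likelihood is deliberately not the
default.

Covariance step: central finite differences (relative step 1e-4, Richardson
extrapolated) of the OFV; covariance = 2·H⁻¹; RSE via the delta method on
the natural scale; condition number = eigenvalue ratio of the correlation
matrix. A non-positive-definite Hessian reports status "failed" rather than
raising. Bootstrap: subjects resampled with replacement, stratified by
cohort, each replicate refit from the original estimates; medians, 95%
percentile intervals and success rates are reported.

## Diagnostics

* **CWRESI** — linearization at the posterior mode:
  `E[y] ≈ f(η̂) − Jη̂`, `Cov[y] ≈ JΩJᵀ + diag(v(f(η̂)))`, residuals whitened
  by the Cholesky factor. Calibrated (mean ≈ 0, SD ≈ 1, ~4.6% outside ±2)
  under the true model.
* **NPDE** — per-subject Monte-Carlo simulation under the population model,
  empirical mean/covariance decorrelation, mid-rank scores clamped at
  `1/(2·n_sim)`, inverse-normal mapped; summarized per treatment day
  (mean, variance, Shapiro–Wilk p as a descriptive, not a gate). Because
  the observation vector is out-of-sample with respect to the estimated
  covariance, the i-th triangular component's variance is inflated by
  ~`n_sim/(n_sim−i−2)`; the decorrelated observations carry the matching
  finite-simulation correction, without which per-day variances reach
  1.2–1.4 on 70-observation subjects even under the true model.
* **pcVPC** — prediction correction by bin-median population prediction
  over clock time (default 12 equal-count bins), percentile bands with
  Monte-Carlo CIs; the coverage summary counts each observed percentile
  point (5/50/95 per bin) against its simulated 95% band. Defined for PRL
  only: pulse timing differs between GH subjects, so clock-time percentile
  bands are meaningless there and GH requests raise
  `UnsupportedDiagnosticError`.
* **Shrinkage** — `100·(1 − SD(EBE)/ω)` per inter-individual effect.
* **Covariate screen** — r² of EBE-vs-covariate regressions (centered),
  candidates flagged at r² > 0.5, optional forward-inclusion (p < 0.05) /
  backward-deletion (p < 0.01) stepping through refits and LRTs.

## Scaled-down re-estimation experiments

The acceptance workflows simulate at the published parameter vectors and
re-estimate. Problem sizes (chosen to keep a full run in minutes on one
CPU): GH placebo stage, 20 subjects (12 single-occasion + 8 two-occasion);
GH drug stage, 40 subjects across all published cohorts; PRL, 40 subjects
(12 placebo, 16 single-dose over four dose levels, 12 b.i.d.);
deconvolution operating characteristics, 100 single-occasion profiles;
diagnostics calibration, 32 subjects. Starting values are deliberately
offset 20–50% from the generating values. Between-occasion variances are
fixed at their nominal values in the recovery fits (two occasions in eight
subjects cannot inform them, and they are not reported quantities).

## Known limitations

* **GH drug-parameter identifiability.** With the published per-pulse
  amplitude variability (CV 555%), forty subjects carry only ~250 active
  pulses; the mean log-suppression per dose group is then determined to
  ~±30%, and the three drug parameters (Emax, EC50, k_e0) lie on a long,
  shallow likelihood ridge: maximum likelihood lands anywhere along it
  (often at the Emax = −100% boundary), regardless of optimizer, pulse
  source (generator truth or deconvolution + augmentation), censoring
  handling, or PK informativeness — importance-sampling checks of the
  exact marginal likelihood confirm the ridge is in the data, not the
  approximation. Recovery of the suppression *curve* over the observed
  concentration range is good; recovery of its individual parameters at
  this scale is not. This is consistent with the source analysis's own
  caveats (no bootstrap was feasible for the GH model, condition number
  54), and it means asymptotic standard errors for these parameters should
  be treated with suspicion at small n. The corresponding acceptance
  checks are kept at their stated tolerances and fail honestly at this
  scale.
* The renewal law for pulse timing matches the published central interval
  statistics but not the upper tail; real pulse trains may also carry
  circadian structure in timing that the generator omits.
* LLOQ substitution (as in the source analysis) biases the GH baseline
  upward in treated arms; the package reproduces, rather than corrects,
  this choice.
* The PK configuration is illustrative; all drug-exposure-dependent
  results are conditional on it.
* Passing recovery tests on these synthetic trials demonstrates internal
  consistency of simulator + estimator under the stated model; it cannot
  validate the model against real hormone physiology (feedback loops,
  secretion-timing rhythms and assay artifacts are all outside the
  generating model).
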