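# Methods

## Structural model

The simulated state couples four linear subsystems, all driven by the
remimazolam central compartment:

1. **Remimazolam disposition** — a three-compartment mammillary model in
   amounts (mg): dA1/dt = in(t) − (CL+Q2+Q3)/V1·A1 + Q2/V2·A2 + Q3/V3·A3,
   with the standard peripheral equations. Infusions enter A1 at a constant
   rate; boluses are instantaneous increments of A1.
2. **Arteriovenous delay** — venous observations are modelled as a convex
   combination of the arterial signal and a mass-less first-order tracer:
   Cven = F·Cp + (1−F)·Cdel with dCdel/dt = k_delay(Cp − Cdel), F = 0.132,
   k_delay = 0.0144 min⁻¹. The delay compartment carries no distributional
   mass (no venous volume is identified). The same F and k_delay are reused
   for the metabolite.
3. **Effect sites** — dCe/dt = ke0(Cp − Ce), mass-less, one each for the
   MOAA/S (ke0 = 0.298 min⁻¹, no covariates) and BIS endpoints
   (ke0 = 0.145·exp(−10.6/1000·(AGE−35)) min⁻¹).
4. **CNS7054** — the full eliminated remimazolam mass (fraction metabolised
   1.0; a molar-mass conversion factor is configurable but defaults to mass
   conservation) enters a depot compartment, transfers at k_depot = 0.215
   min⁻¹ into a two-compartment metabolite model.

Two bookkeeping states integrate eliminated remimazolam and metabolite mass,
so mass balance is a machine-precision identity rather than an approximate
check.

**Solver.** The system is linear and time-invariant with piecewise-constant
input, so trajectories are propagated exactly with matrix exponentials of
the input-augmented rate matrix, segment by segment between dose events and
requested output times; propagators are cached per step length, making
uniform grids cheap. An adaptive ODE integration (`scipy.solve_ivp`, LSODA)
exists only as an independent oracle in the test-suite; agreement over random
dosing problems is required to 1e-6 relative.

## Covariate engine

All fixed effects are expressed relative to a 70-kg, 35-yr-old male without
opioids and with normal hepatic/renal function. Conventions:

* weight: volumes ∝ WGT/70 (remimazolam) or (WGT/70)^0.518 (CNS7054, an
  estimated exponent); clearances ∝ (WGT/70)^0.75;
* distribution clearances use compartmental allometry
  Q = Q_ref (V/V_ref)^0.75, so covariate and random effects on a peripheral
  volume propagate into its clearance;
* age: exp(K/1000·(AGE−35)); binary covariates: exp(K/100);
* ECMO/ICU coefficients are direct multiplicative factors (e.g. remimazolam
  V1 ×46.1 while ECMO runs and ×0.189 for ECMO subjects).

The remimazolam structural estimates are published both rounded to three
significant figures and at full precision in a simplified population-code
listing; the full-precision values (V1 4.30730 L, V2 12.2994 L, V3 18.6411 L,
CL 1.11977 L min⁻¹, Q2 1.45260 L min⁻¹, Q3 0.297838 L min⁻¹, and the
corresponding covariate coefficients) are the package defaults, because the
rounding of V3 alone (18.6 vs 18.6411) otherwise introduces a systematic
0.22 % error against that listing. Parameters printed only once keep their
printed values. A transcription of the simplified code is retained as an
internal oracle; the engine must agree with it to 0.2 % over the full
demographic envelope.

Interindividual variability is log-normal; each parameter with a published
ω² accepts a log-scale deviation η applied as exp(η), in the canonical order
(V1, V2, V3, CL, Q2, Q3 | k_depot, V1m, V2m, CLm, Q2m | Ce50-MOAA/S |
ke0-BIS, Ce50-BIS). The CV(%) implied by a log-normal variance is
100·sqrt(exp(ω²)−1) (the inverse is provided); this reproduces every
published CV cell to one decimal.

**Opioid cut-point adjustment.** The published table footnotes
opioid-specific values of (b0, d01) without printing the formula. We
reconstruct them as d01_op = d01·exp(−K), b0_op = b0 + d01 − d01_op, which
(a) leaves the cumulative logit of scores ≤ 1 exactly invariant, matching
the stated behaviour that opioids shift probability from score 1 to score 0
with other scores unchanged, and (b) reproduces both footnoted values at the
precision allowed by the three-significant-figure inputs (2.65·e^−1.67 =
0.4989 vs the printed 0.500, which the authors evidently computed from
unrounded estimates).

## Pharmacodynamics

Both endpoints share the competitive-interaction kernel
f = (Ce/Ce50)^γ / (1 + (Ce/Ce50)^γ + (Ca/Ca50)^γ), with Ca the
*instantaneous arterial* metabolite concentration — a metabolite effect site
was tested and rejected in the source analysis. The drug effect enters the
MOAA/S model only through the score-0 logit, b0 + DEFF·f, and propagates to
all cumulative logits through the additive cut-point chain; probabilities
follow by logistic transform and differencing. BIS = baseline·(1 − f).

The Hill exponent γ is not reported for either endpoint; the package default
is γ = 1, exposed in configuration (`theta.moaas_gamma`, `theta.bis_gamma`).
With γ = 1 every qualitative published behaviour is reproduced; a different
unreported γ would change effect steepness but none of the structural
conclusions.

Consequences verified by the test-suite: probabilities are non-negative and
sum to one everywhere; the probability-weighted score is strictly decreasing
in Ce and BIS strictly increasing in Ca (at Ce > 0); the metabolite alone
produces no effect (f = 0 at Ce = 0); at constant Ce, metabolite
accumulation drives both endpoints toward lighter levels (apparent
tolerance), more strongly in the young, who need higher absolute targets.

## TCI controller

Plasma mode pins A1 = target·V1 exactly at every control tick (default 1 s)
by solving the one-tick propagator for the required rate, clipped to
[0, pump cap] (default 600 mg h⁻¹). Effect-site mode administers, each tick,
the largest admissible rate such that the *predicted future peak* of Ce does
not exceed the target: with a linear system the future Ce under candidate
rate r is a(t) + r·g(t), where a is the free evolution of the current state
(one matrix–vector product against a precomputed horizon map, 15-min
horizon) and g the precomputed response to a one-tick unit-rate infusion, so
the binding rate is found in closed form. This yields monotone, overshoot-
free induction and automatically transitions into holding Ce at the target
(where Cp = Ce). The MOAA/S ke0 drives the controller; BIS is evaluated as a
passive output.

Scenario definitions: the **sedation** target maximises P(MOAA/S ∈ {2, 3})
at 10 min of constant-target TCI; the **anaesthesia** target is the minimal
one achieving P(MOAA/S = 0) ≥ 0.90 at first target attainment. Both are
solved on the simulated criterion (Brent / golden-section, 1e-3 µg ml⁻¹),
seeded and cross-checked by the closed-form inversion that ignores the small
metabolite correction. Scenario simulations assume opioids present and
normal organ function. The **induction dose** is the cumulative dose until
Ce first reaches 99 % of target (no published definition exists; this one is
insensitive to the asymptotic approach) and the **maintenance rate** is the
mean pump rate over minutes 30–60 of a 60-min simulation.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular source study: covariates uniform over the published
demographic envelope (age 6–93 yr, weight 21–171 kg; configurable
prevalences for sex, opioids, hepatic/renal flags and venous-only sampling);
independent log-normal etas with the published ω² (remimazolam CL variance
×1.86 for venous-only subjects); multiplicative log-normal PK residual error
(the transform-both-sides proportional model); MOAA/S scores drawn
categorically from the model; BIS produced as a 1-Hz stream from the
15-s-delayed effect signal around a per-subject noisy baseline, with
additive noise, then median-filtered in 10-s epochs. Remimazolam /
metabolite concentration rows within 2 / 3 min of the start of
administration are excluded, mirroring the front-end data-cleaning rule.
Residual magnitudes are not published; the defaults σ_PK = 0.20 (log scale)
and σ_BIS = 4 BIS units are field-realistic stand-ins recorded in the
dataset sidecar. Randomness uses `numpy` seed sequences with one spawned
stream per subject, so datasets are bit-reproducible and subjects are
independent.

Because covariates are uniform rather than study-weighted, and there is no
dropout, no assay quantification limit and no model misspecification,
passing recovery tests demonstrate *self-consistency* of the implementation,
not fitness of the model for any real dataset.

## Estimation (desk scale)

Full nonlinear mixed-effects estimation (FOCE/LAPLACE) is deliberately out
of scope. Provided are: per-subject MAP (empirical-Bayes) estimation of the
six remimazolam etas — penalised log-scale least squares solved by
trust-region Gauss–Newton, using only remimazolam concentration rows (the
metabolite rows depend on etas the estimator does not carry) — and pooled
fixed-effect ML with etas pinned at zero, fitting chosen theta fields
(positive parameters on the log scale) to low-IIV cohorts. Performance
metrics follow the anaesthesia-literature convention: proportional
performance error for concentrations, additive for BIS, summarised as
medians (MdPE, MdAPE).

Design points the tests rely on: a rich 21-sample design over 240 min makes
all six remimazolam etas identifiable from noise-free data to <1e-3; a
50-subject, σ = 0.05, zero-IIV cohort recovers CL_ref and V1_ref within 5 %.

## Numerical choices and degenerate inputs

* Propagator cache keys round the step to 12 decimals; boluses at an output
  time are applied before the output (a grid containing the bolus time
  reports the post-bolus concentration).
* Peak-effect timing scans a coarse grid (doubling the window until the
  maximum is interior) and refines by bounded golden-section to 1e-4 min; it
  is dose-independent by linearity.
* Dose-record merging combines consecutive infusions separated by < 1 s,
  differing by < 50 µg min⁻¹ in rate, each shorter than 2 min, repeating to
  a fixed point; total dose is preserved exactly. Boluses never merge.
* σ floors at 1e-6 in estimators to keep noise-free problems well posed;
  proportional performance errors reject non-positive predictions.
* Zero dosing yields identically zero trajectories; empty subjects return
  the prior mode in MAP estimation.

## Known limitations

* The time of peak effect after an *instantaneous* bolus computes to
  2.39 min for the reference adult, slightly below the published "about
  2.5 min"; a 15-s zero-order bolus — how remimazolam boluses are given
  clinically — yields 2.52 min. The package reports the instantaneous-bolus
  definition.
* ECMO/ICU adjustments reproduce the published multipliers but the source
  analysis itself reports poor predictive performance in those groups;
  predictions there should be treated as qualitative.
* Venous predictions share the single published delay model; no
  site-specific venous volumes exist.
* Opioid co-administration is a binary covariate; no opioid concentration
  dependence is modelled. No saturable kinetics, no alternative tolerance
  mechanisms (cumulative-dose or slow Ce50-drift models), and no BIS
  monitor-version differences.
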