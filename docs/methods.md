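# Methods

This note documents the models and procedures implemented in `cogstage`,
the choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## Robust internal norms

Each raw test score is first oriented so that higher is always better
(timed tests such as Trail Making B and error counts such as CPAL are
negated), then regressed by ordinary least squares on age (years), sex
(0/1, female = 1) and a literacy standard score (WRAT-3-style, mean 100,
SD 15) over a robust subsample.  The demographically adjusted z-score is
the residual divided by the residual SD of that fit.  Sex enters as a single
additive offset; no interactions or nonlinear age terms are used.

The robust subsample is built in two passes because membership depends on
staging, which itself needs norms: pass 1 fits provisional norms on visits
of participants never caught by the raw-score or informant cut-offs alone
(no z-scores needed); pass 2 stages the whole cohort with those provisional
norms and refits on visits of participants never assigned CU-D, MCI or
dementia.  The scheme is fixed at exactly two passes — further iteration
changes the fit negligibly but makes the estimator's behaviour harder to
reason about.

Composites are `100 + 15 × mean(z)` over their member tests (immediate
memory: AVLT Total, Logical Memory I, BVMT-R Total; delayed memory: AVLT
Delayed, Logical Memory II, BVMT-R Delayed; executive: Stroop Color-Word,
Trails B, Digit Symbol; PACC3: AVLT Total, Logical Memory II, Digit Symbol;
CogState global: CPAL, GML-MPS, GML-CT, OCL).  A composite is missing when
any member is missing, except the CogState global, which tolerates three of
four (computerized batteries lose single subtests to technical failure far
more often than paper batteries lose a test).

## Two-tier staging

Tier 1 flags a visit if **any** of the following fires (missing inputs
never fire a criterion): Clock Draw ≤ 7, MMSE ≤ 26, AVLT Delayed Recall
≤ 5, Logical Memory II ≤ 16; CDR global ≥ 0.5, QDRS global ≥ 0.5, Lawton
IADL < 14, IQCODE > 52; or any *pencil-and-paper* domain composite
(immediate, delayed, executive) at z ≤ −1.5.  Unflagged visits are CU-S by
definition.  The CogState composite is deliberately excluded from flagging
and from the impairment rule so that computerized outcomes remain
independent of status assignment and can serve as non-circular validation
outcomes.

Tier 2 is a deterministic actuarial stand-in for a human consensus panel:

- **impairment criteria**: ≥ 2 tests within one domain at z ≤ −1.5, or any
  clinical raw cut-off fired;
- **Dementia**: impairment criteria + IADL < 14 + CDR ≥ 1;
- **MCI**: impairment criteria with daily function preserved (IADL ≥ 14 or
  missing);
- **CU-D**: every other flagged visit.

Ties at thresholds follow the printed inequality directions exactly, with no
tolerance band.  An `IMPAIRED_NON_MCI` label is accepted on input as an
exclusion category but is never produced by the rules.

Progression outcomes per participant: *primary progression* is a clinical
status (MCI/dementia) at any visit ≥ 2 **and** at the most recent visit;
*any-visit progression* drops the last-visit requirement.  Reversion is
summarized at the visit-pair level (every status visit with a follow-up
counts, allowing repeats within person), with moves to any strictly
less-impaired status (ordering CU-S < CU-D < MCI < Dementia) as events.

## Inference

- **Cliff's delta** is computed from the joint ranking in
  O((m+n) log(m+n)); magnitude bands at |d| < 0.147 / 0.33 / 0.474.
- **Binomial intervals**: Clopper–Pearson (beta quantiles) for
  small-denominator reversion proportions; Wald for large-denominator
  proportions.  The choice is deliberate: exact intervals are visibly
  asymmetric at n ≈ 43 while Wald reproduces the conventional symmetric
  intervals quoted for n in the hundreds.
- **BH-FDR** uses the standard step-up rule (delegated to statsmodels; the
  test suite checks it against a from-scratch implementation of the
  definition).
- **Two-proportion power**: normal approximation, pooled SE under the null,
  unpooled under the alternative, no continuity correction.
- **Change ANCOVA**: change scores regressed on group indicators plus
  baseline score (regression-to-the-mean adjustment) and inter-assessment
  interval; adjusted group means are evaluated at covariate means; the
  nonparametric companion is a Kruskal–Wallis test on residuals from the
  covariates-only fit.
- **Logistic progression models** are fitted by maximum likelihood; Wald
  CIs on exp(β).  Non-convergence and separation raise errors rather than
  returning silent estimates.
- **Exact r×c tests**: 2×2 via the hypergeometric distribution; 2×c (or
  r×2) via Freeman–Halton enumeration of all tables with the observed
  margins; larger tables fall back to Pearson chi-square.

## PET quantification

Logan graphical analysis regresses y(T) = ∫₀ᵀCt/Ct(T) on
x(T) = [∫₀ᵀCref + Cref(T)/k2′]/Ct(T) over frames with mid-time ≥ t\* and
reports the slope as DVR.  Defaults: k2′ = 0.149 min⁻¹, t\* = 35 min,
trapezoid quadrature from time zero with an implicit (0, 0) origin.  The
late window and the quadrature rule are numerical choices; the identity
case (target ≡ reference → DVR = 1) and the proportional case
(target = c · reference → slope exactly c) hold to machine precision by
construction, and a one-tissue-compartment simulation is recovered within
2% at these settings.

Amyloid positivity is DVR ≥ 1.2 (a configuration constant, not recomputed).
Chronicity — signed years since crossing the threshold — needs an onset
age: a shared sigmoid trajectory
`DVR(age) = floor + (ceiling − floor)/(1 + exp(−rate (age − midpoint)))`
(defaults floor 1.0, ceiling 2.3, rate 0.18 yr⁻¹) is shifted along the age
axis to pass through the observed (scan age, DVR) point and solved for the
age at which it crosses 1.2 (Brent root finding, tolerance 1e-6 years).
This individual-curve inversion is a functional stand-in for published
group-based accumulation trajectories, not a reproduction of them; DVRs at
or outside (floor, ceiling) are reported as unknown onset rather than
extrapolated.  Tau thresholds are mean + 2 sample SD (n−1) of the
amyloid-negative subset per region, with strict `>` for positivity; the
numeric cut-offs therefore depend on the sample at hand by design.

## The synthetic cohort

The generator emulates the *structure* of a midlife-enrollment longitudinal
cohort, not any particular dataset:

- **Enrollment and follow-up**: baseline age N(54, 6.6²) years; visit
  intervals truncated-normal (mean 2.3 y, SD 0.3 y, minimum 1 y); number of
  visits 2–6 with probabilities (0.097, 0.135, 0.240, 0.355, 0.173), median
  five; 70% female; literacy N(106, 9²).
- **Latent dynamics**: a first-order Markov chain over
  {CU_S, CU_D, MCI, DEMENTIA} per visit interval, baseline distribution
  (0.903, 0.097, 0, 0).  The default matrix sends 2.5% of stable visits to
  CU_D and 0.26% directly to MCI per interval; CU_D reverts to CU_S at 40%
  and progresses to MCI at 24% per interval; MCI reverts at 51% (21% to
  CU_S, 30% to CU_D) and converts to dementia at 10%; dementia is absorbing.
  The matrix was calibrated **end-to-end**: the published progression and
  reversion rates describe *assigned* statuses, and the actuarial rules have
  a small but irreducible false-impairment rate and imperfect CU_D flag
  sensitivity, so the latent chain is set so that the *staged* baseline
  progression rates land near 2.9% (CU-S) and 13.5% (CU-D) — verified over
  eight cohort seeds at n = 5000 (2.1–3.0% and 11.0–14.7%).
- **Scores**: raw score = demographic prediction (the same linear model the
  norming module fits, with per-test coefficients on natural scales) +
  state shift × residual SD + correlated noise.  State shifts are in z
  units per domain (CU_D: −0.55 immediate, −0.60 delayed, −0.35 executive,
  −0.50 CogState, −0.25 screening; MCI roughly −2; dementia roughly −3).
  Noise decomposes into a person-stable ability factor (variance 0.68), a
  bounded day effect (0.02, truncated normal at ±1.8 SD) and unique test
  error (0.30).  The person factor is a standardized lognormal — right-
  skewed with a hard left bound — because the emulated cohort *excludes*
  longstanding low performers: with a Gaussian ability factor no parameter
  setting can keep composite SDs near 13–15 while holding the chance
  false-impairment rate near the low levels a conservative review panel
  produces (the multi-test rule then fires on 4–7% of healthy visits under
  any variance split).  The heavy right tail makes sample SDs at small n
  noisy; distribution-level invariants are therefore asserted at the full
  cohort size.
- **Informant ratings**: per-state probabilities of abnormal CDR/QDRS
  (CU_S 1.0/1.2%, CU_D 55%, MCI 80%, dementia 100% with CDR ≥ 1), binomial
  IADL deficits, IQCODE shifts above the 48 "no change" anchor, and
  self-report items.
- **Biomarkers**: a state-dependent fraction of participants are lifetime
  amyloid accumulators (35/55/78/88% for CU_S/CU_D/MCI/dementia) whose DVR
  follows the sigmoid trajectory with onset age N(66/64/58/55, 8²);
  non-accumulators sit at N(1.03, 0.05²).  Regional tau SUVRs are
  state-dependent normals matching the ordering stable < declining ≪
  impaired.  TAC pairs come from one-tissue-compartment kinetics driven by
  a gamma-variate input function on a 28-frame, 70-minute schedule.

What the generator does **not** emulate: real test distributions
(floors/ceilings, integer scores), missingness and attrition mechanisms,
practice effects, family structure or genetics, informant rating drift, and
any dependence of visit scheduling on health.  Passing tests on this cohort
shows that the pipeline's *rules and estimators* behave as specified under a
plausible data-generating process; it does not validate the staging rules
against human consensus on real data.

## Known limitations

- The consensus conference is replaced by codified rules.  This is the
  largest simplification: the rules over-call MCI relative to a
  conservative human panel (synthetic MCI visit prevalence ≈ 3% vs ≈ 1% in
  comparable real programs), and staged CU-D→CU-S reversion runs near 60%
  per visit-pair rather than the published ≈ 48%, because falsely flagged
  CU-D visits revert almost surely.  The progression rates — the primary
  validity quantities — are calibrated; the reversion rate is reported but
  not forced.
- Printed confidence intervals in the motivating literature for the small
  reversion denominators do not match exact Clopper–Pearson bounds to the
  printed precision (nor Jeffreys, mid-p, Wilson or likelihood-ratio
  intervals); this package reports true Clopper–Pearson bounds, which agree
  within one percentage point.
- The tau thresholds (and hence positivity fractions) are sample-derived;
  no external cut-offs are bundled.
- Logan DVR assumes the supplied reference efflux constant; no kinetic
  model fitting beyond the graphical slope is performed.
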