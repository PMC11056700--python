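# Methods

## Model

Patients move among a small set of clinical states — induction &
consolidation treatment (the start state), intermediate states
(off-protocol treatment, MRD-negativity, and in the extended model
on-protocol alloSCT and maintenance), relapsed/refractory disease (R/R),
and the absorbing states relapse mortality (RM, any death after R/R) and
non-relapse mortality (NRM).  The process is modeled as a
**time-inhomogeneous Markov multi-state model on the clock-forward scale**:
all transition intensities are indexed by time since the start of induction
& consolidation and are never reset at a state entry.  Time is kept in days
throughout estimation (years appear only at presentation, 365.25 d/y),
avoiding unit rounding inside risk sets.

For each allowed transition *k* = (g→h) the cumulative hazard
A_k(t) is estimated by **Nelson–Aalen**: at each distinct event time *u*,
the increment is d_k(u)/n_g(u), events over the number of patients occupying
g just before u.  Patient histories are first stacked into long format: per
patient and occupied state, one row per competing transition on the shared
half-open interval (t_start, t_stop], status 1 on the realized row.  A row
is at risk at u iff t_start < u ≤ t_stop, which handles delayed entry into
intermediate states.

Transition probabilities come from the **Aalen–Johansen product integral**
P(s,t) = ∏_{u∈(s,t]} (I + dA(u)), where dA(u) collects all transitions'
increments at u off-diagonally and the diagonal makes rows sum to zero.
Ties across different transitions at one time enter the same factor.  Rows
of P therefore sum to exactly 1 up to floating-point accumulation, and
Chapman–Kolmogorov P(s,u)P(u,t)=P(s,t) holds on event-time grids; both are
enforced in tests at 1e-10.  The competing-risks cumulative incidence
function is computed directly (CIF_k(t) = Σ_{u≤t} S(u−) d_k(u)/n(u)) and is
tested to coincide with the product integral on the equivalent three-state
space at 1e-12.

Treatment effects are **transition-specific Cox models**: the partial
likelihood is maximized over the rows of one transition (or several, with
baseline hazards stratified by transition and shared coefficients), with
the randomization arm coded 0/1 (control reference).  The effect of an
intermediate state on a subsequent event pools all rows into the target
state with a 0/1 origin indicator and a **shared baseline across origins** —
this is what "being off-protocol raises the R/R hazard" means here, and the
MRD analogue uses the not-yet-MRD-negative origin with MRD-negative as
reference.

## Numerical choices

* **Ties**: Breslow by default (Efron available).  Event times from the
  simulator are continuous, so the choice is immaterial in tests; for real
  day-resolution data Breslow matches the common default for stacked
  multi-state fits.
* **Newton–Raphson**: start at β=0, step-halving only when the likelihood
  decreases by more than float noise (1e-9·(|ℓ|+1)), convergence at
  gradient norm < 1e-8, max 50 iterations.  Monotone likelihoods (all
  events in one level of a binary covariate, or |β|>50) raise a
  `ConvergenceError` rather than returning a divergent estimate.
* **Inference** is Wald: CI = exp(β ± 1.96·se), two-sided normal p.
* **Same-day events**: state entries are ordered before death on a shared
  date (so same-day relapse + death is relapse mortality), and a state
  entered and left the same day receives a minimal half-day sojourn to keep
  t_start < t_stop; both rules are applied identically by the stacker and
  by the hand-computed oracle values.
* **2×2 test**: Yates-corrected chi-squared,
  N(|ad−bc|−N/2)²/(r₁r₂c₁c₂) with the correction clamped at zero, 1 df.
  The continuity correction is the default because it is what the reported
  off-protocol comparison uses (corrected p = 0.019 vs ≈0.012 uncorrected).
* The off-protocol **reconciliation rule** clears the off-protocol label
  when an on-protocol alloSCT precedes it (ties included), and is
  idempotent.

## Synthetic data

The generator draws trajectories from the same model class the estimators
assume: piecewise-constant transition intensities in study time, sampled
exactly by inverting each segment's cumulative hazard; per-transition arm
hazard multipliers; uniform accrual over 4 years with an administrative
horizon of 10 years (patient-level censoring uniform on [6, 10] years,
median follow-up ≈ 8 years); an optional Bernoulli mask that hides
generated MRD-negativity times (emulating assay missingness) plus a
probability that a never-MRD-negative patient has a positive assessment on
record.

`default_hovon_like_config()` emulates a 334-patient trial (166 control /
168 CLO).  Control-arm rates (per day) were chosen by iterative simulation
so long-run replicate means land near the emulated trial's aggregates:
off-protocol ≈11% control / ≈20% CLO (arm HR 2.0), recorded MRD-negativity
≈35%/43% (arm HR 1.35, 10% mask), ≈108/334 relapsed/refractory entries, and
≈63% alive at five years; these rates are frozen constants, not refit at
run time.  `recovery_config()` uses constant rates on the plain
off-protocol model with a known arm HR (default 2.0) on going off-protocol
and an origin effect built structurally: the off-protocol→R/R rate is 1.6×
the Ind&Cons→R/R rate, so the proportional-hazards origin model holds
exactly.

What the generator does **not** emulate: dependence of hazards on age or
risk group, semi-Markov (sojourn-time) effects, non-administrative loss to
follow-up, state re-entry, or correlated assessment schedules.  Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to their violation in real trial data.

## Problem sizes in tests

The distributional checks use 4,000–5,000 simulated subjects; parameter
recovery uses 200 replicates of a 2,000-patient trial (bias of the mean
log-HR under 5%, 95% CI coverage within 95%±4%); generator calibration
averages 200 replicates of the 334-patient default.  These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the suite quick.

## Limitations

* No variance estimation for Aalen–Johansen paths (point curves only).
* No semi-Markov models, frailty, time-varying coefficients, Fine–Gray
  subdistribution fits, or MRD imputation.
* Per-arm probability paths are nonparametric (cohort split by arm); a
  Cox-model-predicted alternative would borrow strength across arms but is
  not implemented.
* The extended model's full edge set (which phases feed alloSCT and
  maintenance, and what they may transition to) is configurable because
  clinical conventions differ; the default routes Ind&Cons into alloSCT,
  maintenance or off-protocol, and allows leaving maintenance for
  off-protocol, R/R or NRM, and alloSCT for R/R or NRM.
* The stacker forbids event sequences without a corresponding edge (e.g.
  maintenance dated after off-protocol in the extended model) instead of
  guessing an interpretation; such records surface as `PathError` naming
  the patient.
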