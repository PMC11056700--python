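# msmtrial

Multi-state event-history analysis of two-arm clinical trials, built around
the kind of question that motivated it: an add-on drug in adult acute
lymphoblastic leukemia (ALL) increased measurable residual disease (MRD)
negativity but did not improve survival — did its toxicity (patients leaving
protocol treatment) eat the benefit?  Conventional endpoint analyses cannot
localize *where* in the treatment course an arm effect acts; a multi-state
model can.

`msmtrial` provides:

* **Event-history records** — one row per patient (arm, event days, last
  contact) in plain delimited text, with validation and the reconciliation
  rule that removes the off-protocol label from patients transplanted
  on-protocol first.
* **State spaces** — declarative directed-acyclic models.  Built in:
  an *off-protocol* model (Ind&Cons → {off-protocol, R/R, NRM},
  off-protocol → {R/R, NRM}, R/R → RM), its *extended* variant with
  on-protocol alloSCT and maintenance as intermediate states, and an *MRD*
  model with MRD-negativity as the intermediate event.  Patient records are
  stacked into long format: per occupied state, one row per competing
  transition on the shared clock-forward interval `(t_start, t_stop]`.
* **Estimators** — Nelson–Aalen transition hazards `dA(t) = d(t)/n(t)`; the
  Aalen–Johansen transition-probability matrix as the product integral
  `P(s,t) = ∏_{u∈(s,t]} (I + dA(u))`; Kaplan–Meier; reverse-KM median
  follow-up; competing-risks cumulative incidence; transition-specific Cox
  models (partial likelihood with delayed entry, Breslow/Efron ties,
  Newton–Raphson) including stratified-baseline multi-transition fits and
  origin-state effects; and the Yates-corrected 2×2 chi-squared test.
* **Pipelines & CLI** — `run_model1` / `run_model2` produce per-arm
  probability paths, forest tables and origin-effect fits;
  `msmtrial simulate|run` exposes them from the shell.
* **A synthetic trial generator** — clock-forward time-inhomogeneous Markov
  trajectories with piecewise-constant intensities, arm hazard multipliers,
  staggered accrual and administrative censoring, calibrated to emulate a
  ~334-patient ALL trial.  Every stage is testable without patient data.

## Worked example

```python
import msmtrial as m
from msmtrial.synthetic_data import default_hovon_like_config, simulate_trial

records = simulate_trial(default_hovon_like_config(), seed=1)
records, n_cleared = m.reconcile_offprotocol(records)
run = m.run_model1(records)

fit = run.arm_fit("Ind&Cons", "OffProtocol")
print(f"off-protocol HR (CLO vs control): {fit.hr[0]:.2f} "
      f"[{fit.hr_ci95[0][0]:.2f}-{fit.hr_ci95[0][1]:.2f}], p={fit.p_wald[0]:.3f}")
origin = run.origin_fits["offprotocol_on_rr"]
print(f"off-protocol effect on R/R: HR {origin.hr[0]:.2f}")
print(run.paths["CLO"].at(5 * 365.25)[0])  # state occupation at 5 years
```

prints (seed 1):

```
off-protocol HR (CLO vs control): 4.14 [2.06-8.32], p=0.000
off-protocol effect on R/R: HR 1.54
[0.47024 0.14286 0.06548 0.1369  0.18452]
```

i.e. in this simulated replicate the CLO arm's hazard of going off-protocol
is estimated at 4.1 (the generating value is 2.0; a trial of 334 patients
carries a wide CI), being off-protocol raises the relapse/refractory hazard
about 1.5-fold, and five years after starting treatment a CLO-arm patient
has probability ≈0.47 of remaining in the starting state, ≈0.14 of being
off-protocol, ≈0.07 of living with relapsed/refractory disease, and
≈0.14/0.18 of having died of relapse/non-relapse causes.

The chi-squared helper reproduces a printed result exactly: for 35/168
versus 18/166 off-protocol patients,

```python
m.chisq_2x2_yates(35, 133, 18, 148)   # -> (5.5159..., 0.01884...), p = 0.019
```

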