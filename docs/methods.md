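# Methods

This note documents the model implemented in `ccta_cea`: its structure,
assumptions, parameters, numerical conventions, and the limits of what the
synthetic-data experiments can show.

## Model structure

The analysis compares **AI-guided management** (standard care plus an AI
risk analysis of the routine CCTA and the statin changes it triggers)
against **standard care alone**, over a 30-year horizon in 3-month cycles
(120 cycles), discounting costs and QALYs at 3.5%/year from an NHS and
personal-social-services perspective.

A decision tree first distributes the cohort over six strata — obstructive
vs non-obstructive CAD crossed with three AI risk categories — and, within
each stratum, over baseline statin doses (0/40/80 mg atorvastatin). In the
AI arm, a per-stratum share of patients initiates (0→40 mg, drawn from the
dose-0 mass) or intensifies (40→80 mg, from the dose-40 mass). The change
shares are *observed* shares: exactly what a management survey estimator
returns, so survey estimation and tree expansion compose without
correction. Patients already on 80 mg cannot escalate. Each leaf
(stratum x treatment change x colchicine flag) then enters a Markov chain.

States are {no obstructive CAD, obstructive CAD, MI, stroke, heart
failure, cardiac death, other death}; the disease-free state is dropped
for obstructive strata, whose cohort enters in the obstructive-CAD state.
Death states are absorbing. All alive states share the same per-cycle
event probabilities within a stratum (equal first and subsequent event
risk), so the alive sub-chain is fully connected; post-event states are
chronic. The disease-free state additionally progresses to obstructive
CAD at a configurable per-cycle probability (default 0.004).

## Transition probabilities

The estimator implements the crude rate rule: per-cycle probability =
cycle length x total events / total life-months, per stratum and event
type. Life-months accrue until death or administrative censoring; a
non-fatal event does not truncate them, and events are counted including
recurrences, which makes the rule the maximum-likelihood estimator of a
constant hazard. An exponential conversion p = 1 − exp(−rate x cycle) is
available behind `ModelConfig.rate_conversion="exponential"`; the two
agree to first order for the small per-cycle risks involved (< 0.02).

Non-cardiac mortality is a constant per-cycle probability (default 0.004,
~1.6%/year). An age-dependent background-mortality table is deliberately
not implemented: it would make the transition matrix time-varying and the
package targets the published constant-hazard design. This biases
late-horizon survival slightly upward in both arms and cancels almost
entirely in the increments.

## Treatment effects

Statin effects follow LDL arithmetic: atorvastatin 40 mg lowers LDL by
48%, 80 mg by 53%, from a baseline of 3.7 mmol/L, so initiation lowers
LDL by 1.776 mmol/L and intensification by 0.185 mmol/L. Each mmol/L
multiplies the risk of every MACE outcome by a per-mmol relative risk
keyed by outcome and baseline-risk band (<5%, 5–<10%, ≥10%, mapped from
the three AI risk categories); the default is 0.78/mmol for all keys, and
the log-linear form RR = rr^ΔLDL makes dose steps compose exactly
(RR(0→40)·RR(40→80) = RR(0→80)).

The relative risk attaches to the *change* in dose. Baseline transition
probabilities already reflect whatever treatment the cohort was on, so a
standard-care patient on 40 mg contributes RR = 1, not RR(0→40). The
halved-statin-effect scenario rescales the risk reduction,
RR' = 1 − 0.5(1 − RR), because halving RR itself would overstate efficacy
whenever RR < 0.5. Colchicine multiplies all MACE relative risks by 0.80
for very-high-risk patients whose statin management changed, in the
colchicine scenario only. Adherence, LDL trajectories over time, and
non-statin lipid agents are out of scope.

## Costing and accrual conventions

Chronic state costs, drug costs, and utilities accrue per cycle of
occupancy; one-off event costs are charged on the incident flow (the mass
entering an event state from a different state) in the cycle of
transition. A repeat event within the same state (e.g. re-infarction
while in the MI state) is indistinguishable from staying and carries no
second event cost — a known, conservative simplification of cohort
models. Drug costs accrue only while alive; statin costs are drug plus
dispensing and monitoring (£16/£24 per cycle for 40/80 mg), colchicine
£12 per cycle. The AI analysis price (default £700) is charged once at
entry in the AI arm, which makes the incremental cost affine in the price
with slope one and the ICER affine with slope 1/ΔQALY.

Discounting compounds per cycle at (1.035)^(t/4) with cycle-0 accruals
undiscounted. Half-cycle correction (midpoint of adjacent occupancies for
occupancy-based accruals) is available but off by default, matching
common practice for models of this design; event-flow costs are not
half-cycle corrected. Setting the discount rate to zero reproduces
undiscounted totals exactly (the implementation reuses the same
summation path to keep this equality bitwise).

## Synthetic data

The generator emulates the statistical structure the estimators assume,
not any real dataset:

* **Strata**: 20% obstructive CAD; risk-category mix richer among
  obstructive patients.
* **Events**: independent constant-hazard competing risks per stratum;
  non-fatal events recur at the same hazard; death (cardiac or other)
  ends the history. Total per-cycle MACE probabilities range from 0.003
  (non-obstructive, low/medium risk) to 0.020 (obstructive, very high),
  split MI/stroke/HF/cardiac death as 0.35/0.15/0.30/0.20 — an assumed
  split, since the published per-type composition is supplementary-only.
* **Follow-up**: administrative censoring uniform on 60–124.8 months,
  i.e. censoring median 7.7 years with quartile spread 6.4–9.1 years.
  Observed alive time is slightly shorter because deaths truncate it.
* **Surveys**: each patient draws a baseline dose and a clinician action
  from per-stratum propensities; incompatible pairs (initiate while
  dosed, intensify off 40 mg) resolve to no change. Propensities are
  scaled analytically — once, as part of the generator's definition — so
  the expected overall change share is exactly 0.45 (real-world) or 0.39
  (guideline-compliance context).

Each cohort row carries the first event (type and month), the observed
alive time, and per-type total event counts; the totals are what the rate
estimator consumes. Passing recovery tests on these data shows the
estimators are consistent for the generating process — constant hazards,
uninformative censoring, exact stratum labels. They say nothing about
hazards that rise after an event (the real clinical situation, which the
equal-first/subsequent assumption deliberately ignores and which makes
the modelled benefit conservative), misclassified risk categories, or
informative dropout.

## Probabilistic and deterministic sensitivity analysis

The PSA samples each parameter independently: beta for utilities and
per-cycle probabilities (method-of-moments from mean and SE; SEs default
to 10% of the mean, 0.03 for utilities), gamma for costs (15%; 10% for
drug costs), lognormal for relative risks (3–4%), with `point_mass`
disabling sampling for a target. Per-stratum event probabilities are
sampled once per stratum and event type and applied to every alive
from-state, preserving the equal-first/subsequent structure. Management
change shares stay deterministic: sampling a three-way action
distribution would need a Dirichlet family outside the conventional
beta/gamma/lognormal triplet, and price variation is already explored
deterministically. Draws violating any parameter invariant are resampled
and counted; a resample rate above 10% aborts. Each draw re-runs both
arms on the same parameters; the CEAC reports the fraction of draws with
strictly positive net monetary benefit per threshold (ties count as not
cost-effective, a measure-zero convention). The tornado analysis moves
one parameter at a time to its bounds and sorts by ICER spread, skipping
bounds that violate invariants.

ICER handling: dominant (ΔC<0, ΔQ>0) and dominated (ΔC>0, ΔQ<0) results
carry flags instead of numbers; ΔQ = 0 yields a `zero_delta_q` flag and
no division. Scenario 3 (non-obstructive only) renormalises the stratum
weights after dropping obstructive strata. Scenario 1 swaps in the
guideline-compliant baseline management and change shares for both arms'
management context.

## Numerical and engineering choices

Transition rows store only off-diagonal probabilities; the stay
probability is the residual, so rows sum to one by construction and an
adjusted row exceeding one raises an invalid-rate error naming the row.
`evaluate_strategies` runs all unique stratum x treatment chains in one
batched pass over the 120 cycles (embedding 6-state obstructive chains in
the canonical 7-state space); the public single-branch `run_cohort` is
the reference implementation, asserted equal to the batched path and
validated against an independent individual-level microsimulation of the
same chain (200,000 agents, agreement within Monte-Carlo error on costs,
QALYs and occupancy).

Problem sizes used by the test suite and the acceptance script — 50,000
patients for recovery checks, 20,000 for pipeline estimation, 10,000 per
survey, 1000 PSA draws, 200,000 microsimulation agents — were chosen as
the smallest sizes at which sampling error is comfortably below the
tolerances being asserted.

## Known limitations

* The default cost/utility/transition values are illustrative; absolute
  ICERs from the defaults characterise the model, not the published
  dataset.
* No age- or sex-dependence in background mortality, utilities, or
  hazards; no tunnel states; no post-event risk escalation.
* Management changes are limited to statins and (in one scenario)
  colchicine; revascularisation pathways, downstream testing and
  medication changes over the lifetime are out of scope.
* The budget-impact perspective is not modelled.
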