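# ccta-cea

Lifetime cost-utility modelling of AI-guided cardiovascular risk
stratification after coronary CT angiography (CCTA).

CCTA is the first-line test for stable chest pain, but only about one in
five scans shows obstructive coronary artery disease (CAD), and many acute
cardiac events occur in patients without it. An AI image-analysis report
that grades each patient into a three-level risk category (low/medium,
high, very high) — combining coronary inflammation, plaque extent and
clinical factors — can trigger preventive statin changes that standard
reporting would not. This package asks the health-economic question: is
adding that analysis to every CCTA worth its price to a health system?

It is written for health-economic modellers and methods researchers: a
pure-Python library (NumPy/pandas) with a thin `ccta-cea` command-line
wrapper, designed so every stage — synthetic data, rate estimation,
decision tree, Markov engine, economics — is callable and testable on its
own.

## The model

A hybrid decision tree + population-cohort Markov model compares two arms
over a lifetime (30-year) horizon from an NHS and personal-social-services
perspective:

* **Decision tree.** Patients are cross-classified into six strata
  (obstructive / non-obstructive CAD x three AI risk categories). Under
  standard care each stratum keeps its baseline statin-dose mix; under
  AI-guided care a per-stratum share of patients *initiates*
  (0 → 40 mg atorvastatin) or *intensifies* (40 → 80 mg), calibrated to
  the observed overall change shares (45% in real-world practice, 39%
  against full guideline compliance).
* **Markov model.** Each leaf enters a 3-month-cycle chain over the states
  {no obstructive CAD, obstructive CAD, MI, stroke, heart failure, cardiac
  death, other death}; the disease-free state is dropped for obstructive
  strata. Per-cycle event probabilities follow the crude rate rule
  *p = 3 x events / life-months*, identical for first and subsequent
  events. Costs and QALYs are discounted at 3.5%/year.
* **Treatment effects.** A dose change lowers LDL by 48% (40 mg) or 53%
  (80 mg) of a 3.7 mmol/L baseline; each mmol/L multiplies MACE risk by a
  per-mmol relative risk (default 0.78), log-linearly:
  RR = 0.78^ΔLDL. Optional colchicine adds a further RR of 0.80 for
  very-high-risk patients whose statins changed.
* **Economics.** Incremental cost-effectiveness ratio
  ICER = ΔCost/ΔQALY, net monetary benefit λ·ΔQALY − ΔCost, a 1000-draw
  probabilistic sensitivity analysis with cost-effectiveness acceptability
  curve, one-way tornado analysis, and five univariate scenarios
  (guideline-compliance comparator, colchicine, non-obstructive-only,
  halved statin effect, halved reclassification).

The published supplementary cost/utility/transition tables are not
reproduced here; the shipped defaults are an internally consistent,
clinically plausible illustrative set with the documented headline
structure, and everything is overridable through a YAML configuration
file (see `ccta_cea.save_config` / `load_config`).

## Worked example

`examples/03_base_case_cea.py` runs the base case at a £700 analysis
price:

```text
AI-guided arm:      cost     8230 GBP   QALYs 11.96
standard care arm:  cost     7603 GBP   QALYs 11.83
increment:          cost      628 GBP   QALYs 0.127
ICER: 4,925 GBP per QALY gained (icer)

expected events per 5000 patients over 30 years:
        event  ai_risk  standard_care  events_averted  pct_reduction
           mi    791.3          885.0            93.7           10.6
       stroke    366.0          411.4            45.3           11.0
heart_failure    691.7          774.6            82.9           10.7
cardiac_death    515.0          580.6            65.6           11.3
  other_death   1792.4         1777.2           -15.1           -0.9
```

Reading: AI-guided management costs £628 more per patient (mostly the
analysis price, partly extra statin therapy, partly offset by averted
events) and gains 0.127 discounted QALYs, i.e. £4,925 per QALY — far
below the £20,000–30,000 threshold a UK decision-maker applies, so the
strategy is cost-effective. Roughly 94 myocardial infarctions and 66
cardiac deaths are averted per 5000 patients; other-cause deaths rise
slightly because patients spared a cardiac death live long enough to die
of something else. The remaining examples cover synthetic-data
generation, rate estimation, scenarios, PSA/CEAC and tornado analysis.

The same pipeline is scriptable from a shell:

```bash
ccta-cea simulate --n 3393 --seed 1 --out out/sim
ccta-cea estimate --cohort out/sim/cohort.csv --survey out/sim/survey.csv --out out/est
ccta-cea scenarios --out out/scenarios
ccta-cea psa --draws 1000 --seed 1 --out out/psa
```

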