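# Methods

## Model structure

The model evaluates two follow-up imaging strategies — CE-CT and 18F-FDG
PET/CT — after percutaneous ablation of colorectal liver metastases.  A
single index scan classifies each patient into one of four diagnostic
branches (TP/FN/TN/FP) from the prevalence of incomplete ablation
(base 30%) and the scan's sensitivity/specificity (CE-CT 53.4%/95.7%,
PET/CT 84.6%/92.4%).  Each branch is propagated through a Markov cohort
model with four health states:

* **No recurrence** (utility 1.0, no disease cost)
* **Hepatic recurrence only** (utility 0.65)
* **Any other recurrence** (utility 0.19)
* **Death** (utility 0, absorbing)

Cycles are one month; the horizon is 24 cycles.  Disease-state costs
($25,000/yr while in either recurrence state, pro-rated per cycle) and
utilities accrue per cycle and are discounted at 3%/yr.  Event costs: every
branch carries one index CE-CT scan ($385) at cycle 0 (the strategy layer
adds the PET/CT price differential of $990 for the PET/CT arm — this
"embedded index scan" convention is the only one that reproduces the
published strategy totals from the published branch outcomes); TP and FP add
one re-ablation ($10,229) at cycle 0; FN adds a delayed re-ablation at 1.3×
cost ($13,297.70) at the detection cycle.  Re-ablation succeeds with
probability 93%; successes start (or return to) *no recurrence*, failures
remain in *hepatic recurrence*.

Transitions per cycle: *no recurrence* → *hepatic recurrence* with the
recurrence probability (3.2%), → *other recurrence* with the branch's
metastasis probability (12% timely / 15% delayed), → *death* with
age-dependent background mortality from a life table; the recurrence states
lose mass to *death* via disease-specific mortality (5.44%) combined with
background mortality as independent competing risks, and (where the
conventions allow) regain health via remission (80%/yr).  Residual mass
stays put; an off-diagonal row sum above 1 raises an error rather than
being renormalised, because it signals inconsistent period conventions.

## Conventions and calibration

The published description leaves the period basis of most transition
probabilities, the FN detection delay, the discounting granularity and
several structural details unstated.  These are reified as an enumerated
`Conventions` dataclass, and `convention_search` ranks candidate sets by
the sum of squared relative errors against the published two-year branch
outcomes (costs, QALYs and, where reported, survival).

Calibration over the documented grid (≈77k candidate sets) shows that the
published costs and QALYs identify an internally consistent dynamics, and
the shipped defaults are that best cost/QALY fit:

* recurrence (3.2%), metastasis (12%/15%) and disease-specific death
  (5.44%) probabilities applied **per monthly cycle** as printed;
* disease-specific death only from the *other recurrence* state;
* no remission active (the 80%/yr parameter remains available as a
  convention but the published outcomes are only matched without it);
* metastases arise from both alive non-metastatic states;
* background mortality converted from annual life-table rows by
  1 − (1 − q)^(1/12);
* FN detection and delayed re-ablation at cycle 2, charged to the whole
  cohort;
* no half-cycle correction, no cohort-wide first-month utility, and
  discount factors stepped **per year** (1 for months 0–11, 1/1.03 for
  months 12–23).

Under this set the ten published cost/QALY quantities (four branches, two
strategies) reproduce within 2% (several within 0.1–0.8%), the ICER
reproduces to ≈1% ($49,056 vs the published $50,338.96), and the
complete-ablation threshold lands at 79.67% vs the published 78.14%.

Two published readouts do **not** reproduce, and no candidate in the grid
can reproduce them jointly with the costs/QALYs:

* **Two-year survival** (74.8% TN, 70% FN).  The published figures equal
  the closed form (1 − p_mets)² · (1 − q₆₈)² to all printed digits — a
  metastasis-free-survival-style quantity with annual probability
  application — whereas the dynamics that reproduce the published costs and
  QALYs (which require roughly half the discounted person-time in the
  low-utility *other recurrence* state) imply ≈42% state-based survival.
  The two readouts are mutually inconsistent; the package reports the
  state-based survival its engine computes, and
  `validation.reproduction_report()` tabulates the residual instead of
  hiding it.
* **Tornado sweeps all below $100,000/QALY.**  At the default ±20% range,
  lowering PET/CT sensitivity by 20% pushes the ICER to ≈$170k even when
  the aggregation uses the published branch outcomes themselves, so the
  published all-below-threshold claim must rest on narrower, unprinted
  ranges.  The corresponding acceptance test documents this and fails by
  design.

Because the survival residual is irreducible, the shipped default is the
best *cost/QALY* fit rather than the arg-min of the full search score
(which would trade several percent on every cost for a survival readout
that still misses by >8 points).

## Parameters

All inputs live in a validated `ParameterSet` (2019 USD, US health-system
perspective): prevalence 0.30; the four test accuracies; scan costs
$385/$1,375; re-ablation $10,229 (delayed ×1.3); cancer care $25,000/yr;
utilities 1.0/0.65/0.19/0 plus a one-month post-ablation utility 0.95;
re-ablation efficacy 0.93; transition probabilities as above; discount
3%/yr; horizon 24 months; start age 68; WTP $100,000/QALY.  Ablation
procedure cost ($1,493) and hospital days (4 × $2,184/day) are carried for
completeness but the bundled re-ablation total is what the model charges —
the published FP−TN cost gap equals the bundled total exactly.  Values are
serialisable to JSON/YAML; unknown keys are rejected.

The packaged life table is a **synthetic** Gompertz stand-in approximating
US 2015 all-population annual death probabilities (q₆₈ ≈ 0.0168), stored as
a plain `age,q_annual` CSV.  Background mortality is a second-order effect
at this horizon; any life table in that format can be substituted.

## Sensitivity analyses

* **One-way/tornado**: each diagnostic parameter swept ±20% around base
  (probabilities clamped to [0, 1] with a warning), re-running both
  strategies and the ICER at each grid point; bars are ranked by ICER span.
  The range is configurable per parameter.
* **Threshold**: bisection of ICER(θ) − WTP to |bracket| < 1e-4 (tighter in
  the acceptance pipeline), with dominant/dominated regions mapped below/
  above the threshold so the crossing is well defined; validated against a
  dense grid scan.  For the prevalence parameter the result is reported as
  the complete-ablation probability 1 − p.
* **PSA**: 30,000 iterations by default.  Each uncertain parameter is drawn
  independently — beta for probabilities/utilities, gamma for costs, by
  method of moments from the mean and a standard error expressed as a
  fraction of the mean.  The published distribution column gives no
  spreads; the defaults are SE = 10% of mean (beta) and 20% of mean
  (gamma), conventional for this literature, with boundary values (utility
  1.0, zero costs) held fixed.  A beta spec whose SE implies variance ≥
  m(1−m) is shrunk with a warning.  The generator is numpy's seeded PCG64;
  results are bitwise reproducible given the seed, and seeds are recorded
  in all outputs.
* **CEAC**: fraction of iterations with higher net monetary benefit
  NMB = WTP·E − C for PET/CT over a WTP grid of $0–200,000 in $5,000 steps;
  ties count as not cost-effective.  Under the default dispersions the
  curve crosses 0.5 at ≈$52,000, consistent with the base-case ICER, and
  reaches ≈0.69 at $100,000.

## Microsimulation oracle

`microsim` re-implements the identical stochastic assumptions at patient
level: Bernoulli diagnostic classification, per-cycle categorical
transitions drawn from the same matrices, identical accrual and discounting
rules.  Per-patient RNG substreams derive from the master seed via
`SeedSequence([seed, patient_id])`, so growing *n* never reshuffles earlier
patients.  Its role is validation by Monte-Carlo convergence: the central
repository property asserts branch means of cost, QALYs and survival within
3 standard errors of the cohort engine at n = 100,000, plus pointwise
Kaplan-Meier-style agreement of the survival curve.  The simulator emulates
exactly what the cohort model assumes — independent identical patients, no
parameter heterogeneity, no real-world effects (verification bias,
inter-reader variability, treatment switching) — so agreement validates the
numerics, not clinical realism.

## Numerical choices and edge cases

Cycle-0 event costs carry discount factor 1.  The FN detection event
treats the mass in *hepatic recurrence* at that cycle as detected: it is
re-ablated (success split), charged per the cost-scope convention, and
spends that cycle at the post-ablation utility; in event cycles utilities
accrue on start-of-cycle states so the cohort and patient engines agree
exactly in expectation.  Half-cycle correction, when enabled, averages
start- and end-of-cycle occupancy for state accruals only (never event
costs).  ICERs are always computed from unrounded values; dominance is
flagged instead of returning a signed ratio when the cost and effect
differences disagree in sign; equal effects yield an explicit
undefined-ICER signal rather than a division error.  Convention ranking
breaks ties lexicographically on the dataclass encoding, making the search
deterministic.

## Problem sizes

Default analyses run the full published scale: 24 monthly cycles, 30,000
PSA iterations, 100,000-patient microsimulation per branch in the oracle
check.  Unit tests use smaller n (a few thousand) for the same statistical
checks; the 3-SE criteria are n-aware, so the scale choice affects power,
not correctness.

## Known limitations

The model stops at 24 months (no lifetime extrapolation), has no tunnel
states beyond the one-month post-ablation utility, samples PSA parameters
independently (no correlation structure), treats MRI as out of scope, and
inherits the published analysis's internal inconsistencies documented
above.  Costs are 2019 USD with no inflation adjustment.
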