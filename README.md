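# petct-cea

Cost-effectiveness model of **18F-FDG PET/CT versus contrast-enhanced CT
(CE-CT)** for follow-up imaging after percutaneous ablation of colorectal
liver metastases (CRLM).

After thermal ablation of CRLM, surveillance imaging must detect residual or
locally progressing tumour early enough for a timely re-ablation.  PET/CT is
more sensitive than CE-CT (84.6% vs 53.4% in the model's base case) but
costs substantially more per scan ($1,375 vs $385).  This package asks, from
a US health-system perspective: is the extra scan cost worth the extra
quality-adjusted life years (QALYs)?

It is written for health-economics and HTA practitioners: everything — the
diagnostic decision tree, the Markov cohort engine, deterministic and
probabilistic sensitivity analyses, and a patient-level microsimulation used
as an internal validation oracle — is a tested, configurable Python library
with a thin CLI.

## The model

A follow-up scan classifies each patient by the prevalence of incomplete
ablation *p* and the scan's sensitivity/specificity (Se, Sp) into four
branches:

    P(TP) = p·Se      P(FN) = p·(1−Se)
    P(TN) = (1−p)·Sp  P(FP) = (1−p)·(1−Sp)

Each branch feeds a monthly-cycle Markov cohort model over 24 cycles with
four states — *no recurrence*, *hepatic recurrence only*, *any other
recurrence*, *death* — accruing discounted (3%/yr) costs and QALYs.
True positives are re-ablated immediately (93% success, $10,229); false
negatives are re-ablated after a detection delay at 1.3× cost; false
positives pay for an unnecessary re-ablation but follow disease-free
dynamics.  Strategies are compared by the incremental cost-effectiveness
ratio

    ICER = (C₁ − C₀) / (E₁ − E₀)   [USD per QALY]

against a willingness-to-pay (WTP) of $100,000/QALY, and by the
cost-effectiveness acceptability curve (CEAC) from 30,000-iteration
probabilistic sensitivity analysis with beta/gamma parameter distributions.

Several period conventions of the original analysis are not stated
(per-cycle vs per-year probabilities, detection delay, discount
granularity, ...).  They are explicit, enumerable `Conventions`, and
`convention_search` calibrates them against the published branch outcomes;
the shipped defaults are the calibrated set.  See `docs/methods.md` for the
full account, including which published quantities do *not* reproduce and
why.

## Worked example

```sh
$ petct-cea basecase --defaults --out results/
CE-CT : $28,737.54  0.745 QALYs
PET/CT: $29,345.05  0.758 QALYs
ICER  : $49,055.60/QALY (tradeoff)
```

Over two years an average CE-CT-followed patient costs $28,737.54 and
accrues 0.745 QALYs; PET/CT costs $607.51 more and yields 0.0124 more
QALYs, i.e. about $49,056 per additional QALY — cost-effective at the
$100,000/QALY threshold.

```sh
$ petct-cea threshold --defaults --param p_incomplete_ablation --wtp 100000 --out results/ --force
complete-ablation threshold: 79.6661%
```

If ablation succeeds completely in more than ~79.7% of patients, too few
lesions remain for PET/CT's sensitivity advantage to justify its price and
the ICER exceeds the WTP.

```sh
$ petct-cea psa --defaults --n 2000 --seed 7 --out results/ --force
PET/CT cost-effective in 70.50% of 2000 iterations at WTP $100,000
```

The same analyses are available as library calls
(`strategy_outcome`, `icer`, `threshold_find`, `run_psa`, `ceac`,
`simulate_cohort`, ...), and every subcommand writes machine-readable CSVs
plus a `manifest.json` recording parameters, conventions, seed and version.

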