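# cgmdfa

Crossover detrended fluctuation analysis (DFA) of continuous glucose
monitoring (CGM) time series, with a synthetic-cohort generator and a Cox
proportional-hazards stage linking crossover characteristics to the risk
of developing type 2 diabetes.

## The problem and the method

A CGM sensor samples interstitial glucose every 5 minutes; a clean 24-hour
trace has N = 288 points G_1 … G_288. The trace is analysed without
cumulative-sum pre-treatment: for each window size n in the fixed sequence

    n ∈ {3, 4, 6, 8, 9, 12, 16, 18, 24, 32, 36, 48, 72, 96, 144, 288}

(all divisors of 288, i.e. windows of 15′ up to 1440′), the series is
partitioned into N/n consecutive windows, a least-squares line ŷ_n(k) is
fitted within each window, and the fluctuation function is the RMS residual

    F(n) = sqrt( (1/N) Σ_k (y_k − ŷ_n(k))² ).

The 16 points (ln n, ln F(n)) form a log–log curve. Its overall slope is
the global scaling exponent α. Healthy glucose regulation shows a *scaling
crossover*: a steep short-window limb (exponent `dfa1`, trend build-up
before the insulin response engages) breaking to a flat long-window limb
(`dfa2`, decorrelation once counter-regulation acts). The crossover is
located by exhaustive two-limb regression: for every admissible split
k ∈ {4, …, 11} an OLS line is fitted to points 1..k and k+1..16, the pair
is scored by the point-count-weighted combined R²

    R²_comb = (k·R²_1 + (16−k)·R²_2) / 16,

and the best pair is kept. The limb intersection abscissa x gives the
crossover point in minutes, `5·e^x`; the angle between limbs is
`arctan(dfa1) − arctan(dfa2)`. A delayed (larger) crossover and a blunted
(smaller) angle indicate sluggish counter-regulation. The survival stage
fits a Cox model h(t|x) = h₀(t)·exp(x·β) by Newton–Raphson on the Breslow
partial likelihood, written from scratch, and reports hazard ratios such
as exp(30·β) per 30-minute crossover delay.

Because no patient data ship with the package, a synthetic module
generates traces with a known fast-regulation timescale (a smooth
second-order mean-reverting component, plus meals, circadian drift and
sensor noise) and cohorts whose diabetes-onset hazard rises with that
timescale, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from cgmdfa import (generate_cohort, cohort_records, records_frame,
                    cox_fit, hazard_ratio_per, incidence_rate)

cohort = generate_cohort(n_patients=206, seed=1)     # study-sized cohort
records = cohort_records(cohort)                     # full per-patient pipeline
df = records_frame(records)

print("median crossover (min):", round(df.crossover_minutes.median(), 1))
print("median angle (rad):   ", round(df.angle_rad.median(), 2))
print("events:", int(df.event.sum()))

fit = cox_fit(records, ["crossover_minutes"])
print("beta per minute:", round(fit.beta[0], 4), " p =", round(fit.p[0], 4))
print("HR per 30-min delay:", round(hazard_ratio_per(fit, "crossover_minutes", 30), 2))
```

Output:

```
median crossover (min): 162.7
median angle (rad):    0.5
events: 14
beta per minute: 0.0093  p = 0.0087
HR per 30-min delay: 1.32
```

So in this simulated cohort of 206 patients a 30-minute delay in the
scaling crossover multiplies the diabetes-onset hazard by about 1.3, and
the association is significant at the 5% level — the qualitative pattern
the method is designed to detect. `incidence_rate(18, 206, 1.5)` → 58.25
events per 1000 patient-years is the corresponding crude-incidence
arithmetic at the study's scale.

A command-line interface mirrors the stages: `cgmdfa simulate` writes a
synthetic cohort as CSVs, `cgmdfa dfa` / `cgmdfa crossover` analyse one
trace, and `cgmdfa survive` fits the Cox model from metrics + cohort
tables. See `cgmdfa --help`.

## Layout

- `cgmdfa.preprocess` — CGM CSV reading, 24-h window selection, gap interpolation
- `cgmdfa.dfa` — fluctuation function, 16-point curve, global exponent
- `cgmdfa.crossover` — two-limb piecewise fit, crossover point and angle
- `cgmdfa.metrics` — mean/SD/CV and MAGE covariates
- `cgmdfa.synthetic` — trace and cohort generators with known ground truth
- `cgmdfa.survival` — Breslow partial-likelihood Cox fit, hazard ratios, incidence
- `cgmdfa.pipeline` / `cgmdfa.cli` — per-patient glue and the console script

Methodological details, parameter choices and known limitations are in
`docs/methods.md`.
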