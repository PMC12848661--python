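# recurms

Recurrent-event multistate analysis for two-arm clinical trials, built
around the illness–death model with recovery: patients move between
*alive at home* (state 0) and *in hospital* (state 1) any number of
times before the absorbing state *dead* (state 2), under heavy right
censoring. The package is for biostatisticians who want to go beyond
time-to-first-event analysis when a trial records every hospitalization
and death — for example aftercare trials in chronic heart failure, where
a patient may be rehospitalized a dozen times during follow-up.

## What it computes

For transitions *h → j* with hazards λ<sub>hj</sub>(t), the package
provides, per treatment arm:

* **Nelson–Aalen** cumulative transition hazards
  Λ̂<sub>hj</sub>(t) = Σ<sub>t<sub>k</sub>≤t</sub> d<sub>hj</sub>(t<sub>k</sub>)/Y<sub>h</sub>(t<sub>k</sub>),
  which in a non-Markov model under random censoring estimate
  cumulative *partly conditional transition rates*;
* **Kaplan–Meier** survival for first-event analyses;
* the **Aalen–Johansen** matrix product
  P̂(s,t) = ∏<sub>u∈(s,t]</sub>(I + ΔΛ̂(u)) and with it the state
  occupation probabilities Q̂<sub>l</sub>(t), consistent under random
  censoring even when the Markov property fails;
* marginal summaries: the **expected number of hospitalizations**
  μ̂(t) = Σ<sub>u<sub>k</sub>≤t</sub> Q̂<sub>0</sub>(u<sub>k</sub>−)·ΔΛ̂<sub>01</sub>(u<sub>k</sub>),
  the **average length of hospital stay** ∫<sub>0</sub><sup>t</sup>Q̂<sub>1</sub>(u)du,
  and the between-arm ratio **RR(t)** of hospitalizations per expected
  days alive, with basic (subject-resampling) bootstrap intervals;
* from-scratch semiparametric engines: the **Cox / Andersen–Gill**
  stratified Breslow partial likelihood with model-based and robust
  cluster-sandwich covariance (stratifying by the number of previous
  events gives **Prentice–Williams–Peterson**), and the **Ghosh–Lin**
  IPCW proportional-rates model for recurrent events stopped at death;
* **Markov-property diagnostics**: Wald tests of a
  previous-hospitalization-count or state-entry-time covariate, and a
  replication pipeline that calibrates these tests over a grid of nine
  data-generating scenarios (Markov / frailty / entry-time-dependent ×
  random / state-dependent censoring × illness–death / progressive).

The simulator generates trial-scale cohorts (600 subjects, 300 per arm)
from nested competing-risks experiments with constant daily baseline
rates 0.002 (admission), 0.0007 (death at home), 0.004 (discharge),
0.00075 (death in hospital), exponential or state-dependent censoring,
and optional treatment effects on the admission hazard.

## Worked example

`examples/04_semiparametric_models.py` simulates one trial with a true
admission hazard ratio of 0.85 for the treated arm and fits the three
recurrent-event models:

```
model   HR/RR           95% CI        p
AG      0.953 [0.813, 1.118]   0.5559
PWP     0.952 [0.818, 1.109]   0.5311
GL      0.949 [0.782, 1.151]   0.5942

events used: 659 | PWP strata: 10
```

All three models agree that this particular dataset shows a protective
but non-significant point estimate (single trials at this effect size
are underpowered — the replication grid puts the power near 30–60%).
The nonparametric view of the same data
(`examples/03_nonparametric_summaries.py`):

```
arm 0: Lambda01(1000) = 2.007   P(in hospital) = 0.186   P(dead) = 0.519
         mu(1000) = 1.033 expected hospitalizations,  ALOS(1000) = 182.2 days
arm 1: Lambda01(1000) = 1.909   P(in hospital) = 0.159   P(dead) = 0.522
         mu(1000) = 0.990 expected hospitalizations,  ALOS(1000) = 168.8 days
RR(1000) = 0.963 (treated hospitalizations per day alive, relative to control)
treated mu(1000) 95% basic bootstrap CI: [0.869, 1.103]
```

i.e. by day 1000 a control patient has on average 1.03 hospitalizations
and 182 hospital days; the treated arm has slightly fewer of both while
mortality is balanced, so the reduction is not explained by earlier
death. The other examples cover building event histories from raw
admission/discharge times (`01`), the scenario simulator (`02`), and
the Markov diagnostics (`05`).

A thin CLI wraps the long-running grids:

```sh
recurms simulate --scenario 2 --reps 10 --seed 1 --out scratch/sim
recurms table2 --reps 1000 --seed 0 --out table2.csv
recurms power  --reps 1000 --seed 0 --out power.csv
```

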