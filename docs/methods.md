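# Methods

## The multistate model

Follow-up of a trial patient is a right-continuous path X<sub>t</sub>
through {0 = alive at home, 1 = in hospital, 2 = dead}, observed from
randomization (day 0, everyone at home) until death or right
censoring. Times are continuous and measured in days. The transition
hazard λ<sub>hj</sub>(t; F<sub>t−</sub>) may in general depend on the
whole observed past; the *Markov* assumption restricts it to the
current state and time. Two structural views of the same record set
are supported: the illness–death model with recovery (three states,
back-transitions allowed) and its progressive expansion, where each
state is indexed by the cumulative number of prior hospital stays
(R1, H1, R2, …, D) so that hazards may depend on the event count while
remaining Markov. Progressive labels are derived from the running
count; they are never stored.

Data are kept in counting-process long format, one row per sojourn:
`(id, from, to, start, stop, status)` plus covariates (at minimum the
randomized arm `Z`). Censoring is a status flag, never a state. Risk
sets use the predictable (left-limit) convention: a subject leaving a
state at `t` is still at risk there at `t`. Within-subject zero-length
sojourns are rejected; ties across subjects are allowed and processed
as a single jump with the summed event count.

## Nonparametric estimators

All estimators are exact step functions on the observed event-time
grid; nothing is smoothed or interpolated.

* **Nelson–Aalen**: increment = (observed h→j transitions at
  t<sub>k</sub>) / (subjects in h just prior to t<sub>k</sub>). In a
  non-Markov model with random censoring this estimates the cumulative
  *partly conditional* transition rate (conditioning on the current
  state only), which is the quantity the simulation study probes.
* **Aalen–Johansen**: finite matrix product of (I + ΔΛ̂(u)) with
  diagonal entries −Σ row off-diagonals. Row sums are asserted to be 1
  within 1e−10 at construction. Its start-at-0 row gives occupation
  probabilities Q̂<sub>l</sub>(t), consistent under random censoring
  without the Markov property.
* **Marginal mean** μ̂(t) = Σ Q̂<sub>0</sub>(u<sub>k</sub>−)
  ΔΛ̂<sub>01</sub>(u<sub>k</sub>). The left limit makes the summand
  predictable and yields an exact identity on fully observed data:
  μ̂(t) equals the mean observed admission count, just as uncensored
  Aalen–Johansen occupation equals the empirical state fraction and the
  integrated hospital-occupation curve equals mean observed hospital
  days. These identities are tested at machine precision.
* **RR(t)**: ratio across arms of μ̂(t) / ∫<sub>0</sub><sup>t</sup>(1 −
  Q̂<sub>2</sub>(u))du — hospitalizations per expected days alive.
* **Basic bootstrap**: subjects (clusters) are resampled with
  replacement; limits are 2θ̂ − q<sub>1−α/2</sub>, 2θ̂ − q<sub>α/2</sub>
  of the bootstrap distribution. Closed-form (Greenwood-type) variances
  are deliberately not provided; the bootstrap is the single uncertainty
  mechanism for the nonparametric summaries.

## Semiparametric engines

The Cox engine maximizes the stratified Breslow partial likelihood on
start–stop data by Newton's method (step-halving on overshoot,
convergence when the relative log-likelihood change falls below 1e−9,
at most 25 iterations). Risk-set sums at all event times are
accumulated with difference arrays and prefix sums, so one iteration is
O(rows + events) per stratum. Breslow ties only: the simulated data
are continuous, and user data with heavy ties deserve a deliberate
choice rather than a silent default. Covariates are centered
internally for conditioning; reported baselines are rescaled to
covariate value zero.

One engine serves three models: cause-specific Cox (single event per
subject), Andersen–Gill (recurrent admissions, subjects leave the
admission risk set while hospitalized and re-enter at discharge), and
Prentice–Williams–Peterson on the total-time scale (strata = number of
previous hospitalizations; gap-time PWP is not offered). The robust
covariance is the cluster-by-subject sandwich of score residuals; it is
the default for all treatment tests on recurrent outcomes, with the
model-based covariance available by flag. On single-spell,
correctly-specified data the two agree, which is tested.

Degenerate fits are never returned silently: a diverging coefficient,
a singular information matrix, or a model standard error spanning an
absurd range on the covariate's own scale (SE × covariate range > 50,
the signature of a monotone likelihood / complete separation) raises
`MonotoneLikelihoodError`. The replication pipeline counts such
replications as non-rejections and reports them.

The Ghosh–Lin proportional-rates model treats death as a terminal
event of the *marginal* rate: dead subjects stay in the weighted risk
set with a frozen weight and dN = 0, while censoring removes subjects
and is compensated by inverse-probability-of-censoring weights
1/Ĝ(min(t, T)−) from a Kaplan–Meier of the censoring distribution
(pooled over arms, since censoring is arm-independent in every
scenario; an arm-specific curve would be a one-line change). The
sandwich variance treats the weights as known — slightly conservative.
Near the end of follow-up Ĝ approaches zero and a handful of events
carry enormous weights; the optional `tau` argument restricts the
estimating equation to [0, τ], and the fit refuses to run if Ĝ reaches
zero before the last event used. Weight trimming and multiple
imputation of censoring times are out of scope. Without deaths and
censoring all weights are one and the estimating equation coincides
with Andersen–Gill on full-follow-up risk intervals; this algebraic
reduction is verified numerically to 1e−8.

## The scenario simulator

The generator emulates a two-arm aftercare trial with recurrent
hospitalizations: 600 subjects, exactly 300 per arm (assignment by
permutation, not coin flips), simulated by nested competing-risks
experiments. From the current state, a sojourn is drawn with the
combined hazard of all active causes (inversion method: standard
exponential divided by the total rate) and an independent categorical
draw picks the cause proportionally to its rate; the clock restarts in
the next state. Constant daily baseline rates: λ<sub>01</sub> = 0.002,
λ<sub>02</sub> = 0.0007, λ<sub>10</sub> = 0.004, λ<sub>12</sub> =
0.00075. Under these conditions a typical dataset has ~700 admissions,
~210–285 censored subjects, and a busiest subject with 8–12 stays.

The nine null scenarios cross three mechanisms:

1–4. Illness–death with recovery; scenarios 2 and 4 add a
  subject-level gamma frailty multiplying all four event hazards;
  scenarios 3 and 4 replace random exponential censoring (rate 0.00045,
  one draw per subject, applied when it precedes death) by
  *state-dependent* censoring: a third competing risk with hazard
  0.00045·(1 + 0.05·k), k = number of previous states. State-dependent
  censoring is independent but not random, which is exactly what breaks
  partly-conditional-rate estimation in non-Markov models.

5–8. Progressive analogues: every event hazard is additionally
  multiplied by (1 + 0.1·k), so the truth is Markov on the expanded
  state space for 5 and 7.

9. Progressive with state-entry-time-dependent hazards (no frailty,
  state-dependent censoring, in-hospital death base rate 0.0011): each
  event hazard is multiplied by (entry time into the current state)/1000.

Two corner cases of these rate specifications are degenerate and were
resolved as follows, as deliberate design choices:

* **Frailty normalization.** The frailty is gamma with shape 2,
  *scale 1/2*, i.e. normalized to mean one — the standard
  identifiability convention. A mean-2 multiplier would double the
  population event rates and make the pooled 0→1 rate *start above*
  the Markov reference line 0.002·t; the mean-one version keeps the
  population time scale of the non-frailty scenarios and produces the
  intended signature of unobserved heterogeneity: a concave pooled rate
  bending below the straight line as high-frailty subjects are selected
  out.
* **Entry-time factor at time zero.** The factor (entry/1000) is zero
  for the initial state entered at day 0, which would freeze every
  subject at study start. It is therefore anchored at 1 for the
  time-0 state and applied literally everywhere else. The resulting
  within-risk-set contrast (hazard proportional to entry time among
  subjects at risk at the same calendar time) is what gives the
  entry-time Markov test its essentially saturated power in scenario 9.

Both resolutions shift the censoring mix somewhat: the frailty and
entry-time scenarios censor on average ~250–285 of 600 subjects versus
~210–245 in the plain scenarios, because survivors of a selection
mechanism are systematically slower and remain exposed to censoring
longer. We accepted this rather than distort the scenario rate
constants, since the study's estimands (rejection counts, bias
directions) are insensitive to it.

Treatment alternatives multiply the treated arm's admission hazard by
exp(−0.1625) (hazard ratio 0.85) in every scenario; censoring never
depends on arm or frailty.

Reproducibility: each (master seed, scenario, replication) triple seeds
an independent `numpy` PCG64 substream via `SeedSequence`, so any
replication can be regenerated in isolation and results are independent
of execution order. `simulate_subject` and `simulate_dataset` share one
vectorized engine.

### What the generator does and does not emulate

It reproduces the structure of a long-running heart-failure aftercare
trial — recurrent admissions with discharges, a terminal state, heavy
(~35–45%) right censoring, up to ~a dozen stays for the busiest
subject. It does **not** emulate covariates beyond treatment, seasonal
or calendar-time effects, non-exponential sojourns within a state,
administrative study closure (no common horizon), interval censoring,
or dependence of censoring on covariates. Tests passing under this
generator therefore certify the estimators' contracts and the
documented biases, not robustness to every feature of real registry
data.

## The replication pipeline

For each scenario the pipeline simulates a dataset, builds the at-home
risk intervals, fits the scenario's model — Andersen–Gill for
illness–death scenarios, PWP for progressive ones, robust SEs
throughout — and Wald-tests each covariate at the 5% level. Model 1
contains treatment plus the Markov covariate (previous-hospitalization
count for AG, entry time in days for PWP); model 2 contains treatment
only. Null calibration uses 1000 replications per scenario; the
summary-statistics pass uses 200 datasets per scenario and the
alternative-power pass 250, scaled to a per-1000 basis — sizes chosen
so the full recomputation stays in the minutes range on one core while
keeping binomial Monte-Carlo error a few counts wide. Non-converged
fits are counted as non-rejections and reported, never dropped.

## Known limitations

* No Fine–Gray, proportional-odds, pseudo-value, or frailty
  *regression* models; no gap-time PWP; no time-varying coefficients.
* No landmark (s > 0) transition-probability estimators for non-Markov
  models beyond reading the Aalen–Johansen product as a
  partly-conditional object.
* The Ghosh–Lin variance ignores the estimation of the censoring
  curve, and IPCW instability near the end of follow-up must be
  handled via `tau` rather than weight trimming.
* The bootstrap is percentile-based ("basic" limits); no studentized
  or BCa variants.
* An open hospital stay at a user's administrative study closure can be
  encoded as censoring from either state; the package takes no stance.
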