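"""Semiparametric treatment-effect models for recurrent hospitalizations.

One simulated trial, three models on the same data:
  * Andersen-Gill (AG): intensity model, subjects re-enter the risk set
    after each discharge (robust cluster standard errors);
  * Prentice-Williams-Peterson (PWP): AG stratified by the number of
    previous hospitalizations;
  * Ghosh-Lin (GL): marginal rate model stopped at death, IPCW weights.
"""

from recurms import (ModelSpec, cox_fit, get_scenario, ghosh_lin_fit,
                     simulate_dataset, wald_test)
from recurms.markov import hospitalization_long_data

history = simulate_dataset(get_scenario("alt-1", seed=7), rep=0)
long = hospitalization_long_data(history)

ag = cox_fit(long, ModelSpec(covariates=("Z",)))
pwp = cox_fit(long, ModelSpec(covariates=("Z",), strata="prev_events"))
gl = ghosh_lin_fit(history, tau=2500.0)

print(f"{'model':<6} {'HR/RR':>6} {'95% CI':>16} {'p':>8}")
for name, fit in (("AG", ag), ("PWP", pwp), ("GL", gl)):
    w = wald_test(fit, "Z")
    print(f"{name:<6} {w.hr:6.3f} [{w.ci_low:.3f}, {w.ci_high:.3f}] "
          f"{w.p:8.4f}")

# The data were generated with a true admission hazard ratio of 0.85 for
# the treated arm; all three models should estimate a ratio below one,
# with GL on the (marginal) rate scale rather than the intensity scale.
print("\nevents used:", ag.n_events, "| PWP strata:", len(pwp.baseline))
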