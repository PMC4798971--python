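"""Two-stage maximum-likelihood fitting on a synthetic session.

Simulates a full session at known parameters, tabulates the 4- and
16-category counts, and refits both stages from scratch.  Uses a reduced
number of optimizer starts so the example runs in a few minutes.
"""

import numpy as np

from racemind import (ConfidenceCriterion, FitConfig, RaceParams,
                      RevisionParams, SessionDesign, counts_from_trials,
                      fit_initial, fit_revision, simulate_trials)

truth = dict(kappa=13.64, bound=0.74, tnd_mean=0.461, theta=0.89,
             t_pip=0.30, d1=0.2, d2=0.1, d3=-0.2)
params = RaceParams(kappa=truth["kappa"], bound=truth["bound"],
                    tnd_mean=truth["tnd_mean"], tnd_sd=0.06)
crit = ConfidenceCriterion(truth["theta"])
rev = RevisionParams(truth["t_pip"], truth["d1"], truth["d2"], truth["d3"])

df = simulate_trials(params, crit, rev, SessionDesign(), seed=42)
data = counts_from_trials(df)
print(f"simulated {int(data.counts4.sum())} trials; "
      f"{df.attrs['n_censored']} censored at the 5 s cap")

cfg = FitConfig(dt=0.01, n_loser=61, n_starts=2, seed=3, maxfev=400)
res1 = fit_initial(data, cfg)
print("\nstage 1 (kappa, bound, mu_tnd, theta):")
for k in ("kappa", "bound", "tnd_mean", "theta"):
    print(f"  {k:8s} fit {res1.params[k]:7.3f}   truth {truth[k]:7.3f}")

res2 = fit_revision(data, res1, cfg)
print("\nstage 2 (t_pip, dtheta_1..3), stage-1 estimates carried fixed:")
for k, t in (("t_pip", truth["t_pip"]), ("d1", truth["d1"]),
             ("d2", truth["d2"]), ("d3", truth["d3"])):
    print(f"  {k:8s} fit {res2.params[k]:7.3f}   truth {t:7.3f}")
print(f"\nstage-2 NLL at optimum: {res2.nll:.1f}")

# Initial-stage parameters recover to a few percent at ~9000 trials; the
# post-initiation shifts recover within their sampling error (d3, informed
# only by rare double changes, is the least constrained).
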