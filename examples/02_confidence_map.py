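"""From decision state to confidence: the log-odds-correct belief map.

Evaluates the mapping (elapsed time, evidence balance) -> log-odds that the
leading direction is correct, shows the payoff-optimal criterion, and prints
the predicted 4-way initial outcome breakdown per motion strength.
"""

import numpy as np

from racemind import (ConfidenceCriterion, RaceParams, build_belief_map,
                      initial_outcome_probs, optimal_criterion,
                      probability_equivalent)
from racemind.simulate import COHERENCE_SET

params = RaceParams(kappa=13.64, bound=0.74, tnd_mean=0.461, tnd_sd=0.06)
bmap = build_belief_map(params, COHERENCE_SET)

opt = optimal_criterion([[2, -3], [1, -1]])  # high-risk vs low-risk payoffs
print(f"payoff-indifferent belief criterion: log-odds {opt:.2f} "
      f"(P = {probability_equivalent(opt):.3f})")
crit = ConfidenceCriterion(0.89)  # a fitted observer is slightly risk-averse
print(f"fitted criterion 0.89 -> P = {probability_equivalent(0.89):.2f}\n")

print("same balance, different elapsed time -> different belief:")
for t in (0.2, 0.5, 1.0):
    print(f"  log-odds(t={t:.1f} s, balance=0.8) = "
          f"{float(bmap.log_odds(t, 0.8)):+.3f}")

print("\ncoherence  P(corr,hi)  P(corr,lo)  P(err,hi)  P(err,lo)  mean RT")
for c in (0.0, 0.064, 0.256, 0.512):
    pred = initial_outcome_probs(params, crit, bmap, c)
    ch, cl, eh, el = pred.probs
    print(f"  {c:5.3f}   {ch:9.4f}  {cl:9.4f}  {eh:9.4f}  {el:9.4f}"
          f"   {pred.mean_rt:.3f}")

# Belief falls with elapsed time at a fixed balance (slow decisions are less
# reliable), and high-confidence errors appear at the stronger coherences.
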