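"""Post-initiation processing: predicted changes of decision and confidence.

Continues accumulation for t_pip after the initial commitment, classifies
the final belief into shifted zones, and prints the conditional revision
probabilities the model predicts, alongside a matched simulation.
"""

import numpy as np

from racemind import (ConfidenceCriterion, RaceParams, RevisionParams,
                      SessionDesign, build_belief_map, final_zone_thresholds,
                      outcome_table, simulate_trials)
from racemind.simulate import COHERENCE_SET

params = RaceParams(kappa=13.64, bound=0.74, tnd_mean=0.461, tnd_sd=0.06)
crit = ConfidenceCriterion(0.89)
rev = RevisionParams(t_pip=0.395, d1=0.77, d2=0.24, d3=-0.36)
bmap = build_belief_map(params, COHERENCE_SET)

print("final-report zone thresholds (log-odds, axis toward initial choice):")
for conf in ("high", "low"):
    up, mid, lo = final_zone_thresholds(crit, rev, conf)
    print(f"  after an initial {conf:4s} choice: {up:+.2f} / {mid:+.2f} / {lo:+.2f}")

cs = sorted(set(abs(c) for c in COHERENCE_SET))
ot = outcome_table(params, crit, rev, bmap, cs)
dec, conf_rate = ot.change_rates()
print("\ncoherence  P(chg dec|err)  P(chg dec|corr)  P(chg conf|low)  "
      "P(chg conf|high)")
for i, c in enumerate(cs):
    print(f"  {c:5.3f}     {ot.p_change_decision('error')[i]:10.4f}"
          f"      {ot.p_change_decision('correct')[i]:10.4f}"
          f"      {ot.p_change_confidence('low')[i]:10.4f}"
          f"       {ot.p_change_confidence('high')[i]:10.4f}")

df = simulate_trials(params, crit, rev, SessionDesign(), seed=1, bmap=bmap)
sim_dec = (df.init_choice != df.final_choice).mean()
sim_conf = (df.init_conf != df.final_conf).mean()
print(f"\nsimulated session ({len(df)} trials): "
      f"{100 * sim_dec:.1f}% changes of decision, "
      f"{100 * sim_conf:.1f}% changes of confidence")

# Errors are revised far more often than correct choices (the continuing
# evidence stream opposes them), and confidence is revised more often than
# the direction decision — both single-digit-percent effects overall.
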