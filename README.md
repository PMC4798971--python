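# racemind

An anti-correlated race model of choice, reaction time, confidence, and
changes of mind, with analytic first-passage machinery and full synthetic
pipelines for the reach-to-target random-dot motion task.

## The problem

In reaction-time perceptual decisions the observer controls when to stop
deliberating: noisy momentary evidence is accumulated to a bound, and the
same accumulated evidence, together with the elapsed deliberation time,
supports a graded sense of confidence.  When the report is a reach that
expresses direction and confidence simultaneously, the hand sometimes
changes course mid-flight — the observer revises the direction decision,
the confidence, or both.  Because sensory and motor latencies leave a few
hundred milliseconds of evidence in the processing pipeline at movement
onset, such revisions can be explained by *continuing* the very process
that produced the initial report.  The package exists to state that model
precisely, solve it analytically, fit it, and reproduce the analyses built
on it — including the apparent confidence–accuracy dissociation that
post-decision processing creates.

## The model

Two accumulators race: with signed coherence $C$, the rightward accumulator
has drift $+\kappa C$ and the leftward one $-\kappa C$, each with unit
diffusion variance per second and noise correlation
$\rho \in (-1, 0]$ (default $-\cos(\pi/4) \approx -0.71$).  The first to
reach the shared bound $B$ commits the choice at decision time $t_{dec}$;
reaction time adds a Gaussian non-decision time
$\mathcal{N}(\mu_{tnd}, \sigma_{tnd}^2)$.  For $\rho = -\cos(\pi/k)$ the
survival density has an exact method-of-images solution: whitening maps the
domain to a planar wedge of angle $\pi/k$, whose dihedral reflections give
a signed sum of $2k-1$ Gaussian propagators (3, 5, 7 images for
$\rho = 0, -0.5, -\cos(\pi/4)$), with drift restored by an exact Girsanov
tilt.

The decision state maps to belief: with the winner pinned at $B$, the
balance of evidence $\Delta$ and elapsed time $t$ give the log-odds that
the leading direction is correct, marginalized over the experimental
coherence set,

$$\mathrm{LO}(t, \Delta) = \log \frac{\sum_{c > 0} w_c\,
e^{(\kappa c \Delta - \kappa^2 c^2 t)/(1-\rho)} + w_0/2}
{\sum_{c > 0} w_c\, e^{(-\kappa c \Delta - \kappa^2 c^2 t)/(1-\rho)} + w_0/2}.$$

Confidence is high when $\mathrm{LO} \ge \theta$.  After the initial
commitment the accumulators run on, unbounded, for $t_{pip} \le \mu_{tnd}$;
the final report is read from the belief at $t_{dec} + t_{pip}$ against
three thresholds ($\theta \mp \delta\theta_1$, $-\delta\theta_2$,
$-\theta - \delta\theta_3$) that partition the axis into keep/switch ×
high/low zones, implementing hysteresis and motor-cost asymmetries.

Fitting is two-stage maximum likelihood: stage 1 fits
$(\kappa, B, \mu_{tnd}, \theta)$ to the per-coherence counts of the four
initial categories plus correct-trial mean RTs; stage 2 carries those over
fixed and fits $(t_{pip}, \delta\theta_{1..3})$ to the 16 initial-by-final
category counts.

## A worked example

```python
from racemind import (RaceParams, ConfidenceCriterion, RevisionParams,
                      SessionDesign, build_belief_map, simulate_trials,
                      counts_from_trials, fit_initial, FitConfig,
                      optimal_criterion, probability_equivalent)
from racemind.simulate import COHERENCE_SET

print(round(optimal_criterion([[2, -3], [1, -1]]), 2))   # 0.69
print(round(probability_equivalent(0.89), 2))            # 0.71

params = RaceParams(kappa=13.64, bound=0.74, tnd_mean=0.461, tnd_sd=0.06)
crit = ConfidenceCriterion(0.89)
rev = RevisionParams(t_pip=0.395, d1=0.77, d2=0.24, d3=-0.36)
bmap = build_belief_map(params, COHERENCE_SET)
df = simulate_trials(params, crit, rev, SessionDesign(), seed=1, bmap=bmap)
print(len(df))                                            # 9187
print(round((df.init_conf != df.final_conf).mean(), 3))   # 0.07
print(round((df.init_choice != df.final_choice).mean(), 3))  # 0.04
```

The first two numbers are the payoff-indifferent confidence criterion
(belief 2/3, log-odds 0.69) and the probability equivalent of a fitted
criterion of 0.89.  The simulated session (9187 of 9216 trials decide
before the 5 s cap) then shows confidence being revised more often (7% of
trials) than the direction decision (4%) — the model's signature pattern.  The scripts in `examples/` walk through
each capability (first-passage solution, belief map, change-of-mind
predictions, fitting, motion-energy kernels, behavioral statistics) and
print annotated output.

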