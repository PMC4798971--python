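# Methods

## Model

Two accumulators integrate anti-correlated momentary evidence about the net
direction of a random-dot stimulus.  With signed coherence `c` (proportion,
negative leftward) the rightward accumulator has drift `+kappa*c` per
second, the leftward `-kappa*c`; both diffuse with unit variance per second
(the identifiability normalization — `kappa` and the bound absorb scale)
and share noise with correlation `rho`.  The first accumulator to reach the
common flat bound `B` commits the direction choice at the decision time;
the reaction time adds a Gaussian non-decision time
`N(mu_tnd, sigma_tnd^2)` capturing sensory and motor latencies.

**Analytic solution.**  For `rho = -cos(pi/k)` with integer `k >= 2`, the
survival density of the unabsorbed process is exact by the method of
images: whitening the noise maps the region "both accumulators below `B`"
to a planar wedge of angle `pi/k`, and the dihedral reflection group of
that wedge generates `2k - 1` image sources whose signed Gaussian sum
vanishes on both walls (3 images at `rho = 0`, 5 at `-0.5`, 7 at
`-cos(pi/4)`, the default).  Constant drift is restored exactly by a
Girsanov tilt `exp[mu' S^-1 x - mu' S^-1 mu t / 2]`, which multiplies the
driftless solution and preserves the boundary condition; the tilt is folded
into each Gaussian exponent so extreme parameter points stay finite.  The
absorption flux — the joint density of decision time and the losing
accumulator's state — is the normal component of the probability current,
`-(1/2) d(density)/d(winner)` on the bound, obtained by analytic
differentiation of the image sum (never finite differences).  Flat bounds
only: collapsing bounds and reflecting lower bounds are outside this
solution family and out of scope.

**Belief.**  At decision the winner sits at `B`, so the decision state is
the pair (decision time `t`, evidence balance `Delta` = winner − loser).
The balance is a 1-D diffusion with drift `2*kappa*c` and variance rate
`2*(1 - rho)`.  A useful exact identity drives the implementation: for
constant drift, the likelihood ratio between coherences of the absorbed
event `(t, Delta)` equals the ratio of *free* balance densities — the
Girsanov tilt of the flux is `exp[(kappa*c*Delta - kappa^2 c^2 t)/(1-rho)]`
and the driftless factor is coherence-independent, so the selection induced
by the stopping rule cancels in the posterior.  The log-odds that the
leading direction is correct, marginalized over the experimental coherence
set with prior weights `w_c` (uniform over the 12 signed levels by default,
0% split across directions), is therefore an exact function of `(t, Delta)`
that serves unchanged after further unbounded accumulation: the same map,
read on a common evidence clock, gives the initial belief at `t_dec` and
the revised belief at `t_dec + t_pip`.  This makes the simulated-accuracy
calibration property exact rather than approximate: among trials mapped to
log-odds `L`, the fraction correct is `1/(1+exp(-L))` up to sampling error.
Confidence is high when the log-odds reaches the criterion `theta`
(time-invariant).  The `BeliefMap` object stores a serializable grid for
inspection and interpolation; the fitting and simulation paths always use
the exact evaluator.

**Revision.**  Evidence in the processing pipeline at movement onset
continues to accumulate, without bounds, for `t_pip` (constrained at or
below `mu_tnd`, the mean rather than the per-trial draw, since the latter
is latent).  The final report compares the belief at `t_dec + t_pip`
against three ordered thresholds on the axis oriented toward the initial
choice: `theta - d1` (after an initial high-confidence choice; `theta + d1`
after a low one), `-d2`, and `-theta - d3`, cutting the axis into
keep-high / keep-low / switch-low / switch-high zones.  Positive `d1`, `d2`
implement hysteresis; `d3 < 0` narrows the switch-high zone (double changes
require a costly reach across the workspace).  Parameter points whose
thresholds are not strictly descending are rejected as invalid.  Leftward
initial choices are handled by reflection symmetry; at 0% coherence the
post-initiation drift is zero (the stimulus is the evidence source) and the
randomly designated rewarded direction symmetrizes the outcome table.

## Fitting

Stage 1 minimizes a multinomial negative log likelihood over the four
initial categories (correct/error × high/low) per unsigned coherence plus
a Gaussian term for the correct-trial sample mean RT (all trials at 0%)
with the observed s.e.m. as its standard deviation; error-trial mean RTs
are excluded because a flat bound does not reproduce error chronometry.
Free parameters `(kappa, B, mu_tnd, theta)`; fixed: `rho = -cos(pi/4)` and
`sigma_tnd = 60 ms`.  Stage 2 carries all four stage-1 estimates over,
fixed, and fits `(t_pip, d1, d2, d3)` to the 16 initial-by-final category
counts; invalid zones and `t_pip > mu_tnd` cost +inf (a graded penalty
steers the simplex back when it wanders out).  Optimization is bounded
Nelder-Mead from random starts (rejection-sampled into the admissible zone
region for stage 2); the default configuration uses 30 starts, and the
recovery tests and examples use 2-3 wider-spaced starts with a coarser
discretization (10 ms dense time step, 61 loser-grid points), which the
noise-free recovery test shows is accurate to optimizer precision.
Probabilities are floored at 1e-10 before logs; bounds bracket the
plausible ranges with wide margin (`kappa` up to 50, `B` up to 5,
`mu_tnd` in [0.1, 1] s, `theta` up to 5, shifts in [-3, 3]).

Identifiability at realistic sample sizes: from the Fisher information of
the 16-category likelihood at a 9216-trial session, the standard errors are
about 0.017 s for `t_pip`, 0.013 and 0.024 log-odds for `d1`, `d2`, and
0.065 for `d3` — `d3` is informed only by the rare double changes, so
recovery tests allow it three standard errors.

## Numerics

- Default absorption grids: decision-time step 1 ms to 5 s; the fitting
  configuration uses a 5 or 10 ms step dense to 1.6 s and five-fold sparser
  beyond, where the flux has decayed.  The loser-state grid spans
  diffusion plus maximal drift excursion below the bound, with three
  quarters of its points in the 10 evidence units nearest the bound.
  These conserve probability within 1e-3 over the fitted parameter range;
  a worse defect triggers a warning with the achieved value.
- Predictions are conditional on the decision terminating within the time
  horizon, matching the simulator, which censors unabsorbed trials at the
  5 s cap (configurable; the task itself re-queued trials not initiated
  within 3 s) and reports the censored count.
- Threshold crossings of the belief map are found by bisection on the
  exact, strictly monotone evaluator; the inversion depends only on time
  and level, so it is shared across coherences within a likelihood
  evaluation.
- The Euler simulator (0.5 ms step, correlated increments) adds a per-step
  Brownian-bridge crossing test per accumulator; a pure end-point check
  detects absorptions late by O(sqrt(dt)), visible at the Kolmogorov-
  Smirnov tolerances the oracle tests use.  Both accumulators crossing in
  one step is an O(dt) event broken by a fair coin.

## Synthetic data

The generator reproduces the study's design: 12 signed coherence levels
(0% twice, its sign designating the rewarded direction), 768 trials per
level, ABBA target-layout blocks, truncated-exponential foreperiods
(0.5-2 s, mean 0.82 s), and the payoff matrix (+2/-3 high risk, +1/-1 low
risk, points on the final report).  Dot movies follow the three-
interleaved-set protocol: 13.3 ms frames, dots replotted every third frame,
per-dot Bernoulli(coherence) choice between a coherent 5 deg/s displacement
and random replacement, density 12.5 dots/deg^2/s in a 5-degree aperture,
and horizontally mirrored double-pass partners.  Reach trajectories are
minimum-jerk paths at 1000 Hz to the corners of a 17 × 17 cm square with a
mid-flight re-plan on change trials (uniform within the middle 60% of the
movement) and smoothed additive noise — kinematic fixtures for the change
detector, not a biomechanical model.  What the generator does not emulate:
sequential dependencies, lapses, non-stationary criteria, biomechanical
variability in the reaches, and display photometry; passing tests therefore
certify the internal consistency of model, fitting and analyses under the
model's own assumptions, not their adequacy for any particular empirical
data set.

## Analyses

Motion energy uses opponent quadrature pairs — fourth-order Cauchy spatial
filters (envelope 0.35 deg) and `(kt)^n e^{-kt}` temporal filters (k = 60/s,
orders 3 and 5) — matched to the coherent displacement; all constants sit
in `MotionFilterConfig`.  Kernels average per-trial residuals (condition
means removed; only coherences at or below 6.4% included) conditioned on
choice, confidence, or change type, aligned to stimulus onset or movement;
time bins with fewer than 10 trials are dropped.  The non-decision estimate
fits `alpha * (1 - Phi(t; mu_tnd, sigma_tnd))` convolved with the filter's
two-stroke impulse response to the movement-aligned kernel by least
squares.  The change detector reads the final target from the reach
endpoint and infers a differing initial target when the path area on the
opposite side of the vertical (direction) or horizontal (confidence)
dividing line exceeds 0.1 cm^2, accumulated from where the hand leaves the
1 cm home region with unsigned increments so backtracking cannot cancel an
excursion ("the area over the first 1 cm of movement" admits a second
reading — area within the first centimeter only — which would rarely exceed
the criterion; the adopted movement-initiation reading is switchable by
truncating the input path).  Trials faster than 150 ms are excluded
(strictly less than).  Logistic models for confidence and for choice with a
confidence interaction go through statsmodels, with separation flagged;
odds ratios `odds(high|correct)/odds(high|error)` use the initial-choice
correctness for both the initial- and final-confidence versions, with
percentile bootstrap (N = 1000) confidence intervals, exclusion of points
without errors, and a two-sided sign test across points.

## Design choices and limitations

- The correlation is exposed but defaults to `-cos(pi/4)`: of the two
  stated values for the fixed covariance ("-0.5" and "~ -0.71"), only the
  latter is consistent with a 7-image solution, and the image count is the
  operationally binding choice; `-0.5` (5 images) remains runnable.
- The package is a library with narrative example scripts rather than a
  shell tool: every pipeline entry point is an importable function, and
  `examples/` plays the role a CLI would for interactive use.
- Post-initiation accumulation is unbounded and read out once at
  `t_dec + t_pip`; no second bounded race or mid-flight termination rule is
  modeled, and the kinematics of the corrective movement are out of scope.
- Alternative confidence rules (balance-only and decision-time-only
  thresholds) are implemented for model comparison; on data simulated from
  the main model they fit worse, as expected.
- Runtime-motivated problem sizes: oracle comparisons use 1e5 paths,
  calibration 18,000 trials, recovery one 9216-trial session; these are the
  package's own test scales and can be raised freely.
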