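"""Mapping decision state and elapsed time to the log-odds of being correct.

At decision time the winning accumulator sits at the bound, so the decision
state is summarized by the balance of evidence Delta (winner minus loser)
together with the decision time t.  Under the race dynamics the balance is a
1-D diffusion with drift ``2*kappa*c`` toward the true direction and variance
rate ``2*(1 - corr)``.  For constant drift the likelihood ratio between
coherences of the full absorbed-path event (t, Delta) factorizes (Girsanov)
into ``exp[(kappa*c*Delta - kappa^2*c^2*t) / (1 - corr)]`` — identical to the
ratio of free balance densities — so the posterior probability that the
leading direction is correct, marginalized over the experimental coherence
set, is an exact function of (t, Delta).  The same factorization holds after
unbounded post-initiation accumulation, so one map serves both the initial
report and its revision, queried on a common evidence clock.

Confidence is the comparison of this log-odds with a criterion ``theta``;
the observer earns more points in expectation by choosing the high-risk
target whenever the belief exceeds the payoff-indifference point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import expit, logsumexp

from .race import AbsorptionSolution, RaceParams, absorption_flux

__all__ = [
    "BeliefMap",
    "ConfidenceCriterion",
    "InitialPrediction",
    "CATEGORIES",
    "build_belief_map",
    "initial_outcome_probs",
    "alternative_confidence_rule",
    "probability_equivalent",
    "optimal_criterion",
]

#: Initial report categories, ordered; correctness is relative to the true
#: (or, at 0% coherence, randomly designated) motion direction.
CATEGORIES = ("correct_high", "correct_low", "error_high", "error_low")


@dataclass(frozen=True)
class ConfidenceCriterion:
    """Log-odds criterion separating high- from low-confidence reports."""

    theta: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class BeliefMap:
    """Grid of log-odds that the leading-direction choice is correct.

    The grid is a serializable snapshot; :meth:`log_odds` evaluates the exact
    analytic map (used by the fitting and simulation code), while
    :meth:`interp_log_odds` interpolates the stored grid bilinearly, clamping
    out-of-grid balances with a warning.
    """

    params: RaceParams
    coherences: np.ndarray  # signed set, symmetric about 0
    prior: np.ndarray       # weights over the signed set, sums to 1
    time_grid: np.ndarray
    balance_grid: np.ndarray
    logodds: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            (self.time_grid, self.balance_grid), self.logodds,
            bounds_error=False, fill_value=None)

    def _weights(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positive coherences, their weights, weight at zero)."""
        pos = self.coherences > 0
        w0 = float(self.prior[self.coherences == 0].sum())
        return self.coherences[pos], self.prior[pos], w0

    def log_odds(self, t, delta):
        """Exact log-odds that the direction of ``delta`` is correct.

        ``delta`` is the evidence balance oriented toward the candidate
        direction (winner minus loser at decision time); antisymmetric in
        ``delta`` and zero at ``delta = 0``.
        """
        t = np.asarray(t, dtype=float)
        delta = np.asarray(delta, dtype=float)
        cs, ws, w0 = self._weights()
        scale = self.params.kappa / (1.0 - self.params.corr)
        # exponent per congruent coherence: (kappa c delta - kappa^2 c^2 t)/(1-rho)
        a = scale * cs
        b = scale * self.params.kappa * cs ** 2
        ex_cong = a * delta[..., None] - b * t[..., None]
        ex_opp = -a * delta[..., None] - b * t[..., None]
        logw = np.log(ws)
        if w0 > 0:
            ex_cong, ex_opp = np.broadcast_arrays(ex_cong, ex_opp)
            z = np.zeros(ex_cong.shape[:-1] + (1,))
            ex_cong = np.concatenate([ex_cong, z], axis=-1)
            ex_opp = np.concatenate([ex_opp, z], axis=-1)
            logw = np.concatenate([logw, [math.log(w0 / 2.0)]])
        num = logsumexp(ex_cong + logw, axis=-1)
        den = logsumexp(ex_opp + logw, axis=-1)
        return num - den

    def interp_log_odds(self, t, delta):
        """Bilinear interpolation on the stored grid; clamps out-of-grid."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        if (delta.min() < self.balance_grid[0]
                or delta.max() > self.balance_grid[-1]):
            warnings.warn("balance outside the map grid; clamping",
                          RuntimeWarning, stacklevel=2)
            delta = np.clip(delta, self.balance_grid[0], self.balance_grid[-1])
        t = np.clip(t, self.time_grid[0], self.time_grid[-1])
        return self._interp(np.stack(np.broadcast_arrays(t, delta), axis=-1))

    def invert_delta(self, t, logodds_level):
        """Balance delta at which the map reaches a log-odds level.

        Vectorized bisection on the (strictly increasing) exact map; ``t``
        and ``logodds_level`` broadcast together.
        """
        t, lvl = np.broadcast_arrays(np.asarray(t, float),
                                     np.asarray(logodds_level, float))
        lo = np.full(t.shape, -64.0)
        hi = np.full(t.shape, 64.0)
        for _ in range(20):  # expand brackets if ever needed, then bisect
            need = self.log_odds(t, lo) > lvl
            if not need.any():
                break
            lo = np.where(need, lo * 2.0, lo)
        for _ in range(20):
            need = self.log_odds(t, hi) < lvl
            if not need.any():
                break
            hi = np.where(need, hi * 2.0, hi)
        for _ in range(55):
            mid = 0.5 * (lo + hi)
            below = self.log_odds(t, mid) < lvl
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)

    def to_delimited(self, path) -> None:
        """Write the map as a self-describing tab-delimited grid file."""
        p = self.params
        with open(path, "w") as fh:
            fh.write(f"# kappa\t{float(p.kappa)!r}\n# bound\t{float(p.bound)!r}\n"
                     f"# corr\t{float(p.corr)!r}\n# tnd_mean\t{float(p.tnd_mean)!r}\n"
                     f"# tnd_sd\t{float(p.tnd_sd)!r}\n")
            fh.write("# coherences\t" + "\t".join(repr(float(c)) for c in self.coherences) + "\n")
            fh.write("# prior\t" + "\t".join(repr(float(w)) for w in self.prior) + "\n")
            fh.write("# balance_grid\t" + "\t".join(repr(float(b)) for b in self.balance_grid) + "\n")
            fh.write("time\t" + "\t".join(f"d{j}" for j in range(len(self.balance_grid))) + "\n")
            for i, t in enumerate(self.time_grid):
                fh.write(repr(float(t)) + "\t"
                         + "\t".join(repr(float(v)) for v in self.logodds[i]) + "\n")

    @classmethod
    def from_delimited(cls, path) -> "BeliefMap":
        meta: dict[str, list[float]] = {}
        rows = []
        times = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, *vals = line[1:].strip().split("\t")
                    meta[key] = [float(v) for v in vals]
                elif line.startswith("time"):
                    continue
                else:
                    t, *vals = line.strip().split("\t")
                    times.append(float(t))
                    rows.append([float(v) for v in vals])
        params = RaceParams(kappa=meta["kappa"][0], bound=meta["bound"][0],
                            corr=meta["corr"][0], tnd_mean=meta["tnd_mean"][0],
                            tnd_sd=meta["tnd_sd"][0])
        return cls(params, np.array(meta["coherences"]), np.array(meta["prior"]),
                   np.array(times), np.array(meta["balance_grid"]), np.array(rows))


def build_belief_map(params: RaceParams, coherence_set,
                     prior=None,
                     time_grid=None, balance_grid=None) -> BeliefMap:
    """Construct the (t, Delta) -> log-odds-correct map.

    ``coherence_set`` must be symmetric about zero; ``prior`` (default
    uniform) weights the signed set, with the 0% weight split equally
    between the two direction hypotheses.
    """
    cs = np.sort(np.asarray(coherence_set, dtype=float))
    if not np.allclose(np.sort(-cs), cs):
        raise ValueError("coherence_set must be symmetric about 0")
    if prior is None:
        prior = np.full(len(cs), 1.0 / len(cs))
    prior = np.asarray(prior, dtype=float)
    if np.any(prior <= 0):
        raise ValueError("prior weights must be positive")
    prior = prior / prior.sum()
    if time_grid is None:
        time_grid = np.linspace(0.0, 6.0, 601)
    if balance_grid is None:
        span = max(4.0 * params.bound, 6.0)
        balance_grid = np.linspace(-span, span, 241)
    time_grid = np.asarray(time_grid, float)
    balance_grid = np.asarray(balance_grid, float)
    bmap = BeliefMap(params, cs, prior, time_grid, balance_grid,
                     np.zeros((len(time_grid), len(balance_grid))))
    bmap.logodds = bmap.log_odds(time_grid[:, None], balance_grid[None, :])
    bmap.__post_init__()
    return bmap


@dataclass
class InitialPrediction:
    """Predicted initial-report breakdown at one signed coherence.

    ``probs`` orders the four categories as :data:`CATEGORIES`, conditional
    on the decision terminating within the solution's time horizon; mean RT
    adds the mean non-decision time to the mean decision time.
    """

    coherence: float
    probs: np.ndarray
    mean_decision_time: float
    mean_rt: float
    mean_rt_correct: float


def _category_masses(solution: AbsorptionSolution, high_mask_fn) -> tuple[np.ndarray, float, float]:
    """Integrate the flux sheets against a high/low classification.

    ``high_mask_fn(t_grid, delta_grid_2d)`` returns the boolean high mask on
    the (time, loser) grid.  Returns (4-vector of category masses ordered as
    CATEGORIES for positive coherence, mean decision time, mean decision time
    of correct trials).  At zero coherence the caller symmetrizes.
    """
    t = solution.time_grid
    v = solution.loser_grid
    delta = solution.params.bound - v  # balance toward the winner
    high = high_mask_fn(t[:, None], np.broadcast_to(delta, (len(t), len(v))))
    out = np.empty(4)
    mean_num = 0.0
    mean_num_correct = 0.0
    for sheet, labels in ((0, ("correct_high", "correct_low")),
                          (1, ("error_high", "error_low"))):
        f = solution.flux[sheet]
        hi = np.trapezoid(np.trapezoid(np.where(high, f, 0.0), v, axis=1), t)
        tot_t = np.trapezoid(f, v, axis=1)
        tot = np.trapezoid(tot_t, t)
        out[CATEGORIES.index(labels[0])] = hi
        out[CATEGORIES.index(labels[1])] = tot - hi
        contrib = np.trapezoid(t * tot_t, t)
        mean_num += contrib
        if sheet == 0:
            mean_num_correct = contrib
    return out, mean_num, mean_num_correct


def _prediction_from_masses(params, coherence, masses, mean_num,
                            mean_num_correct) -> InitialPrediction:
    total = masses.sum()
    mean_dt = mean_num / total
    if coherence == 0:
        # random designation: correct/error split evenly within confidence
        high = masses[0] + masses[2]
        low = masses[1] + masses[3]
        probs = np.array([high, low, high, low]) / (2.0 * total)
        mean_dt_corr = mean_dt
    else:
        probs = masses / total
        mean_dt_corr = mean_num_correct / (masses[0] + masses[1])
    return InitialPrediction(coherence, probs, mean_dt,
                             mean_dt + params.tnd_mean,
                             mean_dt_corr + params.tnd_mean)


def initial_outcome_probs(params: RaceParams, crit: ConfidenceCriterion,
                          bmap: BeliefMap, coherence: float,
                          solution: AbsorptionSolution | None = None,
                          **flux_kwargs) -> InitialPrediction:
    """Predicted 4-way initial outcome probabilities and mean RT.

    Integrates the absorption flux, classifying each (decision time, loser
    state) atom by winner identity and by whether the mapped log-odds meets
    the criterion ``theta``.  Correctness is relative to the true direction;
    at 0% coherence the designation is random, so correct and error rows are
    symmetrized.
    """
    c = abs(float(coherence))
    if not np.any(np.isclose(np.abs(bmap.coherences), c)):
        raise ValueError(
            f"coherence {coherence!r} is not in the belief map's set; "
            "refusing to extrapolate")
    if solution is None:
        solution = absorption_flux(params, c, **flux_kwargs)
    masses, mnum, mnumc = _category_masses(
        solution, lambda t, d: bmap.log_odds(t, d) >= crit.theta)
    return _prediction_from_masses(params, c, masses, mnum, mnumc)


def alternative_confidence_rule(kind: str, threshold: float,
                                params: RaceParams, coherence: float,
                                solution: AbsorptionSolution | None = None,
                                **flux_kwargs) -> InitialPrediction:
    """Initial predictions under the two degraded confidence rules.

    ``kind='balance-only'`` assigns high confidence when the balance of
    evidence at decision exceeds ``threshold`` (evidence units), ignoring
    decision time; ``kind='time-only'`` when the decision time is at most
    ``threshold`` (seconds), ignoring the balance.
    """
    if kind not in ("balance-only", "time-only"):
        raise ValueError(f"unknown confidence rule {kind!r}")
    c = abs(float(coherence))
    if solution is None:
        solution = absorption_flux(params, c, **flux_kwargs)
    if kind == "balance-only":
        mask = lambda t, d: d >= threshold
    else:
        mask = lambda t, d: (t + 0.0 * d) <= threshold
    masses, mnum, mnumc = _category_masses(solution, mask)
    return _prediction_from_masses(params, c, masses, mnum, mnumc)


def probability_equivalent(theta: float) -> float:
    """Probability-correct equivalent of a log-odds criterion."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return float(expit(theta))


def optimal_criterion(payoffs) -> float:
    """Log-odds belief at which high- and low-risk targets earn equal points.

    ``payoffs`` is a 2x2 matrix ``[[high_correct, high_error],
    [low_correct, low_error]]`` in points.  Solves for the belief p* at which
    expected points are equal and returns ``log(p*/(1-p*))``.
    """
    (hw, hl), (lw, ll) = np.asarray(payoffs, dtype=float)
    denom = (hw - lw) + (ll - hl)
    if denom == 0:
        raise ValueError("degenerate payoffs: expected points never cross")
    p = (ll - hl) / denom
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"degenerate payoffs: indifference belief {p:.3g} outside (0, 1)")
    return math.log(p / (1.0 - p))
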