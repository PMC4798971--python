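"""Two-stage maximum-likelihood fitting of the race model.

Stage 1 fits the initial-report parameters (kappa, B, mu_tnd, theta) to the
per-coherence counts of the four initial categories plus the sample mean RT
of correct trials (all trials at 0%), combining a multinomial likelihood for
the counts with a Gaussian likelihood for the sample means (observed s.e.m.
as the standard deviation).  Noise correlation and the non-decision SD are
fixed (defaults -cos(pi/4) and 60 ms).  Stage 2 carries all four stage-1
estimates over, fixed, and fits the post-initiation parameters (t_pip,
dtheta_1..3) to the 16-category initial-by-final counts.

Error-trial mean RTs are excluded from the cost: with a flat bound the model
does not reproduce error-trial chronometry, so only correct-trial means are
informative.  Optimization is bounded Nelder-Mead from multiple random
starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .belief import (BeliefMap, CATEGORIES, ConfidenceCriterion,
                     _category_masses, build_belief_map)
from .race import (RaceParams, absorption_flux, default_loser_grid,
                   supported_correlation)
from .revision import (InvalidZoneError, RevisionParams, final_zone_thresholds,
                       outcome_table, propagate_post_initiation)

__all__ = [
    "BehavioralCounts",
    "FitConfig",
    "FitResult",
    "counts_from_trials",
    "predict_initial",
    "nll_initial",
    "fit_initial",
    "nll_revision",
    "fit_revision",
]

PROB_FLOOR = 1e-10


@dataclass
class BehavioralCounts:
    """Per-unsigned-coherence summary the likelihood is computed from.

    ``counts4`` holds the initial-category counts in the order of
    :data:`~racemind.belief.CATEGORIES`; ``mean_rt``/``sem_rt`` are the
    correct-trial reaction-time sample moments (all trials at 0%);
    ``counts16`` the initial-by-final category counts, shape (nc, 4, 4).
    """

    coherences: np.ndarray
    counts4: np.ndarray
    mean_rt: np.ndarray
    sem_rt: np.ndarray
    counts16: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.counts4 < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.sem_rt <= 0):
            raise ValueError("s.e.m. must be positive where a mean is supplied")
        if self.counts16 is not None and np.any(self.counts16 < 0):
            raise ValueError("counts must be non-negative")


def counts_from_trials(trials: pd.DataFrame) -> BehavioralCounts:
    """Tabulate a simulated (or recorded) trial table into fitting counts."""
    ac = trials.coherence.abs().round(6)
    coherences = np.sort(ac.unique())
    nc = len(coherences)
    counts4 = np.zeros((nc, 4), dtype=int)
    counts16 = np.zeros((nc, 4, 4), dtype=int)
    mean_rt = np.zeros(nc)
    sem_rt = np.zeros(nc)
    for i, c in enumerate(coherences):
        sub = trials[ac == c]
        icat = _category_index(sub.init_correct.to_numpy(),
                               (sub.init_conf == "high").to_numpy())
        fcat = _category_index(sub.final_correct.to_numpy(),
                               (sub.final_conf == "high").to_numpy())
        for a in range(4):
            counts4[i, a] = int((icat == a).sum())
            for b in range(4):
                counts16[i, a, b] = int(((icat == a) & (fcat == b)).sum())
        rt = sub.rt[sub.init_correct].to_numpy() if c > 0 else sub.rt.to_numpy()
        mean_rt[i] = rt.mean()
        sem_rt[i] = rt.std(ddof=1) / np.sqrt(len(rt))
    return BehavioralCounts(coherences, counts4, mean_rt, sem_rt, counts16)


def _category_index(correct: np.ndarray, high: np.ndarray) -> np.ndarray:
    return np.where(correct, np.where(high, 0, 1), np.where(high, 2, 3))


def fit_time_grid(dt: float = 5e-3, t_max: float = 5.0,
                  dense_until: float = 1.6, sparse_factor: int = 5) -> np.ndarray:
    """Decision-time grid dense early (where the flux peaks), sparse late."""
    dense = np.arange(dt, dense_until, dt)
    sparse = np.arange(dense_until, t_max + dt, sparse_factor * dt)
    return np.concatenate([dense, sparse])


@dataclass
class FitConfig:
    """Optimization and discretization settings for both stages."""

    n_starts: int = 30
    seed: int = 0
    corr: float = supported_correlation(4)
    tnd_sd: float = 0.06
    dt: float = 5e-3
    t_max: float = 5.0
    n_loser: int = 101
    maxfev: int = 600
    fatol: float = 1e-6
    xatol: float = 1e-4
    bounds_initial: dict = field(default_factory=lambda: {
        "kappa": (0.5, 50.0), "bound": (0.05, 5.0),
        "tnd_mean": (0.1, 1.0), "theta": (0.05, 5.0)})
    start_ranges_initial: dict = field(default_factory=lambda: {
        "kappa": (2.0, 30.0), "bound": (0.3, 2.0),
        "tnd_mean": (0.2, 0.8), "theta": (0.3, 2.5)})
    bounds_revision: dict = field(default_factory=lambda: {
        "t_pip": (0.0, None), "d1": (-3.0, 3.0),
        "d2": (-3.0, 3.0), "d3": (-3.0, 3.0)})
    start_ranges_revision: dict = field(default_factory=lambda: {
        "t_pip": (0.05, 0.4), "d1": (-0.5, 1.5),
        "d2": (-0.5, 1.0), "d3": (-1.0, 0.5)})

    def time_grid(self) -> np.ndarray:
        return fit_time_grid(self.dt, self.t_max)


@dataclass
class FitResult:
    """Point estimates with per-start diagnostics.

    ``starts`` records, per optimizer start, the initial point, initial cost,
    final point, final cost and convergence flag; the reported ``nll`` is the
    best final cost (never worse than any start's initial cost).
    """

    params: dict
    nll: float
    starts: list
    fixed: dict
    success: bool

    def race_params(self) -> RaceParams:
        return RaceParams(kappa=self.params["kappa"], bound=self.params["bound"],
                          corr=self.fixed["corr"], tnd_mean=self.params["tnd_mean"],
                          tnd_sd=self.fixed["tnd_sd"])

    def criterion(self) -> ConfidenceCriterion:
        return ConfidenceCriterion(self.params["theta"])

    def revision_params(self) -> RevisionParams:
        return RevisionParams(t_pip=self.params["t_pip"], d1=self.params["d1"],
                              d2=self.params["d2"], d3=self.params["d3"])

    def report(self) -> str:
        lines = [f"{k} = {v:.6g}" for k, v in self.params.items()]
        lines += [f"{k} = {v:.6g} (fixed)" for k, v in self.fixed.items()]
        lines.append(f"nll = {self.nll:.6f}")
        lines.append(f"converged = {self.success}")
        return "\n".join(lines)


def _signed_set(unsigned: np.ndarray) -> np.ndarray:
    """Signed experimental set; a 0% level enters twice (plus and minus)."""
    return np.sort(np.concatenate([-np.asarray(unsigned), np.asarray(unsigned)]))


def _exact_map(params: RaceParams, unsigned: np.ndarray) -> BeliefMap:
    """Belief map with a token grid: fitting only uses the exact evaluator."""
    return build_belief_map(params, _signed_set(unsigned),
                            time_grid=np.array([0.0, 6.0]),
                            balance_grid=np.array([-8.0, 8.0]))


def predict_initial(params: RaceParams, crit: ConfidenceCriterion,
                    coherences: np.ndarray, config: FitConfig | None = None,
                    solutions: dict | None = None):
    """Model 4-category probabilities and correct-trial mean RT per coherence.

    Returns ``(probs (nc, 4), mean_rt_correct (nc,))``, probabilities
    conditional on the decision terminating within the time horizon.
    """
    if config is None:
        config = FitConfig()
    coherences = np.asarray(coherences, float)
    bmap = _exact_map(params, coherences)
    tg = config.time_grid()
    probs = np.empty((len(coherences), 4))
    mean_rt = np.empty(len(coherences))
    lg = default_loser_grid(params, t_max=config.t_max, n=config.n_loser)
    for i, c in enumerate(coherences):
        sol = None if solutions is None else solutions.get(float(c))
        if sol is None:
            sol = absorption_flux(params, float(c), time_grid=tg,
                                  loser_grid=lg, conservation_tol=np.inf)
        masses, mnum, mnumc = _category_masses(
            sol, lambda t, d: bmap.log_odds(t, d) >= crit.theta)
        total = masses.sum()
        if c == 0:
            high = masses[0] + masses[2]
            low = masses[1] + masses[3]
            probs[i] = np.array([high, low, high, low]) / (2.0 * total)
            mean_rt[i] = mnum / total + params.tnd_mean
        else:
            probs[i] = masses / total
            mean_rt[i] = mnumc / (masses[0] + masses[1]) + params.tnd_mean
    return probs, mean_rt


def nll_initial(params: RaceParams, crit: ConfidenceCriterion,
                data: BehavioralCounts, config: FitConfig | None = None) -> float:
    """Stage-1 cost: multinomial (4 categories) + Gaussian (mean RT).

    Additive constants are dropped.  Predicted probabilities are floored at
    1e-10 (with a warning if an observed category had to be floored).
    """
    probs, mean_rt = predict_initial(params, crit, data.coherences, config)
    floored = probs < PROB_FLOOR
    if np.any(floored & (data.counts4 > 0)):
        warnings.warn("observed category with predicted probability below "
                      "the floor; cost is floored", RuntimeWarning,
                      stacklevel=2)
    probs = np.clip(probs, PROB_FLOOR, None)
    nll = -float(np.sum(data.counts4 * np.log(probs)))
    nll += 0.5 * float(np.sum(((data.mean_rt - mean_rt) / data.sem_rt) ** 2))
    return nll


def _multistart(objective, names, bounds, start_ranges, config,
                start_ok=None):
    rng = np.random.default_rng(config.seed)
    starts = []
    best = None
    lb = np.array([bounds[n][0] for n in names], dtype=float)
    ub = np.array([bounds[n][1] for n in names], dtype=float)
    for _ in range(config.n_starts):
        for _attempt in range(200):
            x0 = np.array([rng.uniform(*start_ranges[n]) for n in names])
            if start_ok is None or start_ok(x0):
                break
        f0 = objective(x0)
        res = minimize(objective, x0, method="Nelder-Mead",
                       bounds=list(zip(lb, ub)),
                       options={"maxfev": config.maxfev, "fatol": config.fatol,
                                "xatol": config.xatol, "adaptive": True})
        starts.append({"x0": x0, "nll0": f0, "x": res.x, "nll": res.fun,
                       "converged": bool(res.success)})
        if best is None or res.fun < best["nll"]:
            best = starts[-1]
    if best is None or not any(s["converged"] for s in starts):
        if best is None:
            raise RuntimeError("fit failed: no optimizer start completed")
        warnings.warn("no optimizer start reported convergence; returning "
                      "the best point found", RuntimeWarning, stacklevel=2)
    return best, starts


def fit_initial(data: BehavioralCounts,
                config: FitConfig | None = None) -> FitResult:
    """Stage-1 bounded multi-start fit of (kappa, B, mu_tnd, theta)."""
    if config is None:
        config = FitConfig()
    names = ["kappa", "bound", "tnd_mean", "theta"]

    def objective(x):
        try:
            p = RaceParams(kappa=x[0], bound=x[1], corr=config.corr,
                           tnd_mean=x[2], tnd_sd=config.tnd_sd)
            return nll_initial(p, ConfidenceCriterion(x[3]), data, config)
        except (ValueError, FloatingPointError):
            return 1e12

    best, starts = _multistart(objective, names, config.bounds_initial,
                               config.start_ranges_initial, config)
    params = dict(zip(names, best["x"]))
    return FitResult(params=params, nll=float(best["nll"]), starts=starts,
                     fixed={"corr": config.corr, "tnd_sd": config.tnd_sd},
                     success=any(s["converged"] for s in starts))


class _RevisionPredictor:
    """Caches stage-1 absorption atoms; evaluates 16-category tables fast."""

    def __init__(self, params: RaceParams, crit: ConfidenceCriterion,
                 coherences: np.ndarray, config: FitConfig):
        self.params = params
        self.crit = crit
        self.coherences = np.asarray(coherences, float)
        self.bmap = _exact_map(params, self.coherences)
        tg = config.time_grid()
        lg = default_loser_grid(params, t_max=config.t_max, n=config.n_loser)
        self.solutions = {float(c): absorption_flux(params, float(c),
                                                    time_grid=tg, loser_grid=lg,
                                                    conservation_tol=np.inf)
                          for c in self.coherences}
        self.atoms_cache: dict = {}

    def probs16(self, rev: RevisionParams) -> np.ndarray:
        table = outcome_table(self.params, self.crit, rev, self.bmap,
                              self.coherences, solutions=self.solutions,
                              atoms_cache=self.atoms_cache)
        return table.tables


def nll_revision(rev: RevisionParams, carried: FitResult,
                 data: BehavioralCounts,
                 config: FitConfig | None = None,
                 predictor: _RevisionPredictor | None = None) -> float:
    """Stage-2 cost: multinomial over the 16 initial-by-final categories.

    Stage-1 parameters are carried over, fixed.  Parameter points with an
    invalid zone partition or with ``t_pip`` above the carried mean
    non-decision time cost +inf (the optimizer must reject them).
    """
    if data.counts16 is None:
        raise ValueError("counts16 required for the revision stage")
    if config is None:
        config = FitConfig()
    if rev.t_pip > carried.params["tnd_mean"]:
        return np.inf
    try:
        for conf in ("high", "low"):
            final_zone_thresholds(carried.criterion(), rev, conf)
    except InvalidZoneError:
        return np.inf
    if predictor is None:
        predictor = _RevisionPredictor(carried.race_params(),
                                       carried.criterion(),
                                       data.coherences, config)
    probs = np.clip(predictor.probs16(rev), PROB_FLOOR, None)
    return -float(np.sum(data.counts16 * np.log(probs)))


def fit_revision(data: BehavioralCounts, carried: FitResult,
                 config: FitConfig | None = None) -> FitResult:
    """Stage-2 bounded multi-start fit of (t_pip, dtheta_1..3)."""
    if config is None:
        config = FitConfig()
    names = ["t_pip", "d1", "d2", "d3"]
    predictor = _RevisionPredictor(carried.race_params(), carried.criterion(),
                                   data.coherences, config)
    bounds = dict(config.bounds_revision)
    if bounds["t_pip"][1] is None:
        bounds["t_pip"] = (0.0, carried.params["tnd_mean"])

    theta = carried.params["theta"]

    def _zone_violation(x):
        # positive when the final-zone thresholds are out of order
        uppers = (theta - x[1], theta + x[1])
        middle, lower = -x[2], -theta - x[3]
        worst = max(middle - u for u in uppers)
        return max(worst, lower - middle, 0.0)

    def objective(x):
        viol = _zone_violation(x)
        if viol > 0:
            # graded penalty: slopes back toward the admissible region
            return 1e9 * (1.0 + viol)
        rev = RevisionParams(t_pip=x[0], d1=x[1], d2=x[2], d3=x[3])
        val = nll_revision(rev, carried, data, config, predictor=predictor)
        return 1e12 if not np.isfinite(val) else val

    best, starts = _multistart(objective, names, bounds,
                               config.start_ranges_revision, config,
                               start_ok=lambda x: _zone_violation(x) == 0.0)
    params = dict(carried.params)
    params.update(dict(zip(names, best["x"])))
    fixed = dict(carried.fixed)
    fixed.update({k: carried.params[k] for k in
                  ("kappa", "bound", "tnd_mean", "theta")})
    return FitResult(params=params, nll=float(best["nll"]), starts=starts,
                     fixed=fixed, success=any(s["converged"] for s in starts))


def parameter_table(result: FitResult) -> pd.DataFrame:
    """Machine-readable parameter table (name, value, fixed flag)."""
    rows = [(k, v, False) for k, v in result.params.items()]
    rows += [(k, v, True) for k, v in result.fixed.items()]
    return pd.DataFrame(rows, columns=["parameter", "value", "fixed"])
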