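"""Post-initiation processing: revising direction and confidence.

Because of sensory and motor latencies, evidence in the processing pipeline
at movement initiation has not yet influenced the decision.  The accumulators
therefore continue, without bounds, for a further period ``t_pip`` (at most
the mean non-decision time), and the belief map is re-read at total evidence
time ``t_dec + t_pip``.  The final log-odds axis, oriented toward the initial
direction, is cut by three thresholds into four zones: keep the direction
with high or low confidence, or switch direction with low or high confidence.
Relative to the initial criterion ``theta``, the thresholds are shifted by
``dtheta_1..3``, implementing hysteresis (resistance to revising a report)
and the asymmetric motor cost of reaching across the workspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .belief import CATEGORIES, BeliefMap, ConfidenceCriterion, _category_masses
from .race import AbsorptionSolution, RaceParams, absorption_flux

__all__ = [
    "RevisionParams",
    "PostInitiationAtoms",
    "InvalidZoneError",
    "OutcomeTable",
    "FinalBeliefDistribution",
    "FINAL_ZONES",
    "final_zone_thresholds",
    "propagate_post_initiation",
    "outcome_table",
]

#: Final report zones in order along the oriented log-odds axis, from above.
FINAL_ZONES = ("same_high", "same_low", "opposite_low", "opposite_high")


class InvalidZoneError(ValueError):
    """Raised when the shifted thresholds do not partition the axis."""


@dataclass(frozen=True)
class RevisionParams:
    """Post-initiation parameters: processing time and threshold shifts.

    ``t_pip`` is in seconds (constrained below the mean non-decision time by
    the fitting stage); the ``d*`` shifts are in log-odds units and carry no
    sign constraint (fits find d3 < 0: a relaxed criterion for switching
    direction with high confidence).
    """

    t_pip: float
    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0

    def __post_init__(self) -> None:
        if self.t_pip < 0:
            raise ValueError("t_pip must be >= 0")


def final_zone_thresholds(crit: ConfidenceCriterion, rev: RevisionParams,
                          initial_confidence: str) -> tuple[float, float, float]:
    """Ordered (upper, middle, lower) log-odds thresholds for the final report.

    For an initial high-confidence choice the thresholds are
    ``(theta - d1, -d2, -theta - d3)``; after an initial low-confidence
    choice the first becomes ``theta + d1``.  The axis is oriented toward the
    initial direction; zones from above: same-direction high, same-direction
    low, opposite-direction low, opposite-direction high.
    """
    if initial_confidence not in ("high", "low"):
        raise ValueError("initial_confidence must be 'high' or 'low'")
    th = crit.theta
    upper = th - rev.d1 if initial_confidence == "high" else th + rev.d1
    middle = -rev.d2
    lower = -th - rev.d3
    if not (upper > middle > lower):
        raise InvalidZoneError(
            f"thresholds ({upper:.3g}, {middle:.3g}, {lower:.3g}) are not "
            "strictly descending; the zone partition is invalid")
    return upper, middle, lower


@dataclass
class FinalBeliefDistribution:
    """Distribution of the final belief, conditioned on each initial category.

    A mixture over absorption atoms: atom ``i`` of a category decided at
    ``time_grid[t_idx[i]]`` and its final oriented balance is Gaussian with
    mean ``mean[i]`` and shared standard deviation ``sd``; its final
    log-odds is the belief map read at ``time_grid[t_idx[i]] + t_pip``.
    Per-category ``weights`` are normalized conditional masses.
    """

    bmap: BeliefMap
    t_pip: float
    sd: float
    time_grid: np.ndarray
    weights: dict = field(repr=False)
    mean: dict = field(repr=False)
    t_idx: dict = field(repr=False)
    init_logodds: dict = field(repr=False)

    def _dstar(self, levels: np.ndarray) -> np.ndarray:
        """Balance thresholds delta*(t + t_pip, level), shape (nlev, nt)."""
        t = self.time_grid + self.t_pip
        return self.bmap.invert_delta(t[None, :], np.asarray(levels, float)[:, None])

    def _cdf_levels(self, levels, category: str,
                    dstar: np.ndarray | None = None) -> np.ndarray:
        """P(final log-odds <= level) for each level, one category.

        ``dstar`` may carry precomputed balance thresholds (nlev, nt) to
        share the map inversion across categories.
        """
        levels = np.atleast_1d(np.asarray(levels, float))
        w = self.weights[category]
        if len(w) == 0:
            return np.full(levels.shape, np.nan)
        if self.sd == 0.0:
            lo = self.init_logodds[category]
            return np.array([(w * (lo <= lv)).sum() for lv in levels])
        if dstar is None:
            dstar = self._dstar(levels)
        dstar = dstar[:, self.t_idx[category]]
        z = (dstar - self.mean[category][None, :]) / self.sd
        return (w[None, :] * norm.cdf(z)).sum(axis=1)

    def cdf_logodds(self, level, category: str) -> np.ndarray:
        """P(final log-odds <= level | initial category)."""
        return self._cdf_levels(level, category)

    def cdf_balance(self, x, category: str) -> np.ndarray:
        """P(final oriented balance <= x | initial category)."""
        x = np.atleast_1d(np.asarray(x, float))
        w = self.weights[category]
        m = self.mean[category]
        if self.sd == 0.0:
            return (w[None, :] * (m[None, :] <= x[:, None])).sum(axis=1)
        z = (x[:, None] - m[None, :]) / self.sd
        return (w[None, :] * norm.cdf(z)).sum(axis=1)

    def zone_probabilities(self, thresholds: dict,
                           levels: list | None = None,
                           dstar_all: np.ndarray | None = None) -> dict:
        """Final-zone probabilities per initial category.

        ``thresholds`` maps initial confidence ('high'/'low') to the ordered
        triple from :func:`final_zone_thresholds`.  Zone order follows
        :data:`FINAL_ZONES`.  ``levels``/``dstar_all`` may carry precomputed
        balance thresholds for the sorted unique levels (the map inversion
        does not depend on coherence, so callers evaluating several
        coherences on a shared time grid can reuse it).
        """
        if levels is None:
            levels = sorted({lv for trip in thresholds.values() for lv in trip})
        if dstar_all is None and self.sd != 0.0:
            dstar_all = self._dstar(np.array(levels))
        out = {}
        for cat in CATEGORIES:
            conf = "high" if cat.endswith("high") else "low"
            trip = list(thresholds[conf])
            dstar = None
            if dstar_all is not None:
                dstar = dstar_all[[levels.index(lv) for lv in trip]]
            c_up, c_mid, c_low = self._cdf_levels(trip, cat, dstar=dstar)
            out[cat] = np.array([1.0 - c_up, c_up - c_mid, c_mid - c_low, c_low])
        return out


class PostInitiationAtoms:
    """Absorption atoms prepared for post-initiation propagation.

    Classifies the (decision time, loser state) atoms of an absorption
    solution into the four initial categories once; the rev-parameter-
    dependent parts (final-balance means, mixture SD, zone thresholds) are
    cheap, so one instance serves many ``t_pip`` values — the stage-2 fit
    reuses it across objective evaluations.
    """

    def __init__(self, params: RaceParams, bmap: BeliefMap, coherence: float,
                 absorption: AbsorptionSolution, crit: ConfidenceCriterion):
        self.params = params
        self.bmap = bmap
        self.coherence = abs(float(coherence))
        self.crit = crit
        t = absorption.time_grid
        v = absorption.loser_grid
        nt, nv = len(t), len(v)
        self.time_grid = t
        delta0 = np.broadcast_to(params.bound - v[None, :], (nt, nv)).ravel()
        tidx = np.broadcast_to(np.arange(nt)[:, None], (nt, nv)).ravel()
        # high/low split of the initial report: balance above the criterion
        # balance dstar(t) solving log-odds(t, dstar) = theta
        dstar = bmap.invert_delta(t, np.full(nt, crit.theta))
        high = delta0 >= dstar[tidx]
        cell = (np.gradient(t)[:, None] * np.gradient(v)[None, :]).ravel()
        self.weights, self.delta0, self.t_idx, self.drift_sign = {}, {}, {}, {}
        self.init_mass = np.empty(4)
        for sheet, sign, cats in ((0, +1.0, ("correct_high", "correct_low")),
                                  (1, -1.0, ("error_high", "error_low"))):
            mass = absorption.flux[sheet].ravel() * cell
            for cat, mask in ((cats[0], high), (cats[1], ~high)):
                w = np.where(mask, mass, 0.0)
                tot = w.sum()
                self.init_mass[CATEGORIES.index(cat)] = tot
                # prune atoms carrying a negligible share of the category
                # mass (they cannot move a 16-cell probability at the 1e-10
                # likelihood floor)
                keep = np.nonzero(w > 1e-12 * max(tot, 1e-300))[0]
                self.weights[cat] = w[keep] / max(w[keep].sum(), 1e-300)
                self.delta0[cat] = delta0[keep]
                self.t_idx[cat] = tidx[keep]
                self.drift_sign[cat] = sign

    def distribution(self, t_pip: float) -> FinalBeliefDistribution:
        if t_pip < 0:
            raise ValueError("t_pip must be >= 0")
        p = self.params
        means, init_lo = {}, {}
        for cat in CATEGORIES:
            shift = 2.0 * p.kappa * self.coherence * self.drift_sign[cat] * t_pip
            means[cat] = self.delta0[cat] + shift
            if t_pip == 0.0:
                init_lo[cat] = self.bmap.log_odds(
                    self.time_grid[self.t_idx[cat]], self.delta0[cat])
        sd = float(np.sqrt(2.0 * (1.0 - p.corr) * t_pip))
        return FinalBeliefDistribution(self.bmap, t_pip, sd, self.time_grid,
                                       self.weights, means, self.t_idx,
                                       init_lo if t_pip == 0.0 else None)


def propagate_post_initiation(params: RaceParams, bmap: BeliefMap,
                              coherence: float,
                              absorption: AbsorptionSolution,
                              t_pip: float,
                              crit: ConfidenceCriterion) -> FinalBeliefDistribution:
    """Diffuse each absorption atom freely for ``t_pip`` and track its belief.

    For each (decision time, loser state) atom the oriented balance starts at
    ``Delta = B - loser`` and drifts at ``2*kappa*c`` toward the true
    direction — positive for an initially correct choice, negative for an
    error — with variance rate ``2*(1 - corr)``.  With ``t_pip = 0`` the
    returned distribution reproduces the initial log-odds exactly.
    """
    atoms = PostInitiationAtoms(params, bmap, coherence, absorption, crit)
    return atoms.distribution(t_pip)


@dataclass
class OutcomeTable:
    """Joint initial x final category probabilities per signed coherence.

    ``tables`` has shape (n_coherence, 4, 4): rows are initial categories
    (:data:`~racemind.belief.CATEGORIES`), columns the final categories in
    the same correctness-by-confidence order.  Each sheet sums to 1.
    """

    coherences: np.ndarray
    tables: np.ndarray

    def sheet(self, coherence: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.coherences - coherence)))
        return self.tables[i]

    def p_change_decision(self, given: str) -> np.ndarray:
        """P(final direction differs | initial correct/error), per coherence."""
        rows = [0, 1] if given == "correct" else [2, 3]
        cols = [2, 3] if given == "correct" else [0, 1]
        joint = self.tables[:, rows, :][:, :, cols].sum(axis=(1, 2))
        base = self.tables[:, rows, :].sum(axis=(1, 2))
        return np.divide(joint, base, out=np.full(len(base), np.nan),
                         where=base > 0)

    def p_change_confidence(self, given: str) -> np.ndarray:
        """P(final confidence differs | initial high/low), per coherence."""
        rows = [0, 2] if given == "high" else [1, 3]
        cols = [1, 3] if given == "high" else [0, 2]
        joint = self.tables[:, rows, :][:, :, cols].sum(axis=(1, 2))
        base = self.tables[:, rows, :].sum(axis=(1, 2))
        return np.divide(joint, base, out=np.full(len(base), np.nan),
                         where=base > 0)

    def change_rates(self, initial_freqs: np.ndarray | None = None):
        """Overall change-of-decision and change-of-confidence rates.

        Conditional change probabilities weighted by the initial-category
        frequencies (observed frequencies may be supplied, as when the model
        curves are evaluated against a session; defaults to the model's own
        initial marginals).  Returns ``(decision_rate, confidence_rate)``
        arrays over the coherence axis.
        """
        cond = self.tables / np.maximum(self.tables.sum(axis=2, keepdims=True),
                                        1e-300)
        if initial_freqs is None:
            initial_freqs = self.tables.sum(axis=2)
        dec_mask = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                             [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        conf_mask = np.array([[0, 1, 0, 1], [1, 0, 1, 0],
                              [0, 1, 0, 1], [1, 0, 1, 0]], dtype=float)
        dec = np.einsum("ci,cij,ij->c", initial_freqs, cond, dec_mask)
        conf = np.einsum("ci,cij,ij->c", initial_freqs, cond, conf_mask)
        return dec, conf

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (coherence, initial_cat, final_cat, probability) table."""
        rows = []
        for i, c in enumerate(self.coherences):
            for a, ic in enumerate(CATEGORIES):
                for b, fc in enumerate(CATEGORIES):
                    rows.append((float(c), ic, fc, float(self.tables[i, a, b])))
        return pd.DataFrame(rows, columns=["coherence", "initial_cat",
                                           "final_cat", "probability"])


def _zone_to_category(initial_correct: bool) -> list[int]:
    """Final-category column index for each zone of :data:`FINAL_ZONES`."""
    if initial_correct:
        return [0, 1, 3, 2]  # same = correct: high, low; opposite = error: low, high
    return [2, 3, 1, 0]


def outcome_table(params: RaceParams, crit: ConfidenceCriterion,
                  rev: RevisionParams, bmap: BeliefMap,
                  coherence_set, solutions: dict | None = None,
                  atoms_cache: dict | None = None,
                  **flux_kwargs) -> OutcomeTable:
    """Full initial x final joint probability tables per signed coherence.

    Composes :func:`propagate_post_initiation` with
    :func:`final_zone_thresholds`.  At 0% coherence the post-initiation drift
    is zero and the random reward designation symmetrizes the sheet.
    Propagates :class:`InvalidZoneError` for inadmissible shift parameters.
    ``atoms_cache`` (unsigned coherence -> :class:`PostInitiationAtoms`) lets
    repeated calls share the atom classification.
    """
    thresholds = {conf: final_zone_thresholds(crit, rev, conf)
                  for conf in ("high", "low")}
    levels = sorted({lv for trip in thresholds.values() for lv in trip})
    cs = np.asarray(coherence_set, dtype=float)
    tables = np.zeros((len(cs), 4, 4))
    cache: dict[float, np.ndarray] = {}
    dstar_cache: dict[bytes, np.ndarray] = {}
    for i, c in enumerate(cs):
        a = abs(float(c))
        if a in cache:
            tables[i] = cache[a]
            continue
        atoms = None if atoms_cache is None else atoms_cache.get(a)
        if atoms is None:
            sol = None if solutions is None else solutions.get(a)
            if sol is None:
                sol = absorption_flux(params, a, **flux_kwargs)
            atoms = PostInitiationAtoms(params, bmap, a, sol, crit)
            if atoms_cache is not None:
                atoms_cache[a] = atoms
        dist = atoms.distribution(rev.t_pip)
        dstar_all = None
        if dist.sd != 0.0:
            key = atoms.time_grid.tobytes()
            if key not in dstar_cache:
                dstar_cache[key] = dist._dstar(np.array(levels))
            dstar_all = dstar_cache[key]
        zp = dist.zone_probabilities(thresholds, levels=levels,
                                     dstar_all=dstar_all)
        init_mass = atoms.init_mass / atoms.init_mass.sum()
        sheet = np.zeros((4, 4))
        for r, cat in enumerate(CATEGORIES):
            cols = _zone_to_category(cat.startswith("correct"))
            if np.isnan(zp[cat]).any():
                continue  # empty initial category carries no mass
            for z in range(4):
                sheet[r, cols[z]] += init_mass[r] * zp[cat][z]
        if a == 0.0:
            swap = [2, 3, 0, 1]
            sheet = 0.5 * (sheet + sheet[swap][:, swap])
        tables[i] = sheet
        cache[a] = sheet
    return OutcomeTable(cs, tables)
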