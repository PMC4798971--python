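"""Trial screening, trajectory-based change detection, and choice/confidence
statistics.

The change detector mirrors the experimental analysis: the final report is
the target the hand reaches; an initial report differing from it is inferred
when the area between the hand path and the dividing line (vertical for
direction, horizontal for confidence) on the side opposite the final choice
exceeds 0.1 cm^2.  The logistic analyses quantify how motion strength drives
confidence and how confidence splits choice sensitivity; the odds-ratio
analysis quantifies the confidence-accuracy coupling and its apparent
inflation when confidence is read out after post-initiation processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest

from .simulate import PAYOFFS, TargetGeometry

__all__ = [
    "ChangeClassification",
    "OddsRatioResult",
    "exclude_trials",
    "detect_change",
    "classify_trajectories",
    "logistic_confidence",
    "logistic_choice_with_confidence",
    "odds_ratio_analysis",
    "points_accounting",
    "AREA_CRITERION",
    "MIN_RT",
]

#: Reaction-time screening threshold (s); trials strictly faster are dropped.
MIN_RT = 0.150

#: Opposite-side area (cm^2) above which an initial report differing from
#: the final one is inferred.
AREA_CRITERION = 0.1


def exclude_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with reaction time below 150 ms (strictly less than).

    The number removed is recorded in ``attrs['n_excluded_rt']``.
    """
    keep = table["rt"] >= MIN_RT
    out = table[keep].reset_index(drop=True)
    out.attrs.update(table.attrs)
    out.attrs["n_excluded_rt"] = int((~keep).sum())
    return out


@dataclass
class ChangeClassification:
    """Initial/final targets inferred from one reach path.

    Targets are (choice, confidence) pairs with choice +1 right / -1 left.
    ``area_vertical``/``area_horizontal`` are the hand-path areas (cm^2) on
    the side of each dividing line opposite the final choice.
    """

    initial_choice: int
    initial_conf: str
    final_choice: int
    final_conf: str
    change_of_decision: bool
    change_of_confidence: bool
    area_vertical: float
    area_horizontal: float


def _opposite_side_area(along: np.ndarray, across: np.ndarray,
                        final_sign: float) -> float:
    """Area between the path and a dividing line on the side opposite ``final_sign``.

    ``across`` is the coordinate perpendicular to the line, ``along`` the
    coordinate along it; contributions are accumulated with |d(along)| so
    that backtracking cannot cancel an excursion.
    """
    opp = np.clip(-final_sign * across, 0.0, None)
    seg = 0.5 * (opp[1:] + opp[:-1]) * np.abs(np.diff(along))
    return float(seg.sum())


def detect_change(trajectory: pd.DataFrame,
                  geometry: TargetGeometry | None = None,
                  layout: str = "A",
                  area_criterion: float = AREA_CRITERION) -> ChangeClassification:
    """Classify one trajectory (columns t, x, y, in cm) into initial/final reports.

    The final target is read from the endpoint; the initial direction and
    confidence are flipped relative to the final ones when the opposite-side
    area about the vertical (respectively horizontal) dividing line exceeds
    the criterion.  The path is evaluated from where the hand leaves the
    home region (1 cm radius) to the end.
    """
    if geometry is None:
        geometry = TargetGeometry()
    x = trajectory["x"].to_numpy()
    y = trajectory["y"].to_numpy()
    r = np.hypot(x, y)
    outside = np.nonzero(r > geometry.home_radius)[0]
    if len(outside) == 0:
        raise ValueError("trajectory never leaves the home region")
    i0 = outside[0]
    x, y = x[i0:], y[i0:]
    final_choice = 1 if x[-1] > 0 else -1
    up = y[-1] > 0
    final_conf = ("high" if up else "low") if layout == "A" else \
                 ("low" if up else "high")
    area_v = _opposite_side_area(y, x, final_choice)
    vert_sign = 1.0 if up else -1.0
    area_h = _opposite_side_area(x, y, vert_sign)
    chg_dec = area_v > area_criterion
    chg_conf = area_h > area_criterion
    init_choice = -final_choice if chg_dec else final_choice
    init_conf = ({"high": "low", "low": "high"}[final_conf]
                 if chg_conf else final_conf)
    return ChangeClassification(init_choice, init_conf, final_choice,
                                final_conf, chg_dec, chg_conf,
                                area_v, area_h)


def classify_trajectories(trajectories: pd.DataFrame,
                          layouts: pd.Series | None = None,
                          geometry: TargetGeometry | None = None) -> pd.DataFrame:
    """Apply :func:`detect_change` to a long (trial, t, x, y) table."""
    rows = []
    for trial, grp in trajectories.groupby("trial"):
        layout = "A" if layouts is None else layouts.loc[trial]
        c = detect_change(grp, geometry, layout)
        rows.append((trial, c.initial_choice, c.initial_conf, c.final_choice,
                     c.final_conf, c.change_of_decision,
                     c.change_of_confidence, c.area_vertical,
                     c.area_horizontal))
    return pd.DataFrame(rows, columns=[
        "trial", "initial_choice", "initial_conf", "final_choice",
        "final_conf", "change_of_decision", "change_of_confidence",
        "area_vertical", "area_horizontal"]).set_index("trial")


def _fit_logit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0)
            separated = not np.all(np.isfinite(res.bse))
        except Exception:
            res = model.fit_regularized(alpha=1e-6, disp=0)
            separated = True
    return res, separated


def logistic_confidence(trials: pd.DataFrame):
    """Logistic fit of P(high confidence) on unsigned coherence.

    Returns ``(b0, b1, separated)`` for
    ``P(high) = 1 / (1 + exp(-b0 - b1*|C|))``.
    """
    y = (trials["init_conf"] == "high").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both confidence levels must be present")
    X = trials["coherence"].abs().to_numpy()[:, None]
    res, separated = _fit_logit(X, y)
    return float(res.params[0]), float(res.params[1]), separated


def logistic_choice_with_confidence(trials: pd.DataFrame):
    """Logistic fit of P(rightward) with a confidence interaction.

    ``P(right) = 1/(1 + exp(-b0 - b1*C - b2*I - b3*I*C))`` with ``C`` the
    signed coherence and ``I`` the high-confidence indicator.  Returns
    ``(coefs (b0..b3), p_value, separated)`` where ``p_value`` tests the
    one-sided null that high confidence does not steepen sensitivity
    (H0: b3 <= 0).
    """
    y = (trials["init_choice"] == 1).to_numpy(dtype=float)
    C = trials["coherence"].to_numpy()
    I = (trials["init_conf"] == "high").to_numpy(dtype=float)
    if len(np.unique(I)) < 2:
        # degenerate indicator: reduces to the plain logistic in C
        res, separated = _fit_logit(C[:, None], y)
        return (float(res.params[0]), float(res.params[1]), 0.0, 0.0), \
            np.nan, separated
    X = np.column_stack([C, I, I * C])
    res, separated = _fit_logit(X, y)
    b3 = res.params[3]
    se = res.bse[3] if np.isfinite(res.bse[3]) else np.nan
    from scipy.stats import norm as _norm
    p_one_sided = float(_norm.sf(b3 / se)) if np.isfinite(se) else np.nan
    return tuple(float(b) for b in res.params), p_one_sided, separated


@dataclass
class OddsRatioResult:
    """Initial- vs final-confidence odds ratios per unsigned coherence.

    Both ORs use the correct/error designation of the *initial* direction
    choice: ``OR = odds(high | correct) / odds(high | error)``.  Points with
    an empty error cell are excluded (``n_excluded``); CIs are percentile
    bootstrap (N resamples); ``sign_test_p`` is the two-sided sign test of
    OR_final > OR_initial across the retained points.
    """

    table: pd.DataFrame
    n_excluded: int
    sign_test_p: float


def _odds_ratio(high: np.ndarray, correct: np.ndarray) -> float:
    hc = np.sum(high & correct)
    lc = np.sum(~high & correct)
    he = np.sum(high & ~correct)
    le = np.sum(~high & ~correct)
    if min(hc, lc, he, le) == 0:
        return np.nan
    return (hc / lc) / (he / le)


def odds_ratio_analysis(trials: pd.DataFrame, n_boot: int = 1000,
                        seed: int = 0) -> OddsRatioResult:
    """Odds-ratio comparison of initial vs final confidence reports.

    Computed per unsigned coherence.  Returns per-point estimates with
    bootstrap CIs and the across-point sign test of the final OR exceeding
    the initial OR (zero-coherence points, where correctness is arbitrary
    designation, are included only if both cells are populated; points
    without errors are excluded as undefined).
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_excluded = 0
    for c, sub in trials.groupby(trials["coherence"].abs()):
        correct = sub["init_correct"].to_numpy(dtype=bool)
        hi_init = (sub["init_conf"] == "high").to_numpy()
        hi_fin = (sub["final_conf"] == "high").to_numpy()
        or_i = _odds_ratio(hi_init, correct)
        or_f = _odds_ratio(hi_fin, correct)
        if not (np.isfinite(or_i) and np.isfinite(or_f)):
            n_excluded += 1
            continue
        n = len(sub)
        boots_i = np.empty(n_boot)
        boots_f = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots_i[b] = _odds_ratio(hi_init[idx], correct[idx])
            boots_f[b] = _odds_ratio(hi_fin[idx], correct[idx])
        ok = np.isfinite(boots_i) & np.isfinite(boots_f)
        ci_i = np.nanpercentile(boots_i[ok], [2.5, 97.5])
        ci_f = np.nanpercentile(boots_f[ok], [2.5, 97.5])
        p_boot = float(np.mean(boots_f[ok] <= boots_i[ok]))
        rows.append((float(c), or_i, ci_i[0], ci_i[1],
                     or_f, ci_f[0], ci_f[1], p_boot))
    table = pd.DataFrame(rows, columns=[
        "coherence", "or_initial", "or_initial_lo", "or_initial_hi",
        "or_final", "or_final_lo", "or_final_hi", "p_boot"])
    n_above = int((table.or_final > table.or_initial).sum())
    n_pts = len(table)
    sign_p = binomtest(n_above, n_pts, 0.5).pvalue if n_pts else np.nan
    return OddsRatioResult(table, n_excluded, float(sign_p))


def points_accounting(trials: pd.DataFrame):
    """Points from the payoff matrix and the benefit of changing one's mind.

    Points are awarded on the final report (+2/-3 high risk, +1/-1 low
    risk).  The change benefit is the mean, over change-of-mind trials only,
    of (points earned) minus (points had the initial report stood).
    Returns ``(per-trial points Series, mean change benefit or nan)``.
    """
    fin_pts = np.array([PAYOFFS[(conf, bool(corr))] for conf, corr in
                        zip(trials["final_conf"], trials["final_correct"])])
    init_correct_if_stood = trials["init_choice"].to_numpy() == trials["direction"].to_numpy()
    init_pts = np.array([PAYOFFS[(conf, bool(corr))] for conf, corr in
                         zip(trials["init_conf"], init_correct_if_stood)])
    changed = ((trials["init_choice"] != trials["final_choice"])
               | (trials["init_conf"] != trials["final_conf"])).to_numpy()
    benefit = float(np.mean(fin_pts[changed] - init_pts[changed])) \
        if changed.any() else np.nan
    return pd.Series(fin_pts, index=trials.index, name="points"), benefit
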