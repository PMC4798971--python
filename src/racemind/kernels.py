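"""Motion-energy filtering of dot movies and psychophysical kernels.

The net motion energy of a stochastic dot movie is obtained by convolving
the space-time sequence of dots with an opponent pair of quadrature
spatiotemporal filters selective for rightward and leftward motion, summing
the oriented energy over space, and subtracting leftward from rightward.
Averaging per-trial energy *residuals* (after removing the mean of each
coherence-by-direction condition) conditioned on the report yields
psychophysical kernels: the time course over which stimulus fluctuations
influenced the choice, the confidence, and their revision.  The decay of the
movement-aligned kernel carries an estimate of the non-decision time,
recovered by fitting a scaled complementary cumulative Gaussian convolved
with the filter's impulse response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

__all__ = [
    "MotionFilterConfig",
    "EnergyTrace",
    "KernelFit",
    "motion_energy",
    "filter_impulse_response",
    "energy_residuals",
    "psychophysical_kernels",
    "fit_nondecision_from_kernel",
    "simulate_trials_from_movies",
]


@dataclass(frozen=True)
class MotionFilterConfig:
    """Constants of the opponent motion-energy filter.

    Spatial quadrature pair: fourth-order Cauchy functions with envelope
    ``sigma_c`` (deg); temporal pair: ``(k t)^n exp(-k t)`` difference
    filters with rate ``k`` (1/s) and orders 3 and 5.  With the defaults the
    preferred displacement matches the coherent dot step (5 deg/s at a
    40 ms interleave).  ``dx`` is the spatial sampling of the dot histogram
    and ``x_half`` the half-width of the spatial kernels (deg).
    """

    sigma_c: float = 0.35
    k: float = 60.0
    dx: float = 0.05
    x_half: float = 1.0
    t_span: float = 0.3
    frame_rate: float = 75.0

    def spatial_kernels(self):
        x = np.arange(-self.x_half, self.x_half + self.dx / 2, self.dx)
        a = np.arctan2(x, self.sigma_c)
        env = np.cos(a) ** 4
        return x, env * np.cos(4 * a), env * np.sin(4 * a)

    def temporal_kernels(self):
        t = np.arange(0.0, self.t_span, 1.0 / self.frame_rate)
        kt = self.k * t
        g1 = kt ** 3 * np.exp(-kt) * (1.0 / 6.0 - kt ** 2 / 120.0)
        g2 = kt ** 5 * np.exp(-kt) * (1.0 / 120.0 - kt ** 2 / 5040.0)
        return t, g1, g2


@dataclass
class EnergyTrace:
    """Net rightward-minus-leftward motion energy over time for one movie."""

    time: np.ndarray
    energy: np.ndarray
    coherence: float
    direction: int

    def __len__(self) -> int:
        return len(self.time)


def _dot_histogram(movie, config: MotionFilterConfig):
    """Space-time dot-count image: rows are frames, columns x bins.

    The filters carry no y structure, so dots are pooled over y (energy is
    summed across space downstream in any case).
    """
    r = movie.aperture / 2.0
    edges = np.arange(-(r + config.x_half), r + config.x_half + config.dx,
                      config.dx)
    img = np.zeros((len(movie.frames), len(edges) - 1))
    for i, f in enumerate(movie.frames):
        if len(f):
            img[i], _ = np.histogram(f[:, 0], bins=edges)
    return img


def motion_energy(movie, config: MotionFilterConfig | None = None) -> EnergyTrace:
    """Opponent motion energy of a dot movie, summed over space.

    Convolves the dot histogram with the quadrature spatiotemporal filter
    pairs, forms rightward and leftward oriented energies, sums over space
    and returns the net (right minus left) trace on the movie's frame times.
    """
    if config is None:
        config = MotionFilterConfig()
    if len(movie.frames) == 0:
        raise ValueError("empty movie")
    img = _dot_histogram(movie, config)
    _, f_even, f_odd = config.spatial_kernels()
    _, g_fast, g_slow = config.temporal_kernels()

    def conv(space_k, time_k):
        s = np.apply_along_axis(np.convolve, 1, img, space_k, "same")
        out = np.apply_along_axis(np.convolve, 0, s, time_k, "full")
        return out[: img.shape[0]]

    ef, es = conv(f_even, g_fast), conv(f_even, g_slow)
    of, os_ = conv(f_odd, g_fast), conv(f_odd, g_slow)
    right = (ef + os_) ** 2 + (of - es) ** 2
    left = (ef - os_) ** 2 + (of + es) ** 2
    net = (right - left).sum(axis=1)
    t = np.arange(img.shape[0]) / movie.frame_rate
    return EnergyTrace(t, net, getattr(movie, "coherence", np.nan),
                       getattr(movie, "direction", 0))


def filter_impulse_response(config: MotionFilterConfig | None = None,
                            n_frames: int = 45) -> EnergyTrace:
    """Filter response to a two-stroke rightward impulse at t = 0.

    A single dot appears at the origin and re-appears one coherent step to
    the right three frames later (the interleaving of the dot-movie
    protocol); the returned trace is the net-energy impulse response used by
    :func:`fit_nondecision_from_kernel`.
    """
    if config is None:
        config = MotionFilterConfig()
    step = 5.0 * 3.0 / config.frame_rate  # matched coherent displacement

    class _Movie:
        aperture = 5.0
        frame_rate = config.frame_rate
        frames = [np.array([[0.0, 0.0]])] + [np.zeros((0, 2))] * 2 \
            + [np.array([[step, 0.0]])] + [np.zeros((0, 2))] * (n_frames - 4)

    return motion_energy(_Movie(), config)


def energy_residuals(traces: list, trials: pd.DataFrame,
                     max_coherence: float = 0.064,
                     min_trials: int = 2):
    """Per-trial motion-energy residuals for the weak-motion trials.

    Subtracts, per time bin, the mean of all trials sharing the same signed
    coherence and direction; only trials with unsigned coherence at or below
    ``max_coherence`` enter.  Traces may have unequal lengths (energy is
    only defined while the stimulus was shown); missing bins are NaN.
    Returns ``(residual matrix (n_kept, T), kept row index)``.
    """
    idx = np.asarray(trials.index)
    ac = trials["coherence"].abs().to_numpy()
    keep = ac <= max_coherence + 1e-12
    T = max(len(tr) for tr in traces)
    mat = np.full((len(traces), T), np.nan)
    for i, tr in enumerate(traces):
        mat[i, : len(tr)] = tr.energy
    key = list(zip(trials["coherence"].round(6), trials["direction"]))
    kept_rows = []
    out = []
    for cond in sorted(set(k for k, m in zip(key, keep) if m)):
        rows = [i for i, (k, m) in enumerate(zip(key, keep)) if m and k == cond]
        if len(rows) < min_trials:
            warnings.warn(f"condition {cond} has fewer than {min_trials} "
                          "trials; excluded", RuntimeWarning, stacklevel=2)
            continue
        sub = mat[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=0)
        out.append(sub - mean[None, :])
        kept_rows.extend(rows)
    if not out:
        return np.zeros((0, T)), np.array([], dtype=idx.dtype)
    order = np.argsort(kept_rows)
    return np.vstack(out)[order], idx[np.sort(kept_rows)]


def _movement_align(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-index rows so each trial's last defined bin sits at time 0."""
    n, T = mat.shape
    out = np.full((n, T), np.nan)
    for i in range(n):
        valid = np.nonzero(np.isfinite(mat[i]))[0]
        if len(valid) == 0:
            continue
        last = valid[-1]
        out[i, T - 1 - last:] = mat[i, : last + 1]
    times = (np.arange(T) - (T - 1)).astype(float)
    return out, times


def psychophysical_kernels(residuals: np.ndarray, trials: pd.DataFrame,
                           grouping: str = "choice",
                           alignment: str = "onset",
                           min_trials: int = 10,
                           frame_rate: float = 75.0) -> pd.DataFrame:
    """Report-conditioned averages of motion-energy residuals.

    ``grouping``: 'choice' (rightward vs leftward initial choice),
    'confidence-within-choice' (choice x initial confidence), or
    'change-type' (changes of decision; confidence high-to-low and
    low-to-high).  ``alignment``: 'onset' (time from stimulus onset) or
    'movement' (time to movement onset, negative).  Time bins supported by
    fewer than ``min_trials`` trials are dropped; empty groups are omitted
    with a warning.  Returns a tidy frame (group, time, mean, sem, n).
    """
    trials = trials.reset_index(drop=True)
    if grouping == "choice":
        groups = {"right": trials.init_choice == 1,
                  "left": trials.init_choice == -1}
    elif grouping == "confidence-within-choice":
        groups = {f"{side}_{conf}": (trials.init_choice == s)
                  & (trials.init_conf == conf)
                  for side, s in (("right", 1), ("left", -1))
                  for conf in ("high", "low")}
    elif grouping == "change-type":
        chg_dec = trials.init_choice != trials.final_choice
        groups = {
            "change_decision": chg_dec,
            "conf_high_to_low": (trials.init_conf == "high")
            & (trials.final_conf == "low") & ~chg_dec,
            "conf_low_to_high": (trials.init_conf == "low")
            & (trials.final_conf == "high") & ~chg_dec,
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if alignment == "movement":
        mat, frames = _movement_align(residuals)
    elif alignment == "onset":
        mat, frames = residuals, np.arange(residuals.shape[1], dtype=float)
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    times = frames / frame_rate
    rows = []
    for name, mask in groups.items():
        sub = mat[np.asarray(mask)]
        n_per = np.isfinite(sub).sum(axis=0)
        if (n_per >= min_trials).sum() == 0:
            warnings.warn(f"group {name!r} below the minimum trial count; "
                          "omitted", RuntimeWarning, stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=0)
            sd = np.nanstd(sub, axis=0, ddof=1)
        sem = sd / np.sqrt(np.maximum(n_per, 1))
        ok = n_per >= min_trials
        for t, m, s, k in zip(times[ok], mean[ok], sem[ok], n_per[ok]):
            rows.append((name, float(t), float(m), float(s), int(k)))
    return pd.DataFrame(rows, columns=["group", "time", "mean", "sem", "n"])


@dataclass
class KernelFit:
    """Non-decision time recovered from a movement-aligned kernel."""

    alpha: float
    mu_tnd: float
    sigma_tnd: float
    fitted: np.ndarray
    success: bool


def kernel_model(time: np.ndarray, alpha: float, mu: float, sigma: float,
                 impulse_response: EnergyTrace) -> np.ndarray:
    """Expected movement-aligned kernel: scaled ccdf-Gaussian (*) filter IR.

    ``time`` is relative to movement onset (negative before).  Evidence
    influences the choice until ``mu`` (s) before movement; Gaussian
    trial-to-trial variability (``sigma``) smooths the step into a
    complementary cumulative Gaussian, and the filter impulse response
    delays and smooths it further.
    """
    ir = impulse_response.energy
    w = ir / max(ir.sum(), 1e-12)
    taus = impulse_response.time
    base = lambda x: norm.cdf((-x - mu) / max(sigma, 1e-6))
    out = np.zeros_like(time, dtype=float)
    for tau, wi in zip(taus, w):
        out += wi * base(time - tau)
    return alpha * out


def fit_nondecision_from_kernel(time: np.ndarray, kernel: np.ndarray,
                                impulse_response: EnergyTrace,
                                p0=(1.0, 0.35, 0.08)) -> KernelFit:
    """Least-squares fit of (alpha, mu_tnd, sigma_tnd) to a kernel.

    ``time`` must be movement-aligned (non-positive, 0 at movement onset).
    A kernel whose dynamic range does not exceed its noise is flagged as a
    failed (non-identifiable) fit.
    """
    time = np.asarray(time, float)
    kernel = np.asarray(kernel, float)
    ok = np.isfinite(kernel)
    time, kernel = time[ok], kernel[ok]
    model = lambda x, a, m, s: kernel_model(x, a, m, s, impulse_response)
    try:
        popt, _ = curve_fit(model, time, kernel, p0=p0,
                            bounds=([0.0, 0.0, 0.0],
                                    [np.inf, 2.0, 1.0]), maxfev=5000)
    except (RuntimeError, ValueError):
        return KernelFit(np.nan, np.nan, np.nan, np.full_like(kernel, np.nan),
                         False)
    fitted = model(time, *popt)
    resid_sd = np.std(kernel - fitted)
    identifiable = np.ptp(fitted) > 2.0 * resid_sd
    return KernelFit(float(popt[0]), float(popt[1]), float(popt[2]), fitted,
                     bool(identifiable))


def simulate_trials_from_movies(movies: list, params, crit=None, bmap=None,
                                gain: float = 1.0, seed: int = 0,
                                tnd_draw: bool = True) -> pd.DataFrame:
    """Closed-loop race simulation driven by each movie's own motion energy.

    The momentary evidence of the rightward accumulator is
    ``gain * net_energy(t)`` (and its negative for the leftward one) plus
    correlated diffusion noise, so stimulus fluctuations causally influence
    the simulated reports — the ground truth for kernel analyses.  Returns a
    trial table aligned with ``movies``; trials that reach no bound while
    the movie lasts decide by the sign of the final balance (flagged
    ``censored``).
    """
    from .race import RaceParams  # typing only; avoids an import cycle
    rng = np.random.default_rng(seed)
    rho = params.corr
    a2 = math.sqrt(1.0 - rho * rho)
    rows = []
    for i, mv in enumerate(movies):
        tr = motion_energy(mv)
        dt = 1.0 / mv.frame_rate
        sdt = math.sqrt(dt)
        x1 = x2 = 0.0
        t_dec = np.nan
        winner = 0
        for j, e in enumerate(tr.energy):
            mu = gain * e
            z = rng.standard_normal(2)
            x1 += mu * dt + sdt * z[0]
            x2 += -mu * dt + sdt * (rho * z[0] + a2 * z[1])
            if x1 >= params.bound or x2 >= params.bound:
                winner = 1 if x1 >= x2 else -1
                t_dec = (j + 1) * dt
                break
        censored = not np.isfinite(t_dec)
        if censored:
            winner = 1 if x1 >= x2 else -1
            t_dec = len(tr.energy) * dt
        delta = abs(x1 - x2) if censored else params.bound - min(x1, x2)
        tnd = params.tnd_mean + (params.tnd_sd * rng.standard_normal()
                                 if tnd_draw else 0.0)
        conf = "high"
        lo = np.nan
        if bmap is not None and crit is not None:
            lo = float(bmap.log_odds(t_dec, delta))
            conf = "high" if lo >= crit.theta else "low"
        rows.append((i, mv.coherence * mv.direction, mv.direction, t_dec,
                     t_dec + tnd, winner, conf, lo, censored))
    df = pd.DataFrame(rows, columns=["movie", "coherence", "direction",
                                     "decision_time", "rt", "init_choice",
                                     "init_conf", "logodds_initial",
                                     "censored"])
    df["init_correct"] = df.init_choice == df.direction
    return df
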