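"""Synthetic behavioral data: simulated trials, reach trajectories, dot movies.

Everything the analysis pipeline consumes can be generated here.  The trial
simulator is a correlated-noise Euler realization of the race and serves as
the Monte-Carlo oracle against the analytic machinery; per step it also
applies a Brownian-bridge crossing test per accumulator, which removes the
leading-order late-absorption bias of a pure end-point check.  Trajectories
are minimum-jerk reaches with mid-flight re-plans on change-of-mind trials
(kinematic fixtures for the change detector, not a biomechanical model), and
dot movies follow the three-interleaved-set random-dot protocol with
per-dot Bernoulli(coherence) coherent displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief import BeliefMap, ConfidenceCriterion, build_belief_map
from .race import RaceParams
from .revision import RevisionParams, final_zone_thresholds

__all__ = [
    "SessionDesign",
    "DotMovie",
    "TargetGeometry",
    "simulate_trials",
    "synthesize_trajectories",
    "generate_dot_movie",
    "PAYOFFS",
]

#: Points for (confidence, correctness) of the final report: the high-risk
#: target pays +2/-3, the low-risk target +1/-1.
PAYOFFS = {("high", True): 2.0, ("high", False): -3.0,
           ("low", True): 1.0, ("low", False): -1.0}

#: The experimental signed coherence set (proportions): 12 levels, with 0%
#: appearing twice (its arbitrary sign designates the rewarded direction).
COHERENCE_SET = tuple(np.concatenate([
    -np.array([51.2, 25.6, 12.8, 6.4, 3.2, 0.0]) / 100.0,
    np.array([0.0, 3.2, 6.4, 12.8, 25.6, 51.2]) / 100.0,
]))


@dataclass(frozen=True)
class SessionDesign:
    """Trial composition and session structure of the reaching task.

    Defaults reproduce the experimental design: 12 signed coherences, 768
    trials per signed coherence (12 sessions of 4 blocks), block target
    layouts ordered ABBA/BAAB alternating between sessions, double-pass
    stimulus pairing (each dot movie and its horizontal mirror shown twice)
    and a truncated-exponential foreperiod on 0.5-2.0 s with mean 0.82 s.
    """

    coherences: tuple = COHERENCE_SET
    trials_per_coherence: int = 768
    block_layouts: tuple = ("A", "B", "B", "A")
    double_pass: bool = True
    foreperiod_range: tuple = (0.5, 2.0)
    foreperiod_mean: float = 0.82

    def n_trials(self) -> int:
        return len(self.coherences) * self.trials_per_coherence

    def sample_foreperiod(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.foreperiod_range
        # exponential with rate chosen so the truncated mean matches
        tau = self.foreperiod_mean - lo  # good approximation when hi >> tau
        out = lo + rng.exponential(tau, size=2 * n + 16)
        out = out[out <= hi][:n]
        while len(out) < n:
            extra = lo + rng.exponential(tau, size=n)
            out = np.concatenate([out, extra[extra <= hi]])[:n]
        return out


def _euler_race(params: RaceParams, coherences: np.ndarray, dt: float,
                t_cap: float, rng: np.random.Generator):
    """Vectorized Euler-Maruyama race with per-step bridge crossing tests.

    Returns (decision_time, winner index 0=right/1=left, loser_state,
    winner_state, absorbed mask).
    """
    n = len(coherences)
    x = np.zeros((n, 2))
    mu = np.stack([params.kappa * coherences, -params.kappa * coherences], axis=1)
    B = params.bound
    rho = params.corr
    a2 = math.sqrt(1.0 - rho * rho)
    sdt = math.sqrt(dt)
    n_steps = int(round(t_cap / dt))
    t_dec = np.full(n, np.nan)
    winner = np.full(n, -1, dtype=int)
    loser_state = np.full(n, np.nan)
    winner_state = np.full(n, np.nan)
    active = np.arange(n)
    for step in range(1, n_steps + 1):
        m = len(active)
        if m == 0:
            break
        e = rng.standard_normal((m, 2))
        dw1 = sdt * e[:, 0]
        dw2 = sdt * (rho * e[:, 0] + a2 * e[:, 1])
        xa = x[active]
        x_new = xa + mu[active] * dt + np.stack([dw1, dw2], axis=1)
        crossed = x_new >= B
        # Brownian-bridge probability of an intra-step excursion above B
        u = rng.random((m, 2))
        with np.errstate(over="ignore"):
            p_bridge = np.exp(-2.0 * np.clip(B - xa, 0.0, None)
                              * np.clip(B - x_new, 0.0, None) / dt)
        crossed |= (~crossed) & (u < p_bridge)
        any_cross = crossed.any(axis=1)
        if any_cross.any():
            hit = active[any_cross]
            ch = crossed[any_cross]
            both = ch.all(axis=1)
            w = np.where(ch[:, 0], 0, 1)
            if both.any():  # rare: O(dt) probability; tie-break at random
                w[both] = rng.integers(0, 2, size=both.sum())
            winner[hit] = w
            t_dec[hit] = step * dt
            xe = x_new[any_cross]
            loser_state[hit] = np.where(w == 0, xe[:, 1], xe[:, 0])
            winner_state[hit] = np.where(w == 0, xe[:, 0], xe[:, 1])
        x[active] = x_new
        active = active[~any_cross]
    absorbed = winner >= 0
    return t_dec, winner, loser_state, winner_state, absorbed, x


def simulate_trials(params: RaceParams, crit: ConfidenceCriterion,
                    rev: RevisionParams, design: SessionDesign | None = None,
                    seed: int = 0, dt: float = 5e-4, t_cap: float = 5.0,
                    bmap: BeliefMap | None = None,
                    keep_censored: bool = False) -> pd.DataFrame:
    """Simulate full trials: race, belief lookup, post-initiation revision.

    Returns a trial table with one row per trial.  Columns (units s and
    evidence units): ``coherence`` (signed), ``direction`` (designated
    rewarded direction, +1 right / -1 left; random at 0%), ``decision_time``,
    ``tnd`` (per-trial non-decision time), ``rt``, ``delta_dec`` and
    ``delta_pip`` (oriented evidence balance at decision and after the
    post-initiation period), ``logodds_initial``/``logodds_final``,
    ``init_choice``/``final_choice`` (+1/-1), ``init_conf``/``final_conf``
    ('high'/'low'), ``init_correct``/``final_correct``, ``points``,
    ``foreperiod``, ``layout``.  Unabsorbed trials at ``t_cap`` are censored
    and dropped (kept with ``censored=True`` when requested); the dropped
    count is recorded in ``DataFrame.attrs['n_censored']`` alongside the
    seed provenance.
    """
    if dt > 1e-3 or dt <= 0:
        raise ValueError("Euler step must be positive and at most 1 ms")
    if design is None:
        design = SessionDesign()
    rng = np.random.default_rng(seed)
    cs = np.repeat(np.asarray(design.coherences, float),
                   design.trials_per_coherence)
    rng.shuffle(cs)
    n = len(cs)
    if bmap is None:
        # pass the design's signed levels directly: a twice-presented 0%
        # level carries twice the prior weight
        bmap = build_belief_map(params, np.asarray(design.coherences))

    direction = np.sign(cs).astype(int)
    zero = direction == 0
    direction[zero] = rng.choice([-1, 1], size=zero.sum())

    t_dec, winner, loser, winner_x, absorbed, x_end = _euler_race(
        params, cs, dt, t_cap, rng)

    # post-initiation: continue the unbounded pair by Euler for t_pip
    n_pip = int(round(rev.t_pip / dt))
    x = x_end.copy()
    mu = np.stack([params.kappa * cs, -params.kappa * cs], axis=1)
    rho = params.corr
    a2 = math.sqrt(1.0 - rho * rho)
    sdt = math.sqrt(dt)
    for _ in range(n_pip):
        e = rng.standard_normal((n, 2))
        x[:, 0] += mu[:, 0] * dt + sdt * e[:, 0]
        x[:, 1] += mu[:, 1] * dt + sdt * (rho * e[:, 0] + a2 * e[:, 1])

    init_choice = np.where(winner == 0, 1, -1)
    # balance oriented toward the winner; the winner is pinned at the bound
    # (the map's convention), and the post-initiation balance adds the
    # simulated free increment to that pinned value
    delta_dec = params.bound - loser
    inc = (np.where(winner == 0, x[:, 0] - x[:, 1], x[:, 1] - x[:, 0])
           - (winner_x - loser))
    delta_pip = delta_dec + inc

    lo_init = bmap.log_odds(np.nan_to_num(t_dec, nan=1.0), delta_dec)
    lo_final = bmap.log_odds(np.nan_to_num(t_dec, nan=1.0) + rev.t_pip,
                             delta_pip)
    init_high = lo_init >= crit.theta

    thr = {conf: final_zone_thresholds(crit, rev, conf)
           for conf in ("high", "low")}
    up = np.where(init_high, thr["high"][0], thr["low"][0])
    mid, low = thr["high"][1], thr["high"][2]
    zone = np.select([lo_final >= up, lo_final >= mid, lo_final >= low],
                     [0, 1, 2], default=3)
    final_choice = np.where(zone <= 1, init_choice, -init_choice)
    final_high = (zone == 0) | (zone == 3)

    tnd = params.tnd_mean + params.tnd_sd * rng.standard_normal(n)
    init_correct = init_choice == direction
    final_correct = final_choice == direction
    conf_lbl = np.array(["low", "high"])
    points = np.array([PAYOFFS[(c, bool(k))] for c, k in
                       zip(conf_lbl[final_high.astype(int)], final_correct)])
    layouts = np.asarray(design.block_layouts)
    layout = layouts[(np.arange(n) * len(layouts)) // max(n, 1)]

    df = pd.DataFrame({
        "coherence": cs,
        "direction": direction,
        "decision_time": t_dec,
        "tnd": tnd,
        "rt": t_dec + tnd,
        "delta_dec": delta_dec,
        "delta_pip": delta_pip,
        "logodds_initial": lo_init,
        "logodds_final": lo_final,
        "init_choice": init_choice,
        "init_conf": conf_lbl[init_high.astype(int)],
        "final_choice": final_choice,
        "final_conf": conf_lbl[final_high.astype(int)],
        "init_correct": init_correct,
        "final_correct": final_correct,
        "points": points,
        "foreperiod": design.sample_foreperiod(rng, n),
        "layout": layout,
        "censored": ~absorbed,
    })
    n_cens = int((~absorbed).sum())
    if not keep_censored:
        df = df[absorbed].reset_index(drop=True)
    df.attrs["n_censored"] = n_cens
    df.attrs["seed"] = seed
    df.attrs["dt"] = dt
    df.attrs["t_cap"] = t_cap
    return df


@dataclass(frozen=True)
class TargetGeometry:
    """Workspace geometry: home at the origin, targets on a square.

    ``half`` is half the target-square side (targets sit at the corners of a
    17 x 17 cm square); layout 'A' places the high-confidence targets at the
    top, layout 'B' at the bottom.  Sampling at 1000 Hz.
    """

    half: float = 8.5
    target_radius: float = 1.5
    home_radius: float = 1.0
    sample_rate: float = 1000.0

    def target_xy(self, choice: int, conf: str, layout: str = "A") -> np.ndarray:
        x = self.half * float(choice)
        up = (conf == "high") == (layout == "A")
        return np.array([x, self.half if up else -self.half])


def _min_jerk(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n)[:, None]
    blend = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
    return p0[None, :] + (p1 - p0)[None, :] * blend


def synthesize_trajectories(trials: pd.DataFrame,
                            geometry: TargetGeometry | None = None,
                            seed: int = 0,
                            duration_mean: float = 0.55,
                            duration_sd: float = 0.05,
                            noise_sd: float = 0.03,
                            replan_range: tuple = (0.2, 0.8)) -> pd.DataFrame:
    """Minimum-jerk reach paths with mid-flight re-plans on change trials.

    On change-of-mind trials the path re-plans toward the final target at a
    uniform draw within the middle 60% of the movement (``replan_range`` as
    fractions of movement time); a re-plan drawn before the hand clears the
    1 cm home region leaves no detectable excursion, as in the task.  Smooth
    (low-pass filtered) Gaussian noise is added to both coordinates.
    Returns a long table (trial, t, x, y) at the geometry's sampling rate.
    """
    if geometry is None:
        geometry = TargetGeometry()
    rng = np.random.default_rng(seed)
    frames = []
    for idx, row in trials.iterrows():
        layout = row.get("layout", "A")
        p_init = geometry.target_xy(row.init_choice, row.init_conf, layout)
        p_final = geometry.target_xy(row.final_choice, row.final_conf, layout)
        T = max(duration_mean + duration_sd * rng.standard_normal(), 0.35)
        n = int(T * geometry.sample_rate)
        if np.allclose(p_init, p_final):
            path = _min_jerk(np.zeros(2), p_final, n)
        else:
            u = rng.uniform(*replan_range)
            n1 = int(n * u)
            first = _min_jerk(np.zeros(2), p_init, n)[:n1]
            n2 = n - n1 + int(0.3 * n)
            second = _min_jerk(first[-1], p_final, n2)
            path = np.vstack([first, second[1:]])
        noise = rng.standard_normal(path.shape) * noise_sd
        kernel = np.exp(-0.5 * (np.arange(-60, 61) / 20.0) ** 2)
        kernel /= kernel.sum()
        for j in range(2):
            noise[:, j] = np.convolve(noise[:, j], kernel, mode="same")
        # keep start and end anchored
        taper = np.minimum(np.linspace(0, 1, len(path)) * 10, 1.0)
        taper = np.minimum(taper, taper[::-1])
        path = path + noise * taper[:, None]
        t = np.arange(len(path)) / geometry.sample_rate
        frames.append(pd.DataFrame({"trial": idx, "t": t,
                                    "x": path[:, 0], "y": path[:, 1]}))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    return out


@dataclass
class DotMovie:
    """A random-dot kinematogram as per-frame dot coordinates (degrees).

    Three interleaved dot sets are updated every third frame (13.3 ms frames
    at 75 Hz); on each update a dot is displaced coherently by
    ``speed * 3 / frame_rate`` with probability ``coherence``, otherwise
    randomly replaced.  ``aperture`` is the diameter of the circular field.
    """

    frames: list
    coherence: float
    direction: int
    aperture: float = 5.0
    frame_rate: float = 75.0
    density: float = 12.5
    seed: int | None = None

    def mirrored(self) -> "DotMovie":
        """Horizontal mirror (x -> -x): the double-pass partner stimulus."""
        return DotMovie([np.column_stack([-f[:, 0], f[:, 1]]) for f in self.frames],
                        self.coherence, -self.direction, self.aperture,
                        self.frame_rate, self.density, self.seed)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# coherence\t{self.coherence}\n# direction\t{self.direction}\n"
                     f"# aperture\t{self.aperture}\n# frame_rate\t{self.frame_rate}\n")
            fh.write("frame\tx\ty\n")
            for i, f in enumerate(self.frames):
                for x, y in f:
                    fh.write(f"{i}\t{x:.5f}\t{y:.5f}\n")


def _sample_in_circle(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def generate_dot_movie(coherence: float, direction: int, n_frames: int,
                       aperture: float = 5.0, seed: int | None = None,
                       density: float = 12.5, speed: float = 5.0,
                       frame_rate: float = 75.0) -> DotMovie:
    """Generate a random-dot movie with the three-set interleaving protocol.

    ``coherence`` in [0, 1] is the probability that a dot is displaced in
    the motion direction (by ``speed * 3/frame_rate`` degrees) when its set
    is next shown, rather than being randomly replaced.  Dots per frame
    equal density x aperture area x frame duration (rounded).
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    radius = aperture / 2.0
    area = math.pi * radius ** 2
    n_dots = max(int(round(density * area / frame_rate)), 1)
    step = direction * speed * 3.0 / frame_rate
    sets = [_sample_in_circle(rng, n_dots, radius) for _ in range(3)]
    frames = []
    for i in range(n_frames):
        s = i % 3
        if i >= 3:
            dots = sets[s]
            coh = rng.random(n_dots) < coherence
            moved = dots.copy()
            moved[coh, 0] += step
            # wrap coherently displaced dots that exit the aperture
            out = np.hypot(moved[:, 0], moved[:, 1]) > radius
            wrap = coh & out
            if wrap.any():
                moved[wrap, 0] -= np.sign(step) * 2.0 * np.sqrt(
                    np.maximum(radius ** 2 - moved[wrap, 1] ** 2, 0.0))
            repl = ~coh
            moved[repl] = _sample_in_circle(rng, int(repl.sum()), radius)
            sets[s] = moved
        frames.append(sets[s].copy())
    return DotMovie(frames, coherence, direction, aperture, frame_rate,
                    density, seed)
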