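"""Analytic first-passage machinery for an anti-correlated two-accumulator race.

Two accumulators integrate opposite-signed momentary evidence: with signed
coherence ``c``, the rightward accumulator has drift ``+kappa*c`` (per second)
and the leftward accumulator ``-kappa*c``.  Each diffuses with unit variance
per second and the two share noise with correlation ``corr`` in ``(-1, 0]``.
The first accumulator to reach the common upper absorbing bound ``B`` commits
the choice; the decision time plus a Gaussian non-decision time gives the
reaction time.

For correlations of the form ``-cos(pi/k)`` (k integer >= 2) the survival
density of the unabsorbed process has an exact solution by the method of
images: after whitening, the domain (both accumulators below bound) becomes a
planar wedge of angle ``pi/k``, and the dihedral reflection group of that
wedge yields a signed sum of ``2k - 1`` free Gaussian propagators that
vanishes on both absorbing walls.  Constant drift is restored exactly by a
Girsanov (exponential tilting) factor, so no per-image drift correction is
needed.  Supported correlations include 0 (3 images), -0.5 (5 images) and
-cos(pi/4) ~ -0.707 (7 images, the default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RaceParams",
    "AbsorptionSolution",
    "UnsupportedCorrelationError",
    "supported_correlation",
    "wedge_order",
    "image_sources",
    "free_propagator",
    "image_propagator",
    "absorption_flux",
    "minimal_image_count",
    "single_bound_fpt_density",
    "default_time_grid",
    "default_loser_grid",
]

_MAX_WEDGE_ORDER = 64


class UnsupportedCorrelationError(ValueError):
    """Raised when ``corr`` is not of the image-solvable form ``-cos(pi/k)``."""


def supported_correlation(k: int) -> float:
    """Correlation value ``-cos(pi/k)`` solvable with ``2k - 1`` images."""
    if k < 2:
        raise ValueError("wedge order k must be >= 2")
    return -math.cos(math.pi / k)


def wedge_order(corr: float, atol: float = 1e-9) -> int:
    """Return the integer k with ``corr == -cos(pi/k)``.

    Raises
    ------
    UnsupportedCorrelationError
        If ``corr`` is not (numerically) of that form; the message names the
        nearest supported value.
    """
    if not -1.0 < corr <= 0.0:
        raise UnsupportedCorrelationError(
            f"corr must lie in (-1, 0], got {corr!r}"
        )
    k_real = math.pi / math.acos(-corr)
    k = int(round(k_real))
    if k < 2 or abs(supported_correlation(max(k, 2)) - corr) > atol:
        lo = max(2, k)
        candidates = [supported_correlation(j) for j in (lo - 1, lo, lo + 1) if j >= 2]
        nearest = min(candidates, key=lambda v: abs(v - corr))
        raise UnsupportedCorrelationError(
            f"corr={corr:g} is not of the image-solvable form -cos(pi/k); "
            f"nearest supported value is {nearest:.6f}"
        )
    return k


@dataclass(frozen=True)
class RaceParams:
    """Parameters of the anti-correlated race.

    Attributes
    ----------
    kappa : float
        Drift sensitivity (1/s per unit coherence proportion); drift of the
        rightward accumulator is ``kappa * c`` for signed coherence ``c``.
    bound : float
        Common upper absorbing bound B (evidence units), > 0.
    corr : float
        Accumulator noise correlation in (-1, 0]; must equal ``-cos(pi/k)``
        for integer k >= 2 when the analytic solution is used.
    tnd_mean, tnd_sd : float
        Mean and SD (s) of the Gaussian non-decision time.
    diff_var : float
        Per-accumulator diffusion variance per second.  Fixed at 1 as the
        identifiability convention (kappa and bound absorb scale).
    """

    kappa: float
    bound: float
    corr: float = supported_correlation(4)
    tnd_mean: float = 0.4
    tnd_sd: float = 0.06
    diff_var: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not -1.0 < self.corr <= 0.0:
            raise ValueError("corr must lie in (-1, 0]")
        if self.tnd_mean <= 0:
            raise ValueError("tnd_mean must be > 0")
        if self.tnd_sd < 0:
            raise ValueError("tnd_sd must be >= 0")
        if self.diff_var != 1.0:
            raise ValueError("diff_var is fixed at 1 (normalization convention)")

    def drift(self, coherence: float) -> np.ndarray:
        """Drift vector (rightward, leftward) for signed coherence."""
        mu = self.kappa * coherence
        return np.array([mu, -mu])


def _whitener(corr: float) -> np.ndarray:
    """Lower Cholesky factor L of the unit-rate covariance [[1, corr], [corr, 1]]."""
    return np.array([[1.0, 0.0], [corr, math.sqrt(1.0 - corr * corr)]])


def image_sources(corr: float, bound: float) -> tuple[np.ndarray, np.ndarray]:
    """Image source points and signs for the two-bound wedge problem.

    Returns ``(points, signs)`` where ``points`` has shape (2k-1, 2) in the
    original accumulator coordinates (the first row is the true source at the
    origin) and ``signs`` alternates with the number of reflections.  Points
    are ordered by reflection depth, interleaving the two reflection
    sequences, so that truncating the list gives the natural partial sums
    used by :func:`minimal_image_count`.
    """
    k = wedge_order(corr)
    L = _whitener(corr)
    Linv = np.linalg.inv(L)
    # normals of the two absorbing walls in whitened coordinates (unit length)
    n1 = L.T @ np.array([1.0, 0.0])
    n2 = L.T @ np.array([0.0, 1.0])
    shift = np.array([bound, bound])
    y0 = Linv @ (np.zeros(2) - shift)

    def reflect(y: np.ndarray, n: np.ndarray) -> np.ndarray:
        return y - 2.0 * (y @ n) * n

    seq_a, seq_b = [], []
    ya, yb = y0, y0
    for depth in range(1, k + 1):
        ya = reflect(ya, n1 if depth % 2 == 1 else n2)
        yb = reflect(yb, n2 if depth % 2 == 1 else n1)
        seq_a.append((ya, (-1.0) ** depth))
        seq_b.append((yb, (-1.0) ** depth))

    points = [y0]
    signs = [1.0]
    for depth in range(k):
        pa, sa = seq_a[depth]
        points.append(pa)
        signs.append(sa)
        pb, sb = seq_b[depth]
        # the deepest reflection of both sequences coincides: keep one copy
        if depth < k - 1 or np.linalg.norm(pa - pb) > 1e-9:
            points.append(pb)
            signs.append(sb)
    pts = np.array([L @ y + shift for y in points])
    return pts, np.array(signs)


def _sigma_inv(corr: float) -> np.ndarray:
    d = 1.0 - corr * corr
    return np.array([[1.0, -corr], [-corr, 1.0]]) / d


def _girsanov_log(params: RaceParams, coherence: float, x1, x2, t):
    """log of the drift tilting factor exp(mu' Sinv x - 0.5 mu' Sinv mu t)."""
    a = params.kappa * coherence / (1.0 - params.corr)
    return a * (np.asarray(x1) - np.asarray(x2)) - params.kappa ** 2 * coherence ** 2 * np.asarray(t) / (1.0 - params.corr)


def free_propagator(params: RaceParams, coherence: float, t: float,
                    start, end) -> np.ndarray:
    """Transition density of the unbounded pair of accumulators.

    Bivariate Gaussian with mean ``start + t*(kappa*c, -kappa*c)``,
    per-component variance ``t`` and cross-covariance ``t*corr``; integrates
    to 1 over end states.  ``end`` may be an array of shape (..., 2).
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    mean = start + t * params.drift(coherence)
    dev = end - mean
    Sinv = _sigma_inv(params.corr) / t
    det = t * t * (1.0 - params.corr ** 2)
    quad = (dev[..., 0] ** 2 * Sinv[0, 0]
            + 2.0 * dev[..., 0] * dev[..., 1] * Sinv[0, 1]
            + dev[..., 1] ** 2 * Sinv[1, 1])
    return np.exp(-0.5 * quad) / (2.0 * math.pi * math.sqrt(det))


def _image_gauss_sum(points: np.ndarray, signs: np.ndarray, corr: float,
                     x1, x2, t, deriv: int | None = None, log_tilt=None):
    """Signed sum of zero-drift Gaussian kernels N(x; x_j, t*Sigma).

    ``deriv=0`` returns the sum of partial derivatives with respect to x1
    instead of the density (used for the boundary flux); ``deriv=1`` the
    x2-derivative.  ``log_tilt`` is an optional log-factor (the Girsanov
    drift tilt) folded into each term's exponent, which keeps the
    computation finite when the tilt overflows on its own.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    t = np.asarray(t, dtype=float)
    Sinv = _sigma_inv(corr)
    det_unit = 1.0 - corr * corr
    lognorm = -np.log(2.0 * math.pi * math.sqrt(det_unit) * t)
    if log_tilt is not None:
        lognorm = lognorm + log_tilt
    out = 0.0
    for (m1, m2), s in zip(points, signs):
        d1 = x1 - m1
        d2 = x2 - m2
        g1 = (Sinv[0, 0] * d1 + Sinv[0, 1] * d2) / t  # [Sigma_t^-1 (x - m)]_1
        g2 = (Sinv[1, 0] * d1 + Sinv[1, 1] * d2) / t
        quad = d1 * g1 + d2 * g2
        with np.errstate(under="ignore"):
            dens = np.exp(lognorm - 0.5 * quad)
        if deriv is None:
            out = out + s * dens
        elif deriv == 0:
            out = out + s * dens * (-g1)
        else:
            out = out + s * dens * (-g2)
    return out


def image_propagator(params: RaceParams, coherence: float, t, end) -> np.ndarray:
    """Survival density of paths from (0, 0) that have touched neither bound.

    Signed sum of free propagators from the dihedral image sources, tilted by
    the Girsanov drift factor; vanishes on both absorbing boundaries.  ``end``
    must lie strictly inside the domain (both components < bound).
    """
    pts, signs = image_sources(params.corr, params.bound)
    end = np.asarray(end, dtype=float)
    x1, x2 = end[..., 0], end[..., 1]
    if np.any(x1 > params.bound) or np.any(x2 > params.bound):
        raise ValueError("end states must satisfy end_i <= bound")
    return _image_gauss_sum(pts, signs, params.corr, x1, x2, t,
                            log_tilt=_girsanov_log(params, coherence, x1, x2, t))


@dataclass
class AbsorptionSolution:
    """Joint density of (decision time, losing-accumulator state) per winner.

    ``flux`` has shape (2, len(time_grid), len(loser_grid)): sheet 0 is the
    rightward accumulator winning (bound crossing at x1 = B, loser state x2),
    sheet 1 the leftward accumulator winning.  Units: probability per second
    per evidence unit.  ``survival_mass`` is the probability that neither
    bound has been reached by the final grid time.
    """

    time_grid: np.ndarray
    loser_grid: np.ndarray
    flux: np.ndarray
    survival_mass: float
    params: RaceParams
    coherence: float

    def fpt_density(self, winner: int) -> np.ndarray:
        """Winner-specific first-passage-time density on ``time_grid``."""
        return np.trapezoid(self.flux[winner], self.loser_grid, axis=1)

    def p_win(self, winner: int) -> float:
        return float(np.trapezoid(self.fpt_density(winner), self.time_grid))

    def absorbed_mass(self) -> float:
        return self.p_win(0) + self.p_win(1)

    def conservation_defect(self) -> float:
        return abs(1.0 - self.absorbed_mass() - self.survival_mass)

    def mean_decision_time(self, winner: int | None = None) -> float:
        """Mean decision time, optionally conditioned on the winner."""
        if winner is None:
            f = self.fpt_density(0) + self.fpt_density(1)
        else:
            f = self.fpt_density(winner)
        mass = np.trapezoid(f, self.time_grid)
        return float(np.trapezoid(self.time_grid * f, self.time_grid) / mass)


def default_time_grid(t_max: float = 5.0, dt: float = 1e-3) -> np.ndarray:
    return np.arange(dt, t_max + 0.5 * dt, dt)


def default_loser_grid(params: RaceParams, t_max: float = 5.0, n: int = 201,
                       coherence_max: float = 0.512) -> np.ndarray:
    """Loser-state grid from ``bound - span`` to ``bound``, dense near the bound.

    The span covers diffusion (8 sqrt(t_max)) plus the largest drift excursion
    of the losing accumulator over the grid horizon; three quarters of the
    points resolve the 10 evidence units below the bound where the flux has
    structure, the rest cover the drift tail.
    """
    span = 8.0 * math.sqrt(t_max) + params.kappa * coherence_max * t_max
    near = min(10.0, span)
    n_near = max(int(0.75 * n), 2)
    dense = np.linspace(params.bound - near, params.bound, n_near)
    if span <= near:
        return dense
    coarse = np.linspace(params.bound - span, params.bound - near,
                         n - n_near + 1)[:-1]
    return np.concatenate([coarse, dense])


def absorption_flux(params: RaceParams, coherence: float,
                    time_grid: np.ndarray | None = None,
                    loser_grid: np.ndarray | None = None,
                    conservation_tol: float = 1e-3) -> AbsorptionSolution:
    """Joint (decision time, loser state) absorption density for both winners.

    The flux across each bound is the normal component of the probability
    current, computed by analytic differentiation of the Gaussian image sum:
    on the bound the density vanishes, so the current reduces to
    ``-(1/2) d(density)/d(winner coordinate)``.

    A warning is issued if absorbed plus surviving mass misses 1 by more than
    ``conservation_tol`` (grids too coarse or too short).
    """
    if time_grid is None:
        time_grid = default_time_grid()
    if loser_grid is None:
        loser_grid = default_loser_grid(params, t_max=float(time_grid[-1]))
    time_grid = np.asarray(time_grid, dtype=float)
    loser_grid = np.asarray(loser_grid, dtype=float)
    if time_grid.ndim != 1 or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if loser_grid.ndim != 1 or np.any(np.diff(loser_grid) <= 0):
        raise ValueError("loser_grid must be strictly increasing")
    if loser_grid[-1] > params.bound + 1e-12:
        raise ValueError("loser_grid must not exceed the bound")

    pts, signs = image_sources(params.corr, params.bound)
    B = params.bound
    tt = time_grid[:, None]
    vv = loser_grid[None, :]
    flux = np.empty((2, len(time_grid), len(loser_grid)))
    for sheet, c in ((0, coherence), (1, -coherence)):
        # winner at x1 = B, loser state v; left-win sheet by mirror symmetry
        dq = _image_gauss_sum(pts, signs, params.corr, B, vv, tt, deriv=0,
                              log_tilt=_girsanov_log(params, c, B, vv, tt))
        flux[sheet] = np.clip(-0.5 * dq, 0.0, None)

    # survival mass at the final time by 2-D quadrature of the image propagator
    t_end = float(time_grid[-1])
    grid1 = np.linspace(loser_grid[0], B, 161)
    X1, X2 = np.meshgrid(grid1, grid1, indexing="ij")
    surv = image_propagator(params, coherence, t_end,
                            np.stack([X1, X2], axis=-1))
    survival_mass = float(np.trapezoid(np.trapezoid(surv, grid1, axis=1), grid1))

    sol = AbsorptionSolution(time_grid, loser_grid, flux, survival_mass,
                             params, coherence)
    defect = sol.conservation_defect()
    if defect > conservation_tol:
        warnings.warn(
            f"absorption grids conserve probability only to {defect:.2e} "
            f"(tolerance {conservation_tol:.0e}); refine the grids",
            RuntimeWarning, stacklevel=2)
    return sol


def minimal_image_count(corr: float, bound: float = 1.0,
                        n_boundary: int = 100, rtol: float = 1e-10,
                        seed: int | None = 0) -> int:
    """Minimal number of image sources whose signed sum vanishes on both bounds.

    Grows the dihedral image expansion term by term (in reflection-depth
    order) and evaluates the partial sums at ``n_boundary`` random points on
    the two absorbing boundaries over a range of times; returns the smallest
    count for which the maximum |density|, relative to the magnitude sum of
    the individual terms, is below ``rtol``.  The count excludes the original
    source (the convention of the reflection literature: 3 images for
    independent accumulators, 5 for corr -0.5, 7 for corr -cos(pi/4)).
    """
    pts, signs = image_sources(corr, bound)
    rng = np.random.default_rng(seed)
    n_half = n_boundary // 2
    ts = rng.uniform(0.05, 2.0, size=n_boundary)
    offs = bound - rng.uniform(0.0, 3.0, size=n_boundary) * np.sqrt(ts)
    x1 = np.where(np.arange(n_boundary) < n_half, bound, offs)
    x2 = np.where(np.arange(n_boundary) < n_half, offs, bound)
    for m in range(1, len(pts) + 1):
        total = _image_gauss_sum(pts[:m], signs[:m], corr, x1, x2, ts)
        scale = sum(abs(_image_gauss_sum(pts[j:j + 1], signs[j:j + 1], corr,
                                         x1, x2, ts)) for j in range(m))
        rel = np.max(np.abs(total) / np.maximum(scale, 1e-300))
        if rel < rtol:
            return m - 1  # exclude the original source from the count
    raise RuntimeError("boundary condition not satisfied by the full expansion")


def single_bound_fpt_density(kappa: float, coherence: float, bound: float,
                             t) -> np.ndarray:
    """First-passage-time density of a single accumulator to one upper bound.

    The two-accumulator machinery reduced to one dimension (the other bound
    pushed to infinity): a two-term image solution for a single absorbing
    bound, differentiated at the bound and tilted by the drift factor.
    Equals the shifted-Wald (inverse Gaussian) density.
    """
    t = np.asarray(t, dtype=float)
    mu = kappa * coherence
    # driftless two-source image solution q(x,t) = phi_t(x) - phi_t(x - 2B);
    # flux = -1/2 exp(mu*B - mu^2 t / 2) dq/dx at x = B
    dq = -(2.0 * bound / t) * np.exp(-0.5 * bound * bound / t) / np.sqrt(2.0 * math.pi * t)
    return -0.5 * np.exp(mu * bound - 0.5 * mu * mu * t) * dq
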