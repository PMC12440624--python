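"""Kinetic models of nanoparticle-cell association.

The homogeneous model describes a well-mixed population of identical cells
taking up particles from the media at rate ``r`` [m s^-1] until a saturating
number of particles per cell ``K`` (the "carrying capacity") is reached.  The
heterogeneous generalisation draws per-cell ``(r_j, K_j)`` from independent
lognormal distributions parameterised by their natural-scale means and
standard deviations, and couples cells only through the shared media
concentration.  Two solution routes are provided: the full coupled system of
``N + 1`` ODEs (slow; used as a verification oracle) and a fast approximation
in which the media concentration is replaced by a mean-field estimate built
from ``M`` homogeneous solutions, after which every cell decouples.

Times are accepted in hours at every public interface and converted to
seconds internally so that ``r`` [m s^-1], ``S`` [m^2] and ``V`` [m^3] are
dimensionally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

HOUR_TO_S = 3600.0

#: relative tolerance on |Vu0 - K| / Vu0 below which the K = Vu0 branch of the
#: analytic solution is used (avoids catastrophic cancellation).
BRANCH_RTOL = 1e-9


@dataclass(frozen=True)
class ExperimentConstants:
    """Fixed parameters of the experimental setup.

    C
        fractional surface coverage of the cells, dimensionless, in (0, 1].
    S
        cell surface area [m^2].
    V
        media volume per cell [m^3].
    u0
        initial particle concentration [particles cell^-1 m^-3].
    """

    C: float
    S: float
    V: float
    u0: float

    def __post_init__(self) -> None:
        for name in ("C", "S", "V", "u0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.C > 1:
            raise ValueError("C is a fractional coverage and must be <= 1")

    @property
    def vu0(self) -> float:
        """Initial number of particles available per cell, V * u0."""
        return self.V * self.u0


@dataclass(frozen=True)
class HyperParams:
    """Natural-scale means and standard deviations of the lognormal trait laws.

    m_r, s_r
        mean and SD of the association rate distribution [m s^-1].
    m_K, s_K
        mean and SD of the carrying-capacity distribution [particles cell^-1].
    """

    m_r: float
    s_r: float
    m_K: float
    s_K: float

    def __post_init__(self) -> None:
        for name in ("m_r", "s_r", "m_K", "s_K"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")

    @classmethod
    def from_theta(cls, theta) -> "HyperParams":
        return cls(*(float(x) for x in theta))

    def theta(self) -> np.ndarray:
        return np.array([self.m_r, self.s_r, self.m_K, self.s_K])


PARAM_NAMES = ("m_r", "s_r", "m_K", "s_K")


@dataclass
class CellTraits:
    """Per-cell association rates and capacities for a simulated population."""

    r: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.r.shape != self.K.shape or self.r.ndim != 1:
            raise ValueError("r and K must be 1-d arrays of equal length")
        if self.r.size == 0 or np.any(self.r <= 0) or np.any(self.K <= 0):
            raise ValueError("all trait values must be strictly positive")

    def __len__(self) -> int:
        return self.r.size


@dataclass
class MediaTrajectory:
    """Mean-field media concentration on a dense time grid.

    ``times`` are in hours; ``cumint`` is the cumulative trapezoid integral of
    ``ubar`` over time *in seconds* [particles cell^-1 m^-3 s].
    """

    times: np.ndarray
    ubar: np.ndarray
    cumint: np.ndarray

    def cumint_at(self, times_h) -> np.ndarray:
        """Linearly interpolate the cumulative integral at requested times."""
        t = np.asarray(times_h, dtype=float)
        if t.size and (t.min() < self.times[0] - 1e-12 or t.max() > self.times[-1] + 1e-12):
            raise ValueError(
                f"requested times [{t.min()}, {t.max()}] h outside the media "
                f"grid [{self.times[0]}, {self.times[-1]}] h"
            )
        return np.interp(t, self.times, self.cumint)


@dataclass
class TrajectorySet:
    """Per-cell particle counts at the measurement times.

    ``P`` has shape (n_cells, n_times).  For solutions of the full coupled
    system, ``u`` carries the media concentration at the same times.
    """

    times: np.ndarray
    P: np.ndarray
    u: np.ndarray | None = None


def lognormal_natural_params(m: float, s: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with mean ``m`` and SD ``s``.

    mu = ln(m^2 / sqrt(m^2 + s^2)),  sigma = sqrt(ln(1 + s^2/m^2)).
    """
    m = float(m)
    s = float(s)
    if not (m > 0 and s > 0):
        raise ValueError("m and s must be strictly positive")
    sigma2 = np.log1p((s / m) ** 2)
    return np.log(m) - 0.5 * sigma2, float(np.sqrt(sigma2))


def sample_cell_traits(hyper: HyperParams, n: int, rng: np.random.Generator) -> CellTraits:
    """Draw ``n`` independent (r_j, K_j) pairs; r and K are uncorrelated."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu_r, sg_r = lognormal_natural_params(hyper.m_r, hyper.s_r)
    mu_k, sg_k = lognormal_natural_params(hyper.m_K, hyper.s_K)
    return CellTraits(rng.lognormal(mu_r, sg_r, n), rng.lognormal(mu_k, sg_k, n))


def homogeneous_solution(t, r, K, consts: ExperimentConstants):
    """Analytic particles-per-cell P(t) for a homogeneous population.

    Broadcasts over ``t`` [h], ``r`` [m s^-1] and ``K`` [particles cell^-1].
    The saturating solution has the two fixed points P = K and P = Vu0; when
    |Vu0 - K| is within ``BRANCH_RTOL`` relative tolerance the degenerate
    K = Vu0 branch is evaluated instead.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if np.any(r < 0):
        raise ValueError("r must be nonnegative")
    if np.any(K <= 0):
        raise ValueError("K must be strictly positive")

    C, S, V, u0 = consts.C, consts.S, consts.V, consts.u0
    vu0 = consts.vu0
    ts = t * HOUR_TO_S
    t, r, K, ts = np.broadcast_arrays(t, r, K, ts)

    near = np.abs(vu0 - K) <= BRANCH_RTOL * vu0
    rcs = r * C * S
    # degenerate K = Vu0 branch
    P_eq = rcs * K * u0 * ts / (K + rcs * u0 * ts)

    # generic branch, written so the exponential argument is always <= 0
    Ksafe = np.where(near, 0.5 * vu0, K)  # dummy, masked out below
    x = rcs * (vu0 - Ksafe) * ts / (Ksafe * V)
    e = np.exp(-np.abs(x))
    with np.errstate(invalid="ignore", divide="ignore"):
        P_pos = vu0 * Ksafe * (1.0 - e) / (vu0 - Ksafe * e)     # x >= 0 (K < Vu0)
        P_neg = vu0 * Ksafe * (e - 1.0) / (vu0 * e - Ksafe)     # x < 0  (K > Vu0)
    P = np.where(near, P_eq, np.where(x >= 0, P_pos, P_neg))
    return P if P.ndim else float(P)


def media_concentration_approx(
    times,
    hyper: HyperParams,
    consts: ExperimentConstants,
    m_eval: int = 100,
    rng: np.random.Generator | None = None,
    grid_points: int = 1001,
) -> MediaTrajectory:
    """Mean-field media concentration ubar(t) = u0 - mean_M[P_hom(t)] / V.

    ``ubar`` is the mean over ``m_eval`` analytic homogeneous solutions at
    independent trait draws, evaluated on a uniform grid of ``grid_points``
    over [0, max(times)]; its cumulative integral (trapezoid rule, over time
    in seconds) is what the decoupled per-cell solution consumes.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if m_eval < 1:
        raise ValueError("m_eval must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    t_max = float(times.max())
    grid = np.linspace(0.0, t_max if t_max > 0 else 1.0, grid_points)
    traits = sample_cell_traits(hyper, m_eval, rng)
    P = homogeneous_solution(grid[None, :], traits.r[:, None], traits.K[:, None], consts)
    ubar = consts.u0 - P.mean(axis=0) / consts.V
    cumint = cumulative_trapezoid(ubar, grid * HOUR_TO_S, initial=0.0)
    return MediaTrajectory(grid, ubar, cumint)


def heterogeneous_solution_approx(
    times,
    traits: CellTraits,
    media: MediaTrajectory,
    consts: ExperimentConstants,
) -> TrajectorySet:
    """Decoupled per-cell trajectories P_j(t) = K_j (1 - exp(-CS r_j I(t)/K_j)).

    ``I(t)`` is the cumulative integral of the mean-field media concentration,
    interpolated at the requested times.  Cost is linear in
    ``len(traits) * len(times)``.
    """
    times = np.asarray(times, dtype=float)
    I = media.cumint_at(times)
    expo = (consts.C * consts.S) * np.outer(traits.r / traits.K, I)
    P = traits.K[:, None] * (-np.expm1(-expo))
    return TrajectorySet(times, P)


def heterogeneous_solution_full(
    times,
    traits: CellTraits,
    consts: ExperimentConstants,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TrajectorySet:
    """Numerically integrate the full coupled system of N + 1 ODEs.

    dP_j/dt = C S r_j (1 - P_j/K_j) u(t),
    du/dt   = -(C S / (N V)) sum_j r_j (1 - P_j/K_j) u(t),

    with P_j(0) = 0 and u(0) = u0.  Cells compete for particles through the
    shared media; the total particle count N V u(t) + sum_j P_j(t) is
    conserved.  Intended as a verification oracle at modest N.
    """
    times = np.asarray(times, dtype=float)
    n = len(traits)
    C, S, V, u0 = consts.C, consts.S, consts.V, consts.u0
    r, K = traits.r, traits.K
    cs = C * S

    # media state is scaled by u0 so all state variables are O(1..K)
    def rhs(t, y):
        P = y[:n]
        w = y[n]
        avail = 1.0 - P / K
        dP = cs * r * avail * (u0 * w)
        dw = -(cs / (n * V)) * np.dot(r, avail) * w
        return np.concatenate([dP, [dw]])

    y0 = np.zeros(n + 1)
    y0[n] = 1.0
    t_end = float(times.max()) * HOUR_TO_S
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-9)),
        y0,
        t_eval=times * HOUR_TO_S,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message} (n={n}, t_end={t_end} s)")
    return TrajectorySet(times, sol.y[:n, :], u=u0 * sol.y[n, :])
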