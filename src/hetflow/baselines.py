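"""Point-estimate comparator methods based on median fluorescence transforms.

Two earlier-generation analyses are reproduced for comparison with the
distribution-level ABC approach: (i) collapse each time point to a single
particles-per-cell point estimate via the median transform and fit the
homogeneous model by least squares, and (ii) transform every individual cell
fluorescence value to a per-cell particle estimate.  The per-cell transform
can produce non-physical negative values; these are never dropped, and the
fraction of negative values is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .flow import ControlData, TimeCourseDataset
from .model import ExperimentConstants, homogeneous_solution


@dataclass
class PointObservation:
    """One particles-per-cell point estimate per time, with Po(0) = 0."""

    times: np.ndarray
    Po: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Po = np.asarray(self.Po, dtype=float)
        if self.times.shape != self.Po.shape:
            raise ValueError("times and Po must have equal length")
        if self.times[0] != 0.0 or self.Po[0] != 0.0:
            raise ValueError("observation must start at (t, Po) = (0, 0)")


@dataclass
class PerCellObservation:
    """Per-cell particle estimates per time; negatives preserved and counted."""

    times: np.ndarray
    values: dict
    fraction_negative: dict


@dataclass
class LeastSquaresFit:
    r: float
    K: float
    sse: float


def median_transform(exp: TimeCourseDataset, controls: ControlData) -> PointObservation:
    """Po(ti) = (median(Dexp(ti)) - median(Dcells)) / median(Dparticles)."""
    med_cells = float(np.median(controls.cells))
    med_particles = float(np.median(controls.particles))
    if med_particles == 0:
        raise ValueError("median particle fluorescence is zero; transform undefined")
    times = [0.0]
    po = [0.0]
    for t in exp.times:
        times.append(t)
        po.append((float(np.median(exp.samples[t])) - med_cells) / med_particles)
    return PointObservation(np.array(times), np.array(po))


def per_cell_transform(exp: TimeCourseDataset, controls: ControlData) -> PerCellObservation:
    """Per-cell particle estimates (d - median(Dcells)) / median(Dparticles)."""
    med_cells = float(np.median(controls.cells))
    med_particles = float(np.median(controls.particles))
    if med_particles == 0:
        raise ValueError("median particle fluorescence is zero; transform undefined")
    values = {}
    frac_neg = {}
    for t in exp.times:
        v = (exp.samples[t] - med_cells) / med_particles
        values[t] = v
        frac_neg[t] = float(np.mean(v < 0))
    return PerCellObservation(np.asarray(exp.times, dtype=float), values, frac_neg)


def least_squares_fit(
    obs: PointObservation,
    consts: ExperimentConstants,
    r_bounds: tuple = (1e-9, 1e-4),
    K_bounds: tuple = (0.5, 1000.0),
    n_starts_r: int = 5,
    n_starts_K: int = 4,
) -> LeastSquaresFit:
    """Fit the homogeneous model to point estimates by unweighted least squares.

    The sum of squares sum_i (Po(ti) - P_hom(ti; r, K))^2 (t = 0 included) is
    minimised over (log r, log K) with L-BFGS-B from a deterministic grid of
    log-spaced multistarts, because r varies over orders of magnitude across
    particle-cell pairs.  Only the point estimate and achieved SSE are
    returned; no Gaussian error model is implied.
    """
    if obs.times.size < 3:
        raise ValueError("need at least 3 time points to fit (r, K)")
    t = obs.times
    y = obs.Po

    def sse(z):
        pred = homogeneous_solution(t, np.exp(z[0]), np.exp(z[1]), consts)
        return float(np.sum((y - pred) ** 2))

    bounds = [tuple(np.log(r_bounds)), tuple(np.log(K_bounds))]
    starts_r = np.linspace(*bounds[0], n_starts_r)
    starts_K = np.linspace(*bounds[1], n_starts_K)
    best = None
    for zr in starts_r:
        for zk in starts_K:
            res = minimize(sse, x0=[zr, zk], method="L-BFGS-B", bounds=bounds)
            if res.success and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        raise RuntimeError(
            f"least-squares fit failed to converge from any of "
            f"{n_starts_r * n_starts_K} starts over bounds r={r_bounds}, K={K_bounds}"
        )
    return LeastSquaresFit(float(np.exp(best.x[0])), float(np.exp(best.x[1])), float(best.fun))
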