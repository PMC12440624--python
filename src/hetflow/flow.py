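"""Generative model of flow-cytometry fluorescence measurements.

A measured cell's total fluorescence is the sum of one autofluorescence draw
from the cell-only control distribution and the fluorescence of its
associated particles, each drawn from the particle-only control distribution.
A non-integer particle count P contributes floor(P) full particle draws plus
one further draw scaled by the fractional part.  Controls are resampled with
replacement, independently across cells, particles and time points: the data
are snapshots, so no cell keeps its autofluorescence draw across times, while
the underlying trajectory identity P_j(t) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ExperimentConstants,
    HyperParams,
    TrajectorySet,
    heterogeneous_solution_approx,
    media_concentration_approx,
    sample_cell_traits,
)

# cap on the per-chunk particle-draw buffer used by the vectorised noise core
_CHUNK_DRAWS = 1 << 23


@dataclass
class ControlData:
    """Empirical control distributions: cell-only and particle-only samples.

    ``cells`` plays the role of the autofluorescence (t = 0) distribution and
    ``particles`` the single-particle fluorescence distribution, both in
    calibrated arbitrary units.  Readers accept any finite reals (calibrated
    experimental data can contain small negative values); the fixture
    generator only emits positive values.
    """

    cells: np.ndarray
    particles: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float).ravel()
        self.particles = np.asarray(self.particles, dtype=float).ravel()
        if self.cells.size == 0 or self.particles.size == 0:
            raise ValueError("control samples must be nonempty")
        if not (np.isfinite(self.cells).all() and np.isfinite(self.particles).all()):
            raise ValueError("control samples must be finite")


@dataclass
class TimeCourseDataset:
    """Per-cell fluorescence samples keyed by measurement time [h]."""

    samples: dict

    def __post_init__(self) -> None:
        items = sorted(self.samples.items())
        if not items:
            raise ValueError("time course must contain at least one time point")
        if any(t <= 0 for t, _ in items):
            raise ValueError("time labels must be strictly positive (t=0 is the cell-only control)")
        self.samples = {float(t): np.asarray(v, dtype=float).ravel() for t, v in items}

    @property
    def times(self) -> tuple:
        return tuple(self.samples.keys())

    def n_per_time(self) -> dict:
        return {t: v.size for t, v in self.samples.items()}


@dataclass
class ControlFixtureSpec:
    """Synthetic control fixture: right-skewed (lognormal) control samples.

    Defaults emulate the published sample sizes (11 605 cell-only and 500 000
    particle-only events) with a single-particle median far below the spread
    of the autofluorescence distribution, so single-particle resolution is
    ambiguous and inference must work at the distribution level.
    """

    cells_n: int = 11_605
    particles_n: int = 500_000
    cells_meanlog: float = float(np.log(200.0))
    cells_sdlog: float = 0.55
    particles_meanlog: float = float(np.log(20.0))
    particles_sdlog: float = 0.7

    def __post_init__(self) -> None:
        if self.cells_n < 1 or self.particles_n < 1:
            raise ValueError("control sample sizes must be >= 1")
        if self.cells_sdlog < 0 or self.particles_sdlog < 0:
            raise ValueError("log-scale SDs must be nonnegative")


def generate_control_fixtures(spec: ControlFixtureSpec, rng: np.random.Generator) -> ControlData:
    """Draw positive, right-skewed control samples per the fixture spec."""
    cells = rng.lognormal(spec.cells_meanlog, spec.cells_sdlog, spec.cells_n)
    particles = rng.lognormal(spec.particles_meanlog, spec.particles_sdlog, spec.particles_n)
    return ControlData(cells, particles)


def median_fluorescence_point(p: float, controls: ControlData) -> float:
    """Deterministic median-summary signal: median(cells) + p * median(particles)."""
    if p < 0:
        raise ValueError("particle count must be nonnegative")
    return float(np.median(controls.cells) + p * np.median(controls.particles))


def _particle_fluorescence(P, particles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Total particle fluorescence for each entry of P (vectorised, chunked).

    Each cell receives floor(P) independent draws plus a fresh draw scaled by
    the fractional part of P.  Cells are processed in chunks so the draw
    buffer stays bounded even for large particle counts.
    """
    P = np.asarray(P, dtype=float).ravel()
    if np.any(P < 0):
        raise ValueError("particle counts must be nonnegative")
    npart = particles.size
    n_int = np.floor(P).astype(np.int64)
    frac = P - n_int
    out = frac * particles[rng.integers(0, npart, P.size)]
    start = 0
    counts_cum = np.concatenate([[0], np.cumsum(n_int)])
    while start < P.size:
        # widest slice whose total draw count fits the buffer (>= one cell)
        stop = int(np.searchsorted(counts_cum, counts_cum[start] + _CHUNK_DRAWS, side="right")) - 1
        stop = max(stop, start + 1)
        total = int(counts_cum[stop] - counts_cum[start])
        if total:
            draws = particles[rng.integers(0, npart, total)]
            cs = np.concatenate([[0.0], np.cumsum(draws)])
            ends = counts_cum[start + 1 : stop + 1] - counts_cum[start]
            begins = counts_cum[start:stop] - counts_cum[start]
            out[start:stop] += cs[ends] - cs[begins]
        start = stop
    return out


def simulate_fluorescence_point(p: float, controls: ControlData, rng: np.random.Generator) -> float:
    """One synthetic fluorescence value for a cell carrying ``p`` particles."""
    if p < 0:
        raise ValueError("particle count must be nonnegative")
    auto = controls.cells[rng.integers(0, controls.cells.size)]
    return float(auto + _particle_fluorescence([p], controls.particles, rng)[0])


def apply_noise(P_column, controls: ControlData, rng: np.random.Generator) -> np.ndarray:
    """Autofluorescence plus particle fluorescence for a vector of counts."""
    P_column = np.asarray(P_column, dtype=float).ravel()
    auto = controls.cells[rng.integers(0, controls.cells.size, P_column.size)]
    return auto + _particle_fluorescence(P_column, controls.particles, rng)


def noisy_dataset_from_trajectories(
    traj: TrajectorySet, controls: ControlData, rng: np.random.Generator
) -> TimeCourseDataset:
    """Apply the measurement model to an existing set of trajectories."""
    samples = {}
    for i, t in enumerate(traj.times):
        samples[float(t)] = apply_noise(traj.P[:, i], controls, rng)
    return TimeCourseDataset(samples)


def simulate_dataset(
    hyper: HyperParams,
    consts: ExperimentConstants,
    times,
    controls: ControlData,
    n_cells: int = 20_000,
    rng: np.random.Generator | None = None,
    m_eval: int = 100,
    grid_points: int = 1001,
) -> TimeCourseDataset:
    """End-to-end synthetic flow-cytometry time course.

    Samples ``n_cells`` trait pairs, builds the mean-field media trajectory,
    evaluates the decoupled per-cell solution at the requested times, and
    applies the control-resampling measurement model per (cell, time).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    traits = sample_cell_traits(hyper, n_cells, rng)
    media = media_concentration_approx(times, hyper, consts, m_eval, rng, grid_points)
    traj = heterogeneous_solution_approx(times, traits, media, consts)
    return noisy_dataset_from_trajectories(traj, controls, rng)


def _keyed_rng(root_seed: int, index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), int(index), int(tag)]))


def _time_tag(t: float) -> int:
    return 2 + int(round(float(t) * 1_000_000))


def simulate_dataset_keyed(
    hyper: HyperParams,
    consts: ExperimentConstants,
    times,
    controls: ControlData,
    n_cells: int,
    root_seed: int,
    index: int,
    t_max: float | None = None,
    m_eval: int = 100,
    grid_points: int = 1001,
) -> TimeCourseDataset:
    """Simulate with noise streams keyed on (root seed, index, time value).

    Trait and media draws are keyed on (root seed, index) alone and the media
    grid always spans [0, t_max], so simulating a subset of time points yields
    values bit-identical to slicing a simulation over the full grid.  This is
    what lets a pre-simulated reference table be subset per design instead of
    re-simulated.
    """
    times = np.asarray(times, dtype=float)
    if t_max is None:
        t_max = float(times.max())
    traits = sample_cell_traits(hyper, n_cells, _keyed_rng(root_seed, index, 0))
    media = media_concentration_approx(
        [t_max], hyper, consts, m_eval, _keyed_rng(root_seed, index, 1), grid_points
    )
    traj = heterogeneous_solution_approx(times, traits, media, consts)
    samples = {}
    for i, t in enumerate(times):
        samples[float(t)] = apply_noise(
            traj.P[:, i], controls, _keyed_rng(root_seed, index, _time_tag(t))
        )
    return TimeCourseDataset(samples)
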