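"""ABC distance functions between simulated and observed time courses.

Each dataset-level distance is the sum over matched time points of a
two-sample statistic.  The workhorse is the non-standardized two-sample
Anderson-Darling statistic (the k = 2 member of the k-sample family), which
weights tail discrepancies more heavily than Cramer-von Mises or
Kolmogorov-Smirnov; all three are rank-based and therefore invariant under
common strictly increasing transforms of the data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .flow import TimeCourseDataset


def ad_2samp(x, y) -> float:
    """Non-standardized two-sample Anderson-Darling statistic A^2.

    A^2 = (1/N) sum_i (1/n_i) sum_{j=1}^{N-1} (N M_ij - j n_i)^2 / (j (N-j)),

    where M_ij counts observations of sample i that are <= the j-th pooled
    order statistic (value-based, so tied values are handled
    deterministically).  Identical samples give the statistic's self-value,
    not zero.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("samples must be nonempty")
    N = n + m
    z = np.concatenate([x, y])
    z.sort(kind="mergesort")
    zs = z[:-1]
    Mx = np.searchsorted(x, zs, side="right").astype(float)
    My = np.searchsorted(y, zs, side="right").astype(float)
    j = np.arange(1, N, dtype=float)
    denom = j * (N - j)
    a = np.sum((N * Mx - j * n) ** 2 / denom) / n
    b = np.sum((N * My - j * m) ** 2 / denom) / m
    return float((a + b) / N)


def cvm_2samp(x, y) -> float:
    """Two-sample Cramer-von Mises statistic T."""
    return float(stats.cramervonmises_2samp(x, y, method="asymptotic").statistic)


def ks_2samp(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup of the ECDF gap)."""
    return float(stats.ks_2samp(x, y).statistic)


def _sum_over_times(stat, sim: TimeCourseDataset, obs: TimeCourseDataset) -> float:
    if set(sim.times) != set(obs.times):
        raise ValueError(
            f"time labels differ: simulated {sorted(sim.times)} vs observed {sorted(obs.times)}"
        )
    return float(sum(stat(sim.samples[t], obs.samples[t]) for t in obs.times))


def distance_anderson_darling(sim: TimeCourseDataset, obs: TimeCourseDataset) -> float:
    """Summed per-time-point two-sample Anderson-Darling distance."""
    return _sum_over_times(ad_2samp, sim, obs)


def distance_cvm(sim: TimeCourseDataset, obs: TimeCourseDataset) -> float:
    """Summed per-time-point two-sample Cramer-von Mises distance."""
    return _sum_over_times(cvm_2samp, sim, obs)


def distance_ks(sim: TimeCourseDataset, obs: TimeCourseDataset) -> float:
    """Summed per-time-point two-sample Kolmogorov-Smirnov distance."""
    return _sum_over_times(ks_2samp, sim, obs)


#: registry of named dataset-level distances (swap point for alternative
#: definitions of the statistics)
DISTANCES = {
    "ad": distance_anderson_darling,
    "cvm": distance_cvm,
    "ks": distance_ks,
}

#: registry of the underlying two-sample statistics
TWO_SAMPLE_STATS = {"ad": ad_2samp, "cvm": cvm_2samp, "ks": ks_2samp}


def get_distance(name: str):
    try:
        return DISTANCES[name]
    except KeyError:
        raise KeyError(f"unknown distance {name!r}; choose from {sorted(DISTANCES)}") from None
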