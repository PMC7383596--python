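"""Circular-statistics primitives shared by the phase-coding analyses.

Includes the resultant vector length, the circular-linear correlation with
a slope fitted by maximizing the resultant (the standard estimator for
phase-precession analyses), a generic circular time-shift shuffle test, and
the V test for a hypothesized mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CircLinResult",
    "resultant",
    "angular_deviation",
    "circ_linear_corr",
    "time_shift_shuffle",
    "v_test",
    "dispersion_permutation_test",
]


@dataclass
class CircLinResult:
    """Circular-linear correlation with shuffle significance.

    ``rho`` carries the sign of the fitted slope, so phase precession
    (phase decreasing with distance) yields a negative coefficient.
    """

    rho: float
    slope: float  # rad per unit of the linear variable
    p: float
    n_shuffles: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def resultant(phases: np.ndarray) -> tuple[float, float]:
    """Resultant vector length R in [0, 1] and circular mean phase."""
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("resultant requires at least one phase")
    z = np.mean(np.exp(1j * phases))
    return float(np.abs(z)), float(np.angle(z))


def angular_deviation(r: float) -> float:
    """Circular standard deviation sqrt(2 (1 - R)) of a resultant length."""
    return float(np.sqrt(2.0 * (1.0 - r)))


def _refine_slope(phases, x, a, span):
    def neg_r(s):
        return -np.abs(np.mean(np.exp(1j * (phases - s * x))))

    res = optimize.minimize_scalar(neg_r, bounds=(a - span, a + span), method="bounded")
    return float(res.x)


def _circ_circ_corr(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Circular-circular correlation coefficient (Fisher-Lee form)."""
    _, ma = resultant(alpha)
    _, mb = resultant(beta)
    sa = np.sin(alpha - ma)
    sb = np.sin(beta - mb)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def _corr_at_slope(phases, x, slope):
    rho = _circ_circ_corr(phases, np.mod(slope * x, 2 * np.pi))
    signed = np.sign(slope) * abs(rho) if slope != 0 else rho
    return signed


def circ_linear_corr(
    phases: np.ndarray,
    positions: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | None = None,
    slope_bounds: tuple[float, float] | None = None,
    n_grid: int = 2001,
    refine: bool = True,
) -> CircLinResult:
    """Circular-linear correlation between firing phase and position.

    The slope (rad per unit position) is found by maximizing the resultant
    length of the phase residuals over a dense slope grid (default +/- 2
    cycles per position range) with local refinement; the correlation is
    the circular-circular coefficient between the phases and the fitted
    linear phase, signed by the slope.  Significance comes from shuffling
    the pairing of phases and positions and re-fitting each time:
    p = (1 + #{|rho_shuf| >= |rho|}) / (1 + n_shuffles).
    """
    phases = np.asarray(phases, float)
    x = np.asarray(positions, float)
    if len(phases) != len(x) or len(x) < 5:
        raise ValueError("need equal-length inputs with at least 5 samples")
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("positions are constant: slope undefined")
    if slope_bounds is None:
        lim = 2 * 2 * np.pi / span  # +/- 2 cycles across the range
        slope_bounds = (-lim, lim)
    slopes = np.linspace(slope_bounds[0], slope_bounds[1], n_grid)
    # slope-grid phasor matrix: depends only on positions, shared by shuffles
    mat = np.exp(-1j * np.outer(slopes, x))
    phasors = np.exp(1j * phases)
    grid_slope = float(slopes[np.argmax(np.abs(mat @ phasors))])
    rho_cmp = _corr_at_slope(phases, x, grid_slope)
    slope = grid_slope
    if refine and n_grid > 1:
        slope = _refine_slope(phases, x, grid_slope, float(slopes[1] - slopes[0]))
    rho = _corr_at_slope(phases, x, slope)
    rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = max(1, int(2e7 / max(n_grid, 1)))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        perms = np.argsort(rng.random((m, len(phases))), axis=1)
        shuffled = phases[perms]  # (m, n)
        r_grid = np.abs(mat @ np.exp(1j * shuffled.T))  # (n_grid, m)
        best = np.argmax(r_grid, axis=0)
        for j in range(m):
            r_s = _corr_at_slope(shuffled[j], x, float(slopes[best[j]]))
            if abs(r_s) >= abs(rho_cmp):
                n_ge += 1
        done += m
    p = (1 + n_ge) / (1 + n_shuffles)
    return CircLinResult(rho=float(rho), slope=float(slope), p=float(p), n_shuffles=n_shuffles)


def time_shift_shuffle(
    statistic,
    spike_times: np.ndarray,
    duration: float,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    seed: int | None = None,
) -> tuple[float, float, bool]:
    """Generic circular time-shift shuffle test.

    ``statistic`` is a pure function of a spike-time array.  Each shuffle
    circularly rotates the spike train by a shift drawn uniformly from
    [1, duration - 1] s; the true value is significant iff it exceeds the
    stated percentile of the shuffle distribution.
    """
    import warnings

    if duration <= 2.0:
        raise ValueError("session must be longer than 2 s for time-shift shuffling")
    if n_shuffles < 20:
        warnings.warn("fewer than 20 shuffles: percentile threshold unreliable")
    spike_times = np.asarray(spike_times, float)
    true_val = float(statistic(spike_times))
    rng = np.random.default_rng(seed)
    shuf_vals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shift = rng.uniform(1.0, duration - 1.0)
        shifted = np.sort(np.mod(spike_times + shift, duration))
        shuf_vals[i] = statistic(shifted)
    threshold = float(np.percentile(shuf_vals, percentile))
    return true_val, threshold, true_val > threshold


def v_test(phases: np.ndarray, mean_dir: float) -> tuple[float, float]:
    """V test for circular non-uniformity with a hypothesized mean direction.

    V = n * R * cos(mean - hypothesized); the p-value uses the large-n
    normal approximation of u = V * sqrt(2 / n).
    """
    phases = np.asarray(phases, float)
    n = len(phases)
    if n < 2:
        raise ValueError("v_test requires at least 2 phases")
    r, mu = resultant(phases)
    v = n * r * np.cos(mu - mean_dir)
    u = v * np.sqrt(2.0 / n)
    p = 1.0 - stats.norm.cdf(u)
    return float(v), float(p)


def dispersion_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for a difference in circular dispersion.

    The statistic is the difference in circular variance (1 - R) between
    the two samples; group labels are permuted.  This is a two-sample
    spread comparison for circular data and is not tied to any particular
    named test statistic.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    stat = (1 - resultant(a)[0]) - (1 - resultant(b)[0])
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        pa = pooled[perm[: len(a)]]
        pb = pooled[perm[len(a) :]]
        s = (1 - resultant(pa)[0]) - (1 - resultant(pb)[0])
        if abs(s) >= abs(stat):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return float(stat), float(p)
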