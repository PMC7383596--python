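"""Temporal analyses of simulated spike trains.

Phase locking (resultant length with a time-shift shuffle), spike-train
autocorrelograms with a parametric decaying-cosine fit yielding an
oscillation index, the intrinsic-versus-baseline frequency difference, and
phase-precession quantification (circular-linear correlation of firing
phase with distance travelled through the firing field).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps, stats

from . import circstats
from .signals import MOVEMENT_SPEED_CM_S, PhaseSeries, Trajectory
from .spatial import FieldSet

__all__ = [
    "Autocorrelogram",
    "ACFitResult",
    "PhaseLockingResult",
    "PrecessionResult",
    "IntrinsicFrequencyResult",
    "phase_locking",
    "autocorrelogram",
    "oscillation_index",
    "intrinsic_frequency_difference",
    "field_traversal_distances",
    "precession",
]


@dataclass
class Autocorrelogram:
    lags: np.ndarray  # bin centres, s (symmetric around 0)
    counts: np.ndarray  # raw coincidence counts

    def corrected(self) -> np.ndarray:
        """Counts with the zero-lag bin replaced by the maximum count."""
        out = self.counts.astype(float).copy()
        zero = np.argmin(np.abs(self.lags))
        out[zero] = out.max()
        return out


@dataclass
class ACFitResult:
    """Parameters of the decaying-cosine autocorrelogram fit.

    A(t) = a exp(-|t|/tau1) (cos(2 pi F t) + 1) + b exp(-|t|/tau2)
         + c exp(-t^2/tau3^2) + d

    The oscillation index a / max(A) measures how much of the
    autocorrelogram's amplitude is carried by the oscillatory component.
    """

    a: float
    b: float
    c: float
    d: float
    frequency: float  # F, Hz
    tau1: float
    tau2: float
    tau3: float
    r_squared: float
    m_ac: float  # maximal autocorrelation value (parameter bound)
    lags: np.ndarray = field(repr=False, default=None)

    def curve(self, t: np.ndarray | None = None) -> np.ndarray:
        if t is None:
            t = self.lags
        return _ac_model(
            t, self.a, self.tau1, self.frequency, self.b, self.tau2, self.c, self.tau3, self.d
        )

    @property
    def oscillation_index(self) -> float:
        return float(self.a / np.max(self.curve()))


@dataclass
class PhaseLockingResult:
    r: float
    mean_phase: float
    threshold: float | None = None
    significant: bool | None = None
    n_spikes: int = 0
    low_confidence: bool = False


@dataclass
class PrecessionResult:
    rho: float
    slope: float  # rad per normalized field distance
    p: float
    distances: np.ndarray = field(repr=False, default=None)
    phases: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class IntrinsicFrequencyResult:
    delta_f: np.ndarray  # Hz, per sample (NaN outside traversals)
    mean_delta_f: float  # Hz
    speed_slope: float  # Hz per cm/s


def _movement_spike_mask(spike_times, trajectory: Trajectory, threshold):
    idx = np.clip(np.round(np.asarray(spike_times) / trajectory.dt).astype(int), 0, trajectory.n - 1)
    return trajectory.movement_mask(threshold)[idx]


def phase_locking(
    spike_times: np.ndarray,
    phase_series: PhaseSeries,
    trajectory: Trajectory | None = None,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    seed: int | None = None,
    speed_threshold: float = MOVEMENT_SPEED_CM_S,
) -> PhaseLockingResult:
    """Phase modulation of a spike train by the LFP.

    The statistic is the resultant vector length of the spike phases
    (movement periods only); significance compares it against the stated
    percentile of a circular time-shift shuffle of the spike train
    relative to the LFP.
    """
    spike_times = np.asarray(spike_times, float)
    # rotation modulus = session duration, so that every shift wraps some
    # spikes (the spike train spans the session, the LFP may run longer)
    duration = trajectory.duration if trajectory is not None else phase_series.n * phase_series.dt
    # movement filtering is a spike-vs-tracking property: select once, then
    # rotate only the spike-vs-LFP pairing in the shuffle
    move_times = spike_times
    if trajectory is not None:
        move_times = spike_times[_movement_spike_mask(spike_times, trajectory, speed_threshold)]
    low_conf = len(move_times) < 10
    if len(move_times) == 0:
        return PhaseLockingResult(0.0, np.nan, None, False, 0, True)
    r, mean_phase = circstats.resultant(phase_series.phase_at(move_times))

    def stat(times):
        return circstats.resultant(phase_series.phase_at(times))[0]

    _, threshold, significant = circstats.time_shift_shuffle(
        stat, move_times, duration, n_shuffles=n_shuffles, percentile=percentile, seed=seed
    )
    return PhaseLockingResult(
        r=r,
        mean_phase=mean_phase,
        threshold=threshold,
        significant=significant,
        n_spikes=len(move_times),
        low_confidence=low_conf,
    )


def autocorrelogram(
    spike_times: np.ndarray, window_s: float = 2.0, bin_s: float = 0.01
) -> Autocorrelogram:
    """Spike-train temporal autocorrelogram (raw coincidence counts).

    Counts ordered pairs of distinct spikes with lags in [-window, window]
    at ``bin_s`` resolution.
    """
    t = np.sort(np.asarray(spike_times, float))
    n_half = int(round(window_s / bin_s))
    edges = (np.arange(2 * n_half + 1) - n_half) * bin_s - bin_s / 2
    edges = np.append(edges, edges[-1] + bin_s)
    counts = np.zeros(2 * n_half + 1)
    lo = np.searchsorted(t, t - window_s - bin_s)
    hi = np.searchsorted(t, t + window_s + bin_s)
    for i, ti in enumerate(t):
        diffs = t[lo[i] : hi[i]] - ti
        diffs = diffs[diffs != 0.0]
        c, _ = np.histogram(diffs, bins=edges)
        counts += c
    lags = (np.arange(2 * n_half + 1) - n_half) * bin_s
    return Autocorrelogram(lags=lags, counts=counts)


def _ac_model(t, a, tau1, f, b, tau2, c, tau3, d):
    at = np.abs(t)
    osc = a * np.exp(-at / tau1) * (np.cos(2 * np.pi * f * t) + 1.0)
    slow = b * np.exp(-at / tau2)
    burst = c * np.exp(-(t**2) / max(tau3, 1e-6) ** 2)
    return osc + slow + burst + d


def oscillation_index(
    spike_times: np.ndarray,
    n_restarts: int = 100,
    seed: int | None = None,
    window_s: float = 2.0,
    bin_s: float = 0.01,
    f_bounds: tuple = (2.0, 20.0),
) -> ACFitResult:
    """Fit the decaying-cosine model to the autocorrelogram.

    The zero-lag bin is first replaced by the maximum across lags.  Bounded
    nonlinear least squares is run from ``n_restarts`` random
    initializations drawn uniformly within the parameter bounds, keeping
    the fit with the greatest R^2.
    """
    spike_times = np.asarray(spike_times, float)
    if len(spike_times) < 100:
        raise ValueError("need at least 100 spikes for a stable autocorrelogram fit")
    acg = autocorrelogram(spike_times, window_s=window_s, bin_s=bin_s)
    y = acg.corrected()
    t = acg.lags
    m = float(y.max())
    if m <= 0:
        raise ValueError("empty autocorrelogram")
    lower = [0.0, 0.1, f_bounds[0], 0.0, 0.1, -m, 1e-3, 0.0]
    upper = [m, 100.0, f_bounds[1], m, 100.0, m, 0.05, m]
    rng = np.random.default_rng(seed)
    best = None
    sst = float(np.sum((y - y.mean()) ** 2))
    for _ in range(n_restarts):
        p0 = rng.uniform(lower, upper)
        try:
            res = optimize.least_squares(
                lambda p: _ac_model(t, *p) - y,
                p0,
                bounds=(lower, upper),
                method="trf",
                max_nfev=200,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise RuntimeError("all autocorrelogram fits failed")
    sse, p = best
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return ACFitResult(
        a=float(p[0]),
        tau1=float(p[1]),
        frequency=float(p[2]),
        b=float(p[3]),
        tau2=float(p[4]),
        c=float(p[5]),
        tau3=float(p[6]),
        d=float(p[7]),
        r_squared=float(r2),
        m_ac=m,
        lags=t,
    )


def intrinsic_frequency_difference(
    r_phi: np.ndarray,
    phase_series: PhaseSeries,
    speeds: np.ndarray | None = None,
    in_field: np.ndarray | None = None,
    boxcar_s: float = 0.05,
    speed_bins: np.ndarray | None = None,
) -> IntrinsicFrequencyResult:
    """Difference between a cell's intrinsic burst frequency and the LFP.

    The oscillatory phase of the (mean-normalized) phase-code factor
    r_phi(t) is estimated with the Hilbert transform; its instantaneous
    frequency (clamped at zero, boxcar-smoothed) is compared with the LFP
    frequency at each time step.  The mean difference is taken over
    within-field samples (optionally movement-filtered), and the slope of
    intrinsic frequency versus running speed is estimated by linear
    regression on speed-binned means.
    """
    r_phi = np.asarray(r_phi, float)
    dt = phase_series.dt
    x = r_phi - r_phi.mean()
    analytic = sps.hilbert(x)
    ph = np.unwrap(np.angle(analytic))
    dph = np.diff(ph)
    f_int = np.maximum(dph, 0.0) / (2 * np.pi * dt)
    f_int = np.concatenate([f_int[:1], f_int])
    width = max(1, int(round(boxcar_s / dt)))
    kernel = np.ones(width) / width
    f_int = np.convolve(f_int, kernel, mode="same")
    n = min(len(f_int), phase_series.n)
    delta = f_int[:n] - phase_series.frequency[:n]
    mask = phase_series.valid_mask[:n]
    if in_field is not None:
        mask = mask & in_field[:n]
    if speeds is not None:
        mask = mask & (speeds[:n] >= MOVEMENT_SPEED_CM_S)
    out = np.where(mask, delta, np.nan)
    mean_df = float(np.nanmean(out)) if mask.any() else np.nan
    slope = np.nan
    if speeds is not None and mask.any():
        if speed_bins is None:
            speed_bins = np.arange(5.0, 31.0, 5.0)
        centers, means = [], []
        s = speeds[:n]
        for lo, hi in zip(speed_bins[:-1], speed_bins[1:]):
            sel = mask & (s >= lo) & (s < hi)
            if sel.sum() >= 10:
                centers.append((lo + hi) / 2)
                means.append(np.mean(f_int[:n][sel]))
        if len(centers) >= 3:
            slope = float(stats.linregress(centers, means).slope)
    return IntrinsicFrequencyResult(delta_f=out, mean_delta_f=mean_df, speed_slope=slope)


def field_traversal_distances(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    field_set: FieldSet,
    min_chord_cm: float = 4.0,
    speed_threshold: float = MOVEMENT_SPEED_CM_S,
    normalized: bool = True,
    centered: bool = False,
):
    """Distance through the firing field for each spike.

    With ``centered=True`` distances are measured from the traversal
    midpoint instead of the entry, which removes the attenuation that
    variable detected-field widths otherwise introduce when slopes are
    fitted on pooled distances.

    Each contiguous run of within-field samples is one traversal; the
    distance of a sample through the field is its displacement from the
    traversal entry point projected onto the entry-to-exit chord,
    normalized to [0, 1] per traversal (or left in cm with
    ``normalized=False``).  Spikes are assigned the distance of their
    sample.  Returns (per-spike distance, keep mask) where the mask drops
    out-of-field and sub-threshold-speed spikes.
    """
    labels = field_set.labels
    bin_cm = field_set.bin_cm
    pos = trajectory.positions
    nb = labels.shape[0]
    if trajectory.ndim == 1:
        bidx = np.clip((pos / bin_cm).astype(int), 0, nb - 1)
        samp_lab = labels[bidx]
    else:
        bx = np.clip((pos[:, 0] / bin_cm).astype(int), 0, nb - 1)
        by = np.clip((pos[:, 1] / bin_cm).astype(int), 0, nb - 1)
        samp_lab = labels[bx, by]
    in_field = samp_lab > 0
    # traversal = contiguous run of in-field samples with a constant label
    change = np.diff(samp_lab) != 0
    run_starts = np.concatenate([[0], np.flatnonzero(change) + 1])
    run_ends = np.concatenate([run_starts[1:], [len(samp_lab)]])
    norm_dist = np.full(trajectory.n, np.nan)
    for a, b in zip(run_starts, run_ends):
        if samp_lab[a] == 0 or b - a < 2:
            continue
        entry = pos[a]
        exit_ = pos[b - 1]
        chord = exit_ - entry
        length = np.linalg.norm(chord) if trajectory.ndim == 2 else abs(chord)
        if length < min_chord_cm:
            continue
        rel = pos[a:b] - entry
        if trajectory.ndim == 2:
            proj = rel @ chord / (length**2)
        else:
            proj = rel * chord / (length**2)
        proj = np.clip(proj, 0.0, 1.0)
        if centered:
            proj = proj - 0.5
        norm_dist[a:b] = proj if normalized else proj * length
    idx = np.clip(np.round(np.asarray(spike_times) / trajectory.dt).astype(int), 0, trajectory.n - 1)
    dist = norm_dist[idx]
    keep = np.isfinite(dist) & trajectory.movement_mask(speed_threshold)[idx]
    return dist, keep


def precession(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    field_set: FieldSet,
    phase_series: PhaseSeries,
    n_shuffles: int = 1000,
    seed: int | None = None,
    n_grid: int = 2001,
    min_spikes: int = 10,
) -> PrecessionResult:
    """Phase precession as a circular-linear correlation.

    Pools (distance-through-field, firing-phase) pairs across traversals
    and fields and applies the circular-linear correlation with shuffle
    significance (phases shuffled relative to distances).
    """
    dist, keep = field_traversal_distances(spike_times, trajectory, field_set)
    times = np.asarray(spike_times)[keep]
    dist = dist[keep]
    # drop spikes inside the flagged filter-edge windows
    edge_ok = (times >= phase_series.edge_s) & (
        times <= phase_series.n * phase_series.dt - phase_series.edge_s
    )
    times, dist = times[edge_ok], dist[edge_ok]
    if len(times) < min_spikes:
        return PrecessionResult(np.nan, np.nan, np.nan)
    phases = phase_series.phase_at(times)
    res = circstats.circ_linear_corr(
        phases, dist, n_shuffles=n_shuffles, seed=seed, n_grid=n_grid
    )
    return PrecessionResult(
        rho=res.rho, slope=res.slope, p=res.p, distances=dist, phases=phases
    )
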