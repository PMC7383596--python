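"""Per-cycle decoding of location, speed, direction and an auxiliary variable.

All location decoders are Poisson maximum-likelihood estimators over 2-cm
location bins (or candidate oscillatory cycles), computed in the log
domain.  The observed data are per-cycle (or per-phase-bin) population
spike-count vectors; the expectations come from the model's rate code
(optionally combined with the phase code), scaled by average cycle or
phase-bin durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import grid_model as gm
from .signals import CycleSegmentation, PhaseSeries, Trajectory

__all__ = [
    "PopulationVectors",
    "ExpectedCounts",
    "DecodeResult",
    "population_vectors",
    "expected_rate_maps",
    "decode_speed",
    "decode_location_rate",
    "expected_cycle_counts",
    "decode_cycle",
    "decode_direction",
    "decode_cycle_variable",
]

RATE_FLOOR_HZ = 1e-6  # floor on expected rates inside log-likelihoods
CATASTROPHIC_CM = 50.0


@dataclass
class PopulationVectors:
    """Per-cycle and per-phase-bin population spike-count vectors.

    Phase-bin edges are quantiles of the session-pooled spike-phase
    distribution (so pooled counts per bin are approximately equal) and
    are applied identically to every cycle.
    """

    counts: np.ndarray  # (n_cycles, n_cells)
    counts_phase: np.ndarray  # (n_cycles, n_cells, n_phase_bins)
    phase_edges: np.ndarray  # (n_phase_bins + 1,), radians in (-pi, pi]
    mean_cycle_s: float  # mean movement-cycle duration
    mean_bin_s: np.ndarray  # (n_phase_bins,) mean duration of each bin
    cycles: CycleSegmentation
    sample_bins: np.ndarray = field(repr=False, default=None)  # phase bin per sample

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_phase_bins(self) -> int:
        return self.counts_phase.shape[2]

    @property
    def movement(self) -> np.ndarray:
        return self.cycles.movement


@dataclass
class ExpectedCounts:
    """Expected firing rates per location bin (Hz) for every cell."""

    rates: np.ndarray  # (n_cells, n_bins) or (n_cells, nx, ny)
    bin_centers: np.ndarray
    bin_cm: float
    informed: bool


@dataclass
class DecodeResult:
    """Per-cycle decoded values with truth and error summaries."""

    predicted: np.ndarray
    truth: np.ndarray
    errors: np.ndarray
    catastrophic: np.ndarray | None = None
    excluded: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def median_error(self) -> float:
        return float(np.nanmedian(self.errors))

    def fraction_within(self, tol: float) -> float:
        e = self.errors[np.isfinite(self.errors)]
        if len(e) == 0:
            return np.nan
        return float(np.mean(e <= tol))

    @property
    def catastrophic_rate(self) -> float:
        return float(np.nanmean(self.catastrophic)) if self.catastrophic is not None else np.nan


def population_vectors(
    spike_trains: list,
    cycles: CycleSegmentation,
    phase_series: PhaseSeries,
    n_phase_bins: int = 5,
) -> PopulationVectors:
    """Build per-cycle and per-phase-bin population count vectors.

    Only spikes falling inside a segmented cycle are counted.  Phase-bin
    edges are the ``n_phase_bins``-quantiles of the pooled spike phases.
    """
    n_cells = len(spike_trains)
    n_cyc = cycles.n_cycles
    if n_cyc == 0:
        raise ValueError("no cycles to decode")
    b = cycles.boundary_phase
    # cycle-position coordinate: phase measured from the cycle boundary, so
    # bin index follows temporal order within every cycle
    all_u = np.concatenate(
        [
            np.mod(phase_series.phase_at(tr.times) - b, 2 * np.pi)
            for tr in spike_trains
            if tr.n
        ]
    )
    if len(all_u) == 0:
        raise ValueError("no spikes in session")
    qs = np.quantile(all_u, np.linspace(0, 1, n_phase_bins + 1)[1:-1])
    edges = np.concatenate([[0.0], qs, [2 * np.pi]])
    n_samples = int(cycles.ends[-1])
    cyc_of_sample = cycles.cycle_of_sample(n_samples)
    counts = np.zeros((n_cyc, n_cells), dtype=np.int32)
    counts_phase = np.zeros((n_cyc, n_cells, n_phase_bins), dtype=np.int32)
    for j, tr in enumerate(spike_trains):
        if tr.n == 0:
            continue
        idx = np.clip(np.round(tr.times / cycles.dt).astype(int), 0, n_samples - 1)
        cyc = cyc_of_sample[idx]
        ok = cyc >= 0
        u = np.mod(phase_series.phase_at(tr.times[ok]) - b, 2 * np.pi)
        pbin = np.clip(np.searchsorted(edges, u, side="left") - 1, 0, n_phase_bins - 1)
        np.add.at(counts[:, j], cyc[ok], 1)
        np.add.at(counts_phase[:, j, :], (cyc[ok], pbin), 1)
    move = cycles.movement
    mean_cycle = float(np.mean(cycles.durations[move])) if move.any() else float(
        np.mean(cycles.durations)
    )
    # duration of each phase bin: count samples per (cycle, bin)
    samp_u = np.mod(phase_series.phase[:n_samples] - b, 2 * np.pi)
    samp_bin = np.clip(np.searchsorted(edges, samp_u, side="left") - 1, 0, n_phase_bins - 1)
    in_cyc = cyc_of_sample >= 0
    dur = np.zeros((n_cyc, n_phase_bins))
    np.add.at(dur, (cyc_of_sample[in_cyc], samp_bin[in_cyc]), cycles.dt)
    mean_bin = dur[move].mean(axis=0) if move.any() else dur.mean(axis=0)
    return PopulationVectors(
        counts=counts,
        counts_phase=counts_phase,
        phase_edges=edges,
        mean_cycle_s=mean_cycle,
        mean_bin_s=mean_bin,
        cycles=cycles,
        sample_bins=samp_bin,
    )


def expected_rate_maps(
    cells: list,
    trajectory: Trajectory,
    bin_cm: float = 2.0,
    mean_rate: float = 2.0,
    informed: bool = True,
) -> ExpectedCounts:
    """Model-derived expected firing rate of each cell in each location bin.

    The spatial rate code is evaluated at bin centres and normalized
    (weighted by movement occupancy) so each cell's expected session-mean
    rate equals ``mean_rate`` — mirroring the generative normalization.
    With ``informed=False`` the decoder is naive to per-field peak rates
    (r_c treated as 1 everywhere).
    """
    n_bins = int(np.ceil(trajectory.extent / bin_cm))
    move = trajectory.movement_mask()
    pos = trajectory.positions[move]
    if trajectory.ndim == 1:
        centers = (np.arange(n_bins) + 0.5) * bin_cm
        occ = np.bincount(
            np.clip((pos / bin_cm).astype(int), 0, n_bins - 1), minlength=n_bins
        ).astype(float)
        coords = centers
        head = np.ones(n_bins)
    else:
        c1 = (np.arange(n_bins) + 0.5) * bin_cm
        xx, yy = np.meshgrid(c1, c1, indexing="ij")
        coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
        bx = np.clip((pos[:, 0] / bin_cm).astype(int), 0, n_bins - 1)
        by = np.clip((pos[:, 1] / bin_cm).astype(int), 0, n_bins - 1)
        occ = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
        head = np.zeros((n_bins * n_bins, 2))
        centers = coords
    w = occ / max(occ.sum(), 1.0)
    rates = np.empty((len(cells), len(w)))
    for j, cell in enumerate(cells):
        use = cell
        if not informed and cell.peak_rates is not None:
            use = gm.GridCellParams(
                cell_id=cell.cell_id,
                module=cell.module,
                scale=cell.scale,
                offset=cell.offset,
                orientation=cell.orientation,
                phase_mode=cell.phase_mode,
                k=cell.k,
                m_v=cell.m_v,
                peak_rates=None,
            )
        geom = gm.nearest_node(coords, head, use)
        rx = gm.rate_code(geom, use)
        denom = float(np.sum(w * rx))
        rates[j] = mean_rate * rx / max(denom, 1e-12)
    return ExpectedCounts(rates=rates, bin_centers=centers, bin_cm=bin_cm, informed=informed)


def _alternate_split(n: int):
    idx = np.arange(n)
    return idx % 2 == 0, idx % 2 == 1


def decode_speed(pop: PopulationVectors, min_cycles: int = 20) -> DecodeResult:
    """Decode running speed from total population spike counts per cycle.

    A linear fit of speed on total count is estimated on alternate
    (even-indexed) movement cycles and used to predict the odd-indexed
    ones.
    """
    move = pop.movement
    if move.sum() < min_cycles:
        raise ValueError("too few movement cycles for speed decoding")
    totals = pop.counts.sum(axis=1)[move].astype(float)
    speeds = pop.cycles.mean_speeds[move]
    train, test = _alternate_split(len(totals))
    if np.std(totals[train]) == 0 or np.std(speeds[train]) == 0:
        raise ValueError("degenerate speed fit")
    fit = stats.linregress(totals[train], speeds[train])
    pred = fit.intercept + fit.slope * totals[test]
    err = np.abs(pred - speeds[test])
    return DecodeResult(
        predicted=pred,
        truth=speeds[test],
        errors=err,
        extra={"slope": fit.slope, "intercept": fit.intercept, "error_sd": float(np.std(pred - speeds[test]))},
    )


def _poisson_loglik(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """log L(cycle, candidate) = sum_cells [k log mu - mu] (k! dropped)."""
    mu = np.maximum(mu, RATE_FLOOR_HZ * 1e-3)
    return counts @ np.log(mu).T - mu.sum(axis=1)


def decode_location_rate(
    pop: PopulationVectors,
    expected: ExpectedCounts,
    trajectory: Trajectory,
) -> DecodeResult:
    """Maximum-likelihood location per movement cycle from spike counts.

    Expected counts are the per-bin rates times the mean cycle duration;
    the decoded location is the likelihood-maximizing bin centre (ties
    broken by smallest index).  Catastrophic errors are those of at least
    50 cm.
    """
    move = pop.movement
    counts = pop.counts[move].astype(float)
    mu = (expected.rates * pop.mean_cycle_s).T  # (bins, cells) expected counts
    ll = _poisson_loglik(counts, mu)
    best = np.argmax(ll, axis=1)
    if trajectory.ndim == 1:
        pred = expected.bin_centers[best]
        truth = pop.cycles.mean_positions[move]
        err = np.abs(pred - truth)
    else:
        pred = expected.bin_centers[best]
        truth = pop.cycles.mean_positions[move]
        err = np.linalg.norm(pred - truth, axis=1)
    return DecodeResult(
        predicted=pred,
        truth=truth,
        errors=err,
        catastrophic=err >= CATASTROPHIC_CM,
    )


def expected_cycle_counts(
    cells: list,
    trajectory: Trajectory,
    phase_series: PhaseSeries,
    pop: PopulationVectors,
    mode: str = "rate+phase",
    informed: bool = True,
    mean_rate: float = 2.0,
) -> np.ndarray:
    """Expected spike counts per (cycle, cell, phase bin) from the model.

    For each cell the normalized model rate along the known trajectory and
    LFP is averaged over the samples of every (cycle, phase-bin) cell and
    multiplied by the mean phase-bin duration.  In ``rate`` mode the phase
    code factor is omitted (rate code alone); with ``informed=False``
    per-field peak rates are treated as uniform.
    """
    if mode not in ("rate+phase", "rate"):
        raise ValueError("mode must be 'rate+phase' or 'rate'")
    cycles = pop.cycles
    n_samples = int(cycles.ends[-1])
    cyc_of_sample = cycles.cycle_of_sample(n_samples)
    in_cyc = cyc_of_sample >= 0
    nb = pop.n_phase_bins
    flat = cyc_of_sample[in_cyc] * nb + pop.sample_bins[:n_samples][in_cyc]
    denom = np.bincount(flat, minlength=cycles.n_cycles * nb).astype(float)
    out = np.empty((cycles.n_cycles, len(cells), nb))
    for j, cell in enumerate(cells):
        use = cell
        if not informed and cell.peak_rates is not None:
            use = gm.GridCellParams(
                cell_id=cell.cell_id, module=cell.module, scale=cell.scale,
                offset=cell.offset, orientation=cell.orientation,
                phase_mode=cell.phase_mode, k=cell.k, m_v=cell.m_v, peak_rates=None,
            )
        rates = gm.cell_rates(trajectory, phase_series, use, mean_rate=mean_rate)
        r = rates.r_tot
        if mode == "rate":
            # rate code alone: strip the phase factor, renormalize
            base = rates.big_r / np.maximum(rates.r_phi, 1e-300)
            tot = base.sum() * trajectory.dt
            r = mean_rate * len(base) * trajectory.dt * base / max(tot, 1e-300)
        vals = np.bincount(flat, weights=r[:n_samples][in_cyc], minlength=cycles.n_cycles * nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_r = np.where(denom > 0, vals / np.maximum(denom, 1), 0.0)
        out[:, j, :] = mean_r.reshape(cycles.n_cycles, nb) * pop.mean_bin_s[None, :]
    return out


def decode_cycle(
    pop: PopulationVectors,
    expected_counts: np.ndarray,
    mode: str = "rate+phase",
) -> DecodeResult:
    """Maximum-likelihood *cycle* from per-phase-bin population vectors.

    The candidate set is all movement cycles (including the test cycle:
    expectations are model-derived, not observed).  The decoded location is
    the decoded cycle's mean position.
    """
    move = pop.movement
    k = pop.counts_phase[move].astype(float)  # (C, N, P)
    mu = expected_counts[move]  # (C, N, P)
    c, n, p = k.shape
    if c < 2:
        raise ValueError("need at least two candidate cycles")
    ll = _poisson_loglik(k.reshape(c, n * p), mu.reshape(c, n * p))
    best = np.argmax(ll, axis=1)
    pos = pop.cycles.mean_positions[move]
    pred = pos[best]
    truth = pos
    if pos.ndim == 1:
        err = np.abs(pred - truth)
    else:
        err = np.linalg.norm(pred - truth, axis=1)
    return DecodeResult(
        predicted=pred,
        truth=truth,
        errors=err,
        catastrophic=err >= CATASTROPHIC_CM,
        extra={"decoded_cycle": best, "mode": mode},
    )


def decode_direction(
    pop: PopulationVectors,
    expected: ExpectedCounts,
    trajectory: Trajectory,
    min_bins: int = 3,
    min_spikes_per_bin: int = 1,
    tol_deg: float = 30.0,
) -> DecodeResult:
    """Decode movement direction from the within-cycle location sequence.

    Location is ML-decoded independently in each phase bin of each
    movement cycle; the slopes of decoded x and y against phase-bin index
    (linear regression) give the direction as their arctangent.  The true
    direction is computed identically from the actual mean positions in
    the same phase bins.  Cycles with fewer than ``min_bins`` usable bins
    or zero decoded displacement are excluded (and counted).
    """
    if trajectory.ndim != 2:
        raise ValueError("direction decoding requires a 2D environment")
    move_idx = np.flatnonzero(pop.movement)
    nbins = pop.n_phase_bins
    cycles = pop.cycles
    n_samples = int(cycles.ends[-1])
    cyc_of_sample = cycles.cycle_of_sample(n_samples)
    # actual mean position per (cycle, phase bin)
    in_cyc = cyc_of_sample >= 0
    flat = cyc_of_sample[in_cyc] * nbins + pop.sample_bins[:n_samples][in_cyc]
    npos = np.bincount(flat, minlength=cycles.n_cycles * nbins).astype(float)
    sumx = np.bincount(flat, weights=trajectory.positions[:n_samples][in_cyc, 0], minlength=cycles.n_cycles * nbins)
    sumy = np.bincount(flat, weights=trajectory.positions[:n_samples][in_cyc, 1], minlength=cycles.n_cycles * nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        true_x = (sumx / npos).reshape(cycles.n_cycles, nbins)
        true_y = (sumy / npos).reshape(cycles.n_cycles, nbins)
    npos = npos.reshape(cycles.n_cycles, nbins)
    # ML-decode location per (movement cycle, phase bin), batched per bin
    dec_x = np.full((len(move_idx), nbins), np.nan)
    dec_y = np.full((len(move_idx), nbins), np.nan)
    for p in range(nbins):
        mu = (expected.rates * pop.mean_bin_s[p]).T  # (bins, cells)
        k = pop.counts_phase[move_idx, :, p].astype(float)
        ll = _poisson_loglik(k, mu)
        best = np.argmax(ll, axis=1)
        dec_x[:, p] = expected.bin_centers[best, 0]
        dec_y[:, p] = expected.bin_centers[best, 1]
    spikes_per_bin = pop.counts_phase[move_idx].sum(axis=1)  # (C, P)
    usable = (spikes_per_bin >= min_spikes_per_bin) & (npos[move_idx] > 0)
    pred_dir, true_dir = [], []
    excluded = 0
    bin_index = np.arange(nbins, dtype=float)

    def _slope(b, y):
        bm = b.mean()
        return np.sum((b - bm) * (y - y.mean())) / np.sum((b - bm) ** 2)

    for row, ci in enumerate(move_idx):
        use = usable[row]
        if use.sum() < min_bins:
            excluded += 1
            continue
        bu = bin_index[use]
        sx = _slope(bu, dec_x[row, use])
        sy = _slope(bu, dec_y[row, use])
        tsx = _slope(bu, true_x[ci, use])
        tsy = _slope(bu, true_y[ci, use])
        if sx == 0 and sy == 0:
            excluded += 1
            continue
        pred_dir.append(np.arctan2(sy, sx))
        true_dir.append(np.arctan2(tsy, tsx))
    pred_dir = np.asarray(pred_dir)
    true_dir = np.asarray(true_dir)
    err = np.abs(np.angle(np.exp(1j * (pred_dir - true_dir))))
    return DecodeResult(
        predicted=pred_dir,
        truth=true_dir,
        errors=np.rad2deg(err),
        excluded=excluded,
        extra={"fraction_within_tol": float(np.mean(np.rad2deg(err) <= tol_deg)) if len(err) else np.nan},
    )


def decode_cycle_variable(
    pop: PopulationVectors,
    variable: np.ndarray,
    predictor: str = "frequency",
    tol_frac: float = 0.05,
) -> DecodeResult:
    """Decode an auxiliary scalar from per-cycle oscillatory durations.

    ``variable`` is a per-sample series (e.g. an affine function of LFP
    frequency); its per-cycle mean is regressed on the cycle duration —
    via the inverse duration (per-cycle frequency) by default, which
    linearizes a frequency-encoded variable — using alternate cycles for
    training.  Errors are reported relative to the variable's range.
    """
    cycles = pop.cycles
    move = pop.movement
    n_samples = int(cycles.ends[-1])
    cyc_of_sample = cycles.cycle_of_sample(n_samples)
    in_cyc = cyc_of_sample >= 0
    nsamp = np.bincount(cyc_of_sample[in_cyc], minlength=cycles.n_cycles).astype(float)
    sums = np.bincount(cyc_of_sample[in_cyc], weights=variable[:n_samples][in_cyc], minlength=cycles.n_cycles)
    z = (sums / np.maximum(nsamp, 1))[move]
    durations = cycles.durations[move]
    if np.std(durations) == 0:
        raise ValueError("constant cycle durations: degenerate fit")
    x = 1.0 / durations if predictor == "frequency" else durations
    train, test = _alternate_split(len(x))
    fit = stats.linregress(x[train], z[train])
    pred = fit.intercept + fit.slope * x[test]
    rng_z = np.ptp(z) if np.ptp(z) > 0 else 1.0
    err = np.abs(pred - z[test]) / rng_z
    return DecodeResult(
        predicted=pred,
        truth=z[test],
        errors=err,
        extra={"fraction_within_tol": float(np.mean(err <= tol_frac)), "slope": fit.slope},
    )
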