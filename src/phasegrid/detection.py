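"""Empirical detection of phase coding without rhythmicity.

Spike-triggered averages of the amplitude-normalized synthetic signal
cos(theta(t)), split by early/middle/late thirds of the firing field,
reveal a systematic shift of the preferred deflection with progress
through the field when cells phase-precess — without requiring a narrow
spectral peak.  Band-pass-filtered multi-unit activity (summed population
rate) can substitute for the LFP as the phase reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import circstats
from .signals import LFPSeries, PhaseSeries, Trajectory
from .spatial import FieldSet
from .temporal import field_traversal_distances

__all__ = [
    "STAResult",
    "assign_field_regions",
    "spike_triggered_average",
    "mua_substitute",
]

REGIONS = ("early", "middle", "late")


@dataclass
class STAResult:
    """Spike-triggered averages and circular mean phases by field region."""

    lags: np.ndarray  # s
    traces: dict  # region -> mean trace over the lag window
    mean_phases: dict  # region -> circular mean spike phase
    counts: dict  # region -> number of spikes
    low_confidence: dict  # region -> True if < 10 spikes


def assign_field_regions(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    field_set: FieldSet,
) -> dict:
    """Split spikes into early/middle/late thirds of the traversed field.

    Thirds are defined on the normalized distance through the field
    (entry-to-exit chord), pooled over traversals and fields.
    """
    dist, keep = field_traversal_distances(spike_times, trajectory, field_set)
    times = np.asarray(spike_times)[keep]
    dist = dist[keep]
    out = {}
    out["early"] = times[dist < 1 / 3]
    out["middle"] = times[(dist >= 1 / 3) & (dist < 2 / 3)]
    out["late"] = times[dist >= 2 / 3]
    return out


def spike_triggered_average(
    spikes_by_region: dict,
    signal: LFPSeries,
    window_s: float = 0.25,
    phase_series: PhaseSeries | None = None,
) -> STAResult:
    """Average the signal around spike times, per field region.

    ``signal`` is normally the synthetic amplitude-normalized signal
    cos(theta) (use the raw LFP instead to demonstrate the amplitude
    confound).  If a phase series is given, per-region circular mean spike
    phases are returned as well.
    """
    fs = signal.sample_rate
    half = int(round(window_s * fs))
    lags = np.arange(-half, half + 1) / fs
    x = np.asarray(signal.samples, float)
    traces, phases, counts, lowconf = {}, {}, {}, {}
    for region, times in spikes_by_region.items():
        times = np.asarray(times, float)
        idx = np.round(times * fs).astype(int)
        idx = idx[(idx >= half) & (idx < len(x) - half)]
        counts[region] = len(idx)
        lowconf[region] = len(idx) < 10
        if len(idx) == 0:
            traces[region] = np.full(2 * half + 1, np.nan)
            phases[region] = np.nan
            continue
        windows = x[idx[:, None] + np.arange(-half, half + 1)[None, :]]
        traces[region] = windows.mean(axis=0)
        if phase_series is not None:
            phases[region] = circstats.resultant(phase_series.phase_at(idx / fs))[1]
        else:
            phases[region] = np.nan
    return STAResult(
        lags=lags, traces=traces, mean_phases=phases, counts=counts, low_confidence=lowconf
    )


def mua_substitute(
    summed_rates: np.ndarray,
    dt: float,
    synthetic: LFPSeries,
    band_lo: float = 2.0,
    band_hi: float = 20.0,
    max_lag_s: float = 0.1,
    trough_reference: bool = True,
) -> tuple[np.ndarray, float, float, float]:
    """Band-pass-filtered multi-unit activity as an LFP substitute.

    The summed population rate is filtered with a *causal* second-order
    Butterworth band-pass (a leaky-integration stand-in that cannot see
    the future) and correlated with the amplitude-normalized synthetic
    signal.  Population firing concentrates at the oscillation trough
    (preferred phase pi), so by default the comparison uses the
    trough-referenced signal -cos(theta); set ``trough_reference=False``
    to correlate against cos(theta) directly.  Because a causal filter
    delays its output, the correlation is also maximized over small lags.

    Returns (filtered trace, zero-lag correlation, best correlation over
    lags, best lag in seconds).
    """
    fs = 1.0 / dt
    if fs <= 2 * band_hi:
        raise ValueError("rate series sampled too slowly for the filter band")
    sos = sps.butter(2, [band_lo, band_hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfilt(sos, np.asarray(summed_rates, float))
    n = min(len(filt), len(synthetic.samples))
    a = filt[:n] - filt[:n].mean()
    b = np.asarray(synthetic.samples[:n], float)
    if trough_reference:
        b = -b
    b = b - b.mean()
    sd_a, sd_b = a.std(), b.std()
    if sd_a == 0 or sd_b == 0:
        return filt, np.nan, np.nan, 0.0
    r0 = float(np.mean(a * b) / (sd_a * sd_b))
    max_lag = int(round(max_lag_s * fs))
    best_r, best_lag = r0, 0.0
    for lag in range(1, max_lag + 1):
        # positive lag: MUA delayed relative to the synthetic signal
        r = float(np.corrcoef(a[lag:], b[: n - lag])[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag * dt
    return filt, r0, best_r, best_lag
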