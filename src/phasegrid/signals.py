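"""Trajectory and LFP generation, phase extraction, and cycle segmentation.

Synthetic trajectories emulate foraging behaviour (bounded smooth random
walks in speed and heading) and synthetic LFP signals emulate either the
rodent condition (a constant-frequency theta sinusoid) or an arrhythmic
signal with broadband low-frequency power, from which instantaneous phase
and frequency are extracted with a zero-phase band-pass filter and the
Hilbert transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Trajectory",
    "LFPSeries",
    "PhaseSeries",
    "CycleSegmentation",
    "gen_trajectory_1d",
    "gen_trajectory_2d",
    "gen_broadband_lfp",
    "preprocess_lfp",
    "synthetic_signal",
    "segment_cycles",
]

#: running-speed threshold (cm/s) defining periods of movement
MOVEMENT_SPEED_CM_S = 5.0


@dataclass
class Trajectory:
    """Uniformly sampled positions and velocities of a simulated agent.

    Attributes
    ----------
    dt : float
        Seconds per sample.
    positions : ndarray
        ``(n,)`` in 1D or ``(n, 2)`` in 2D, cm.
    speeds : ndarray
        ``(n,)`` running speed, cm/s.
    headings : ndarray
        Unit direction-of-travel vectors ``(n, 2)`` in 2D, or the sign of
        travel ``(n,)`` in 1D.
    extent : float
        Track length (1D) or box side (2D), cm.
    """

    dt: float
    positions: np.ndarray
    speeds: np.ndarray
    headings: np.ndarray
    extent: float

    @property
    def n(self) -> int:
        return len(self.speeds)

    @property
    def ndim(self) -> int:
        return 1 if self.positions.ndim == 1 else 2

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def movement_mask(self, threshold: float = MOVEMENT_SPEED_CM_S) -> np.ndarray:
        """Boolean mask of samples with running speed >= ``threshold``."""
        return self.speeds >= threshold

    def to_csv(self, path) -> None:
        cols = {"t_s": self.times}
        if self.ndim == 1:
            cols["x_cm"] = self.positions
        else:
            cols["x_cm"] = self.positions[:, 0]
            cols["y_cm"] = self.positions[:, 1]
        cols["speed_cm_s"] = self.speeds
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, extent: float | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("trajectory file must contain at least two samples")
        dt = float(np.median(np.diff(t)))
        speeds = df["speed_cm_s"].to_numpy(float)
        if "y_cm" in df.columns:
            pos = df[["x_cm", "y_cm"]].to_numpy(float)
            vel = np.gradient(pos, dt, axis=0)
            norm = np.linalg.norm(vel, axis=1)
            headings = np.where(norm[:, None] > 0, vel / np.maximum(norm, 1e-12)[:, None], 0.0)
            ext = extent if extent is not None else float(pos.max())
        else:
            pos = df["x_cm"].to_numpy(float)
            headings = np.sign(np.gradient(pos, dt))
            headings[headings == 0] = 1.0
            ext = extent if extent is not None else float(pos.max())
        return cls(dt=dt, positions=pos, speeds=speeds, headings=headings, extent=ext)


@dataclass
class LFPSeries:
    """A single-channel sampled voltage trace (dimensionless amplitude)."""

    samples: np.ndarray
    sample_rate: float
    kind: str = "raw"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_csv(self, path) -> None:
        pd.DataFrame({"sample": self.samples}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate: float) -> "LFPSeries":
        df = pd.read_csv(path)
        return cls(samples=df["sample"].to_numpy(float), sample_rate=sample_rate)

    @classmethod
    def from_raw(cls, path, sample_rate: float) -> "LFPSeries":
        """Read a raw little-endian float32 sample stream."""
        samples = np.fromfile(path, dtype="<f4").astype(float)
        if len(samples) == 0:
            raise ValueError("empty raw LFP stream")
        return cls(samples=samples, sample_rate=sample_rate)


@dataclass
class PhaseSeries:
    """Instantaneous LFP phase and smoothed frequency on the simulation clock.

    ``phase`` is wrapped to (-pi, pi]; ``frequency`` is the per-sample phase
    advance (clamped at zero) smoothed with a 50 ms boxcar.  The first and
    last ``edge_s`` seconds are flagged invalid because of filter and
    analytic-signal edge artifacts.
    """

    phase: np.ndarray
    frequency: np.ndarray
    dt: float
    edge_s: float = 0.5

    @property
    def n(self) -> int:
        return len(self.phase)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def valid_mask(self) -> np.ndarray:
        t = self.times
        return (t >= self.edge_s) & (t <= t[-1] - self.edge_s)

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times (continuous, via complex interpolation).

        Linear interpolation of the unit phasor between samples avoids the
        per-spike quantization jitter a nearest-sample lookup would add.
        """
        t = np.clip(np.asarray(times, float), 0.0, (self.n - 1) * self.dt)
        i0 = np.minimum((t / self.dt).astype(int), self.n - 2)
        frac = t / self.dt - i0
        z = (1 - frac) * np.exp(1j * self.phase[i0]) + frac * np.exp(1j * self.phase[i0 + 1])
        return np.angle(z)

    def frequency_at(self, times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round(np.asarray(times) / self.dt).astype(int), 0, self.n - 1)
        return self.frequency[idx]


@dataclass
class CycleSegmentation:
    """Contiguous oscillatory cycles, one per full 2*pi phase revolution.

    Cycle boundaries are the upward crossings of ``boundary_phase``
    (default: the oscillation peak, theta = 0).  Each cycle records its
    sample range, duration, mean running speed and mean position, plus a
    movement flag (mean speed >= 5 cm/s).
    """

    starts: np.ndarray  # sample index of cycle start (inclusive)
    ends: np.ndarray  # sample index of cycle end (exclusive)
    durations: np.ndarray  # s
    mean_speeds: np.ndarray  # cm/s
    mean_positions: np.ndarray  # (n_cyc,) or (n_cyc, 2) cm
    movement: np.ndarray  # bool
    dt: float = 0.005
    boundary_phase: float = 0.0

    @property
    def n_cycles(self) -> int:
        return len(self.starts)

    def cycle_of_sample(self, n_samples: int) -> np.ndarray:
        """Map each sample index to its cycle index (-1 outside any cycle)."""
        out = np.full(n_samples, -1, dtype=int)
        for i, (a, b) in enumerate(zip(self.starts, self.ends)):
            out[a:b] = i
        return out


def _reflect(x: np.ndarray | float, lo: float, hi: float):
    """Reflect values into [lo, hi] (single fold is enough for small steps)."""
    width = hi - lo
    y = np.mod(np.asarray(x) - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return y + lo


def _bounded_random_walk(n, lo, hi, tau_s, dt, rng, x0=None):
    """Gaussian-increment random walk reflected into [lo, hi].

    The per-step increment scale is chosen so that the walk decorrelates
    (diffuses across the range) over roughly ``tau_s`` seconds.
    """
    if hi == lo:
        return np.full(n, lo)
    step_sd = (hi - lo) * np.sqrt(dt / tau_s)
    steps = rng.normal(0.0, step_sd, size=n)
    if x0 is None:
        x0 = rng.uniform(lo, hi)
    walk = x0 + np.cumsum(steps)
    return _reflect(walk, lo, hi)


def gen_trajectory_1d(
    duration_s: float = 300.0,
    dt_s: float = 0.005,
    speed_min: float = 2.0,
    speed_max: float = 30.0,
    seed: int | None = None,
    speed_tau_s: float = 1.0,
) -> Trajectory:
    """Generate movement along a linear track.

    Running speed varies randomly within [speed_min, speed_max] cm/s as a
    reflected Gaussian random walk and is integrated over time to give
    displacement along the track (~50 m over 300 s with defaults).
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")
    if not (0 < speed_min <= speed_max):
        raise ValueError("need 0 < speed_min <= speed_max")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    if speed_min == speed_max:
        speeds = np.full(n, speed_min)
    else:
        speeds = _bounded_random_walk(n, speed_min, speed_max, speed_tau_s, dt_s, rng)
    # position at sample i is the integral of speed over preceding samples,
    # so that position[0] = 0 and speeds[i] = (x[i+1]-x[i])/dt
    pos = np.concatenate([[0.0], np.cumsum(speeds[:-1]) * dt_s])
    headings = np.ones(n)
    return Trajectory(dt=dt_s, positions=pos, speeds=speeds, headings=headings, extent=float(pos[-1] + speeds[-1] * dt_s))


def gen_trajectory_2d(
    duration_s: float = 300.0,
    dt_s: float = 0.005,
    box_cm: float = 100.0,
    seed: int | None = None,
    speed_min: float = 2.0,
    speed_max: float = 30.0,
    speed_tau_s: float = 1.0,
    heading_tau_s: float = 1.0,
) -> Trajectory:
    """Generate a smooth correlated random walk in a square box.

    A synthetic stand-in for rat open-field foraging: speed follows a
    reflected random walk in [speed_min, speed_max] cm/s, heading follows a
    wrapped random walk (decorrelating over ~``heading_tau_s``), and walls
    are reflective.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")
    if box_cm <= 0:
        raise ValueError("box_cm must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    walk_speeds = _bounded_random_walk(n, speed_min, speed_max, speed_tau_s, dt_s, rng)
    # angular Brownian motion with <cos(psi(t)-psi(0))> = exp(-t/heading_tau_s)
    ang_step = np.sqrt(2 * dt_s / heading_tau_s)
    psi = rng.uniform(-np.pi, np.pi) + np.cumsum(rng.normal(0.0, ang_step, size=n))
    steps = (walk_speeds * dt_s)[:, None] * np.stack([np.cos(psi), np.sin(psi)], axis=1)
    x0 = rng.uniform(0.2 * box_cm, 0.8 * box_cm, size=2)
    raw = x0 + np.concatenate([np.zeros((1, 2)), np.cumsum(steps[:-1], axis=0)])
    # reflective walls: fold the unconstrained path back into the box
    # (billiard reflection preserves step lengths and mirrors headings)
    pos = _reflect(raw, 0.0, box_cm)
    disp = np.diff(pos, axis=0)
    disp = np.concatenate([disp, disp[-1:]], axis=0)
    norms = np.linalg.norm(disp, axis=1)
    speeds = norms / dt_s
    head = disp / np.maximum(norms, 1e-12)[:, None]
    return Trajectory(dt=dt_s, positions=pos, speeds=speeds, headings=head, extent=box_cm)


def gen_broadband_lfp(
    duration_s: float = 300.0,
    sample_rate: float = 512.0,
    band_lo: float = 2.0,
    band_hi: float = 20.0,
    seed: int | None = None,
    freq_tau_s: float = 1.0,
    noise_amp: float = 0.3,
    amp_mod_depth: float = 0.5,
    amp_tau_s: float = 2.0,
) -> LFPSeries:
    """Generate a baseline signal with broadband low-frequency power.

    A frequency-modulated oscillator whose instantaneous frequency follows a
    bounded random walk across [band_lo, band_hi] Hz (decorrelating over
    ~1 s), multiplied by a slowly varying positive amplitude envelope, plus
    an optional 1/f background.  The result has no dominant narrow spectral
    peak but a well-defined extractable phase.

    Setting ``band_lo == band_hi`` gives the constant-frequency degenerate
    mode: a pure sinusoid (the rodent theta condition, e.g. 8 Hz).
    """
    if band_lo > band_hi:
        raise ValueError("band_lo must not exceed band_hi")
    if duration_s <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    dt = 1.0 / sample_rate
    if band_lo == band_hi:
        t = np.arange(n) * dt
        return LFPSeries(np.cos(2 * np.pi * band_lo * t), sample_rate, kind="sinusoid")
    # random walk on log-frequency: uniform occupancy per octave, i.e. a
    # 1/f-weighted (low-frequency dominated) broadband spectrum as seen in
    # hippocampal LFP recordings
    freq = np.exp(
        _bounded_random_walk(n, np.log(band_lo), np.log(band_hi), freq_tau_s, dt, rng)
    )
    phase = np.cumsum(2 * np.pi * freq * dt)
    carrier = np.cos(phase)
    if amp_mod_depth > 0:
        env = 1.0 + amp_mod_depth * (
            _bounded_random_walk(n, -1.0, 1.0, amp_tau_s, dt, rng)
        )
        env = np.clip(env, 0.1, None)
        carrier = carrier * env
    if noise_amp > 0:
        # 1/f background: shape white noise in the frequency domain
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, dt)
        f[0] = f[1]
        spec = spec / np.sqrt(f)
        pink = np.fft.irfft(spec, n)
        pink = pink / np.std(pink)
        carrier = carrier + noise_amp * pink
    return LFPSeries(carrier, sample_rate, kind="broadband")


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    # reflect-pad so edges are averaged over available samples
    pad = width // 2
    xp = np.pad(x, pad, mode="reflect")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def preprocess_lfp(
    lfp: LFPSeries,
    band_lo: float = 2.0,
    band_hi: float = 20.0,
    target_dt: float = 0.005,
    boxcar_s: float = 0.05,
) -> PhaseSeries:
    """Extract instantaneous phase and frequency from an LFP trace.

    The trace is band-pass filtered (zero-phase second-order Butterworth),
    the phase taken from the analytic (Hilbert) signal, instantaneous
    frequency computed from per-sample phase increments (clamped at zero,
    then smoothed with a 50 ms boxcar), and both linearly interpolated to
    the simulation time step.
    """
    if lfp.duration < 1.0:
        raise ValueError("LFP shorter than 1 s: edge effects dominate")
    fs = lfp.sample_rate
    if fs <= 2 * band_hi:
        raise ValueError("sample rate must exceed twice the upper band edge")
    sos = sps.butter(2, [band_lo, band_hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, lfp.samples)
    analytic = sps.hilbert(filt)
    phase = np.unwrap(np.angle(analytic))
    dphase = np.diff(phase)
    # broadband Hilbert phase can locally regress; clamp at zero frequency
    inst_f = np.maximum(dphase, 0.0) * fs / (2 * np.pi)
    inst_f = np.concatenate([inst_f[:1], inst_f])
    width = max(1, int(round(boxcar_s * fs)))
    inst_f = _boxcar(inst_f, width)
    t_src = np.arange(len(phase)) / fs
    n_out = int(round(lfp.duration / target_dt))
    t_out = np.arange(n_out) * target_dt
    t_out = t_out[t_out <= t_src[-1] + 1e-9]
    phase_i = np.interp(t_out, t_src, phase)
    freq_i = np.interp(t_out, t_src, inst_f)
    wrapped = np.angle(np.exp(1j * phase_i))
    # represent phase in (-pi, pi]
    wrapped[wrapped == -np.pi] = np.pi
    return PhaseSeries(phase=wrapped, frequency=freq_i, dt=target_dt)


def synthetic_signal(phase_series: PhaseSeries) -> LFPSeries:
    """Amplitude-normalized synthetic signal s(t) = cos(theta(t)).

    Reconstructing the baseline from the cosine of its phase removes
    amplitude differences between cycles, which would otherwise skew
    spike-triggered averages.
    """
    return LFPSeries(
        samples=np.cos(phase_series.phase),
        sample_rate=1.0 / phase_series.dt,
        kind="synthetic-from-phase",
    )


def segment_cycles(
    phase_series: PhaseSeries,
    trajectory: Trajectory,
    speed_threshold: float = MOVEMENT_SPEED_CM_S,
    boundary_phase: float = 0.0,
) -> CycleSegmentation:
    """Segment the phase series into oscillatory cycles.

    A cycle spans one full 2*pi revolution of the phase; boundaries are
    the upward crossings of ``boundary_phase``.  The default boundary is
    the oscillation peak (theta = 0), so that firing concentrated at the
    trough (preferred phase pi) falls mid-cycle and population activity
    dips between cycles.  Cycles overlapping the flagged filter edges are
    dropped.  Each cycle's mean running speed sets its movement flag.
    """
    n = min(phase_series.n, trajectory.n)
    # cycle-position coordinate: 0 at the boundary, increasing to 2*pi
    u = np.mod(phase_series.phase[:n] - boundary_phase, 2 * np.pi)
    wraps = np.flatnonzero(np.diff(u) < -np.pi) + 1
    if len(wraps) < 2:
        return CycleSegmentation(
            starts=np.array([], int),
            ends=np.array([], int),
            durations=np.array([]),
            mean_speeds=np.array([]),
            mean_positions=np.array([]),
            movement=np.array([], bool),
            dt=phase_series.dt,
            boundary_phase=boundary_phase,
        )
    starts = wraps[:-1]
    ends = wraps[1:]
    valid = phase_series.valid_mask[:n]
    keep = valid[starts] & valid[np.minimum(ends, n - 1)]
    starts, ends = starts[keep], ends[keep]
    durations = (ends - starts) * phase_series.dt
    speeds = trajectory.speeds[:n]
    pos = trajectory.positions[:n]
    cs = np.concatenate([[0.0], np.cumsum(speeds)])
    mean_speeds = (cs[ends] - cs[starts]) / (ends - starts)
    if pos.ndim == 1:
        cp = np.concatenate([[0.0], np.cumsum(pos)])
        mean_pos = (cp[ends] - cp[starts]) / (ends - starts)
    else:
        cp = np.concatenate([np.zeros((1, 2)), np.cumsum(pos, axis=0)])
        mean_pos = (cp[ends] - cp[starts]) / (ends - starts)[:, None]
    movement = mean_speeds >= speed_threshold
    return CycleSegmentation(
        starts=starts,
        ends=ends,
        durations=durations,
        mean_speeds=mean_speeds,
        mean_positions=mean_pos,
        movement=movement,
        dt=phase_series.dt,
        boundary_phase=boundary_phase,
    )
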