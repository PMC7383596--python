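"""End-to-end experiment orchestration.

A run = one synthetic session: trajectory + LFP + simulated population +
the requested analyses, with every random draw seeded deterministically
from the master seed and run index.  Conditions combine the baseline kind
(constant-frequency theta vs arrhythmic broadband), the phase-coding mode
(precession vs locking) and per-field peak-rate heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import decoding as dc
from . import grid_model as gm
from . import signals as sg
from . import spatial as sp
from . import temporal as tp

__all__ = ["ExperimentConfig", "SessionData", "simulate_session", "run_experiment", "compare_conditions"]


@dataclass
class ExperimentConfig:
    """Configuration of a simulated experiment (paper-default values)."""

    environment: str = "2d"  # "1d" (linear track) or "2d" (square box)
    duration_s: float = 300.0
    box_cm: float = 100.0
    lfp: str = "broadband"  # "broadband" or "constant"
    theta_hz: float = 8.0  # frequency of the constant-theta condition
    band: tuple = (2.0, 20.0)
    lfp_sample_rate: float = 512.0
    phase_mode: str = "precession"  # or "locking"
    heterogeneous: bool = False
    n_cells: int = 200
    n_runs: int = 20
    master_seed: int = 0
    n_shuffles: int = 100
    analyses: tuple = ("locking", "decode")  # + "gridness", "precession", "oscillation"

    def run_seeds(self, run: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.master_seed, spawn_key=(run,))


@dataclass
class SessionData:
    """All raw objects of one simulated session."""

    trajectory: sg.Trajectory
    lfp: sg.LFPSeries
    phases: sg.PhaseSeries
    cells: list
    trains: list
    cycles: sg.CycleSegmentation


def simulate_session(config: ExperimentConfig, run: int = 0) -> SessionData:
    """Generate one full session deterministically from the master seed."""
    ss = config.run_seeds(run)
    s_traj, s_lfp, s_cells, s_spikes = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    if config.environment == "1d":
        traj = sg.gen_trajectory_1d(config.duration_s, seed=s_traj)
    else:
        traj = sg.gen_trajectory_2d(config.duration_s, box_cm=config.box_cm, seed=s_traj)
    # generate slightly more LFP than needed so filter edges fall outside
    lfp_dur = config.duration_s + 1.07
    if config.lfp == "constant":
        lfp = sg.gen_broadband_lfp(lfp_dur, config.lfp_sample_rate, config.theta_hz, config.theta_hz)
    else:
        lfp = sg.gen_broadband_lfp(
            lfp_dur, config.lfp_sample_rate, config.band[0], config.band[1], seed=s_lfp
        )
    phases = sg.preprocess_lfp(lfp, config.band[0], config.band[1])
    pcfg = gm.PopulationConfig(
        n_cells=config.n_cells,
        phase_mode=config.phase_mode,
        heterogeneous=config.heterogeneous,
    )
    cells = gm.build_population(pcfg, traj, seed=s_cells)
    trains = gm.simulate_population(traj, phases, cells, seed=s_spikes)
    cycles = sg.segment_cycles(phases, traj)
    return SessionData(
        trajectory=traj, lfp=lfp, phases=phases, cells=cells, trains=trains, cycles=cycles
    )


def _analyze_session(config: ExperimentConfig, data: SessionData, run: int) -> dict:
    ss = config.run_seeds(run)
    shuffle_seed = int(ss.spawn(5)[4].generate_state(1)[0] % 2**31)
    out = {"per_cell": None, "decode": {}}
    rows = []
    do_lock = "locking" in config.analyses
    do_grid = "gridness" in config.analyses and data.trajectory.ndim == 2
    do_prec = "precession" in config.analyses
    do_osc = "oscillation" in config.analyses
    for i, (cell, train) in enumerate(zip(data.cells, data.trains)):
        row = {"cell_id": cell.cell_id, "module": cell.module, "scale": cell.scale, "n_spikes": train.n}
        if do_lock:
            pl = tp.phase_locking(
                train.times, data.phases, data.trajectory,
                n_shuffles=config.n_shuffles, seed=shuffle_seed + i,
            )
            row.update(R=pl.r, mean_phase=pl.mean_phase, locking_sig=pl.significant)
        if do_grid or do_prec:
            rm = sp.rate_map(train.times, data.trajectory)
            fs = sp.detect_fields(rm)
            row.update(n_fields=fs.n_fields, cv=fs.cv)
            if do_grid:
                g = sp.gridness_shuffle_test(
                    train.times, data.trajectory,
                    n_shuffles=config.n_shuffles, seed=shuffle_seed + 1000 + i,
                )
                row.update(gridness=g.score, grid_scale=g.scale_cm, gridness_sig=g.significant)
            if do_prec:
                pr = tp.precession(
                    train.times, data.trajectory, fs, data.phases,
                    n_shuffles=max(200, config.n_shuffles), seed=shuffle_seed + 2000 + i,
                    n_grid=201,
                )
                row.update(rho=pr.rho, slope=pr.slope, precession_p=pr.p)
        if do_osc and train.n >= 100:
            oi = tp.oscillation_index(train.times, n_restarts=100, seed=shuffle_seed + 3000 + i)
            row.update(oi=oi.oscillation_index, ac_frequency=oi.frequency)
        rows.append(row)
    out["per_cell"] = pd.DataFrame(rows)
    if "decode" in config.analyses:
        pop = dc.population_vectors(data.trains, data.cycles, data.phases)
        exp = dc.expected_rate_maps(data.cells, data.trajectory)
        summary = {}
        speed = dc.decode_speed(pop)
        summary["speed_frac_within_5cm_s"] = speed.fraction_within(5.0)
        summary["speed_error_sd"] = speed.extra["error_sd"]
        loc = dc.decode_location_rate(pop, exp, data.trajectory)
        summary["location_median_error_cm"] = loc.median_error
        summary["location_catastrophic_rate"] = loc.catastrophic_rate
        if data.trajectory.ndim == 2:
            d = dc.decode_direction(pop, exp, data.trajectory)
            summary["direction_frac_within_30deg"] = d.extra["fraction_within_tol"]
        z = (data.phases.frequency - config.band[0]) / (config.band[1] - config.band[0])
        var = dc.decode_cycle_variable(pop, z)
        summary["variable_frac_within_5pct"] = var.extra["fraction_within_tol"]
        out["decode"] = summary
    return out


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Run ``n_runs`` sessions and write per-run and aggregate tables.

    Identical configuration and master seed give byte-identical outputs.
    Returns the aggregate summary dict (also written as JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    decode_rows = []
    cell_frames = []
    for run in range(config.n_runs):
        data = simulate_session(config, run)
        res = _analyze_session(config, data, run)
        run_dir = out_dir / f"run{run:03d}"
        run_dir.mkdir(exist_ok=True)
        gm.spikes_to_csv(data.trains, run_dir / "spikes.csv")
        data.trajectory.to_csv(run_dir / "trajectory.csv")
        res["per_cell"].insert(0, "run", run)
        res["per_cell"].to_csv(run_dir / "per_cell.csv", index=False)
        cell_frames.append(res["per_cell"])
        if res["decode"]:
            decode_rows.append({"run": run, **res["decode"]})
    cells = pd.concat(cell_frames, ignore_index=True)
    cells.to_csv(out_dir / "per_cell_all.csv", index=False)
    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_runs": config.n_runs,
    }
    if "R" in cells.columns:
        summary["median_R"] = float(cells["R"].median())
        summary["pct_locking_significant"] = float(100 * cells["locking_sig"].mean())
    if "gridness" in cells.columns:
        summary["median_gridness"] = float(cells["gridness"].median())
        summary["pct_gridness_significant"] = float(100 * cells["gridness_sig"].mean())
    if "cv" in cells.columns:
        summary["median_cv"] = float(cells["cv"].median())
    if "rho" in cells.columns:
        summary["median_rho"] = float(cells["rho"].median())
        summary["pct_precession_significant"] = float(100 * (cells["precession_p"] < 0.05).mean())
    if "oi" in cells.columns:
        summary["median_oi"] = float(cells["oi"].median())
    if decode_rows:
        dec = pd.DataFrame(decode_rows)
        dec.to_csv(out_dir / "decode_summary.csv", index=False)
        for col in dec.columns:
            if col != "run":
                summary[f"mean_{col}"] = float(dec[col].mean())
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def compare_conditions(a, b, pooled: bool = True) -> dict:
    """Two-sample comparison of a per-cell metric between conditions.

    Returns the t statistic, degrees of freedom, p-value and Cohen's d
    (pooled-SD effect size).  This is report plumbing for condition
    contrasts; with pooled variances df = n_a + n_b - 2.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = len(a) + len(b) - 2
        sd = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        )
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    d = (a.mean() - b.mean()) / sd if sd > 0 else 0.0
    return {"t": float(t), "df": float(df), "p": float(p), "cohens_d": float(d)}
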