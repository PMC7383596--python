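"""Phenomenological grid-cell simulator with independent rate and phase codes.

Each cell's firing rate is the product of a spatial rate code (a Gaussian
of distance to the nearest grid node), a phase code (a circular Gaussian of
the difference between the LFP phase and a location-dependent preferred
phase), the instantaneous baseline frequency (normalizing spikes per
cycle), and running speed.  Spike trains are drawn from an inhomogeneous
Poisson process whose rate is normalized to a fixed session-mean firing
rate.

In *precession* mode the preferred phase advances linearly with the
distance to the nearest node projected onto the direction of travel, so
spikes occur at progressively earlier phases as a field is traversed; in
*locking* mode the preferred phase is pi everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import PhaseSeries, Trajectory

__all__ = [
    "PopulationConfig",
    "GridCellParams",
    "FieldGeometry",
    "RateSeries",
    "SpikeTrain",
    "build_population",
    "nearest_node",
    "rate_code",
    "preferred_phase",
    "phase_factor",
    "assign_field_peaks",
    "simulate_cell",
    "simulate_population",
    "spikes_to_csv",
    "spikes_from_csv",
]


@dataclass
class PopulationConfig:
    """Model constants shared across the simulated population.

    Module scales follow a geometric progression
    ``scale_min * scale_ratio**(m-1)`` -> {30, 42, 58.8, 82.32, 115.248} cm
    with defaults.
    """

    n_cells: int = 200
    n_modules: int = 5
    scale_min: float = 30.0
    scale_ratio: float = 1.4
    mean_rate: float = 2.0  # Hz, session-mean firing rate of every cell
    dt: float = 0.005  # s, simulation time step
    phase_mode: str = "precession"  # or "locking"
    phase_concentration: float = 1.5  # k of the circular-Gaussian phase code
    speed_gain: float = 0.16  # m_v, 1/cm
    heterogeneous: bool = False  # rectified-Normal(1,1) per-field peak rates

    def __post_init__(self):
        if self.n_cells % self.n_modules:
            raise ValueError("n_cells must be divisible by n_modules")
        if self.phase_mode not in ("precession", "locking"):
            raise ValueError("phase_mode must be 'precession' or 'locking'")

    @property
    def scales(self) -> np.ndarray:
        return self.scale_min * self.scale_ratio ** np.arange(self.n_modules)


@dataclass
class GridCellParams:
    """Per-cell grid parameters (lattice geometry and coding constants)."""

    cell_id: int
    module: int
    scale: float  # cm
    offset: np.ndarray  # cm; scalar-like (1,) in 1D, (2,) in 2D
    orientation: float = 0.0  # rad (2D)
    phase_mode: str = "precession"
    k: float = 1.5
    m_v: float = 0.16
    peak_rates: dict | None = None  # field (i[,j]) -> r_c; None = uniform 1

    @property
    def sigma(self) -> float:
        """Field width: scale / 10, cm."""
        return self.scale / 10.0

    def peak_rate(self, nodes: np.ndarray) -> np.ndarray:
        """Per-sample r_c for the given nearest-node integer coordinates."""
        nodes = np.atleast_2d(nodes)
        if self.peak_rates is None:
            return np.ones(len(nodes))
        codes, values = self._encoded_peaks()
        query = _encode_nodes(nodes)
        pos = np.searchsorted(codes, query)
        pos = np.clip(pos, 0, len(codes) - 1)
        hit = codes[pos] == query
        out = np.ones(len(nodes))
        out[hit] = values[pos[hit]]
        return out

    def _encoded_peaks(self):
        cached = getattr(self, "_peak_cache", None)
        if cached is not None:
            return cached
        keys = np.array(list(self.peak_rates.keys()), dtype=np.int64)
        codes = _encode_nodes(np.atleast_2d(keys))
        order = np.argsort(codes)
        self._peak_cache = (codes[order], np.array(list(self.peak_rates.values()))[order])
        return self._peak_cache


@dataclass
class FieldGeometry:
    """Geometry of the nearest grid node for each trajectory sample."""

    distance: np.ndarray  # d >= 0, cm
    displacement: np.ndarray  # d_vec = node - position, cm
    projected: np.ndarray  # d_phi = heading . d_vec, cm
    nodes: np.ndarray  # integer lattice coordinates of the nearest node


@dataclass
class RateSeries:
    """Per-sample rate components of one simulated cell."""

    r_x: np.ndarray  # spatial rate code
    r_phi: np.ndarray  # phase code factor
    r_g: np.ndarray  # r_x * r_phi
    big_r: np.ndarray  # r_g * f * m_v * v
    r_tot: np.ndarray  # normalized rate, Hz
    dt: float


@dataclass
class SpikeTrain:
    """Spike times of one cell plus per-spike lookups on the simulation clock."""

    cell_id: int
    times: np.ndarray  # s, strictly increasing

    @property
    def n(self) -> int:
        return len(self.times)

    def positions(self, trajectory: Trajectory) -> np.ndarray:
        idx = np.clip(np.round(self.times / trajectory.dt).astype(int), 0, trajectory.n - 1)
        return trajectory.positions[idx]

    def speeds(self, trajectory: Trajectory) -> np.ndarray:
        idx = np.clip(np.round(self.times / trajectory.dt).astype(int), 0, trajectory.n - 1)
        return trajectory.speeds[idx]

    def phases(self, phase_series: PhaseSeries) -> np.ndarray:
        return phase_series.phase_at(self.times)


def _encode_nodes(ij: np.ndarray) -> np.ndarray:
    """Pack integer lattice coordinates into sortable int64 keys."""
    ij = np.asarray(ij, dtype=np.int64)
    if ij.shape[1] == 1:
        return ij[:, 0]
    return (ij[:, 0] + 2**20) * 2**22 + (ij[:, 1] + 2**20)


def _lattice_basis(scale: float, orientation: float) -> np.ndarray:
    """Basis vectors of the rhombic lattice (60 degree acute angle), rows."""
    c, s = np.cos(orientation), np.sin(orientation)
    rot = np.array([[c, -s], [s, c]])
    b1 = rot @ np.array([scale, 0.0])
    b2 = rot @ np.array([scale * 0.5, scale * np.sqrt(3) / 2])
    return np.stack([b1, b2])


def nearest_node(
    positions: np.ndarray,
    headings: np.ndarray,
    cell: GridCellParams,
) -> FieldGeometry:
    """Nearest grid node, its distance, and the heading-projected distance.

    Works on arrays of positions (vectorized over trajectory samples).  For
    2D lattices the search rounds the fractional lattice coordinates and
    checks the neighbouring integer combinations, which is exact for this
    geometry.  Where the heading is zero the projected distance is 0.
    """
    positions = np.asarray(positions, float)
    if positions.ndim == 1 or (positions.ndim == 2 and positions.shape[1] == 1):
        x = positions.reshape(-1)
        off = float(np.atleast_1d(cell.offset)[0])
        idx = np.round((x - off) / cell.scale).astype(int)
        node_x = off + idx * cell.scale
        d_vec = node_x - x
        d = np.abs(d_vec)
        sign = np.asarray(headings, float).reshape(-1)
        d_phi = sign * d_vec
        return FieldGeometry(distance=d, displacement=d_vec, projected=d_phi, nodes=idx[:, None])
    basis = _lattice_basis(cell.scale, cell.orientation)
    inv = np.linalg.inv(basis.T)
    rel = positions - np.asarray(cell.offset, float)
    frac = rel @ inv.T  # fractional lattice coordinates
    base = np.rint(frac).astype(np.int64)
    res0 = base @ basis - rel  # displacement to the rounded node
    best_d2 = np.full(len(positions), np.inf)
    best_di = np.zeros(len(positions), dtype=np.int8)
    best_dj = np.zeros(len(positions), dtype=np.int8)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            off = di * basis[0] + dj * basis[1]
            dx = res0[:, 0] + off[0]
            dy = res0[:, 1] + off[1]
            d2 = dx * dx + dy * dy
            better = d2 < best_d2
            np.copyto(best_d2, d2, where=better)
            best_di[better] = di
            best_dj[better] = dj
    best_ij = base + np.stack([best_di, best_dj], axis=1)
    d_vec = best_ij @ basis - rel
    d = np.sqrt(best_d2)
    head = np.asarray(headings, float)
    d_phi = np.einsum("ij,ij->i", head, d_vec)
    return FieldGeometry(distance=d, displacement=d_vec, projected=d_phi, nodes=best_ij)


def rate_code(geometry: FieldGeometry, cell: GridCellParams) -> np.ndarray:
    """Spatial rate code: r_x = r_c * exp(-d^2 / (2 sigma^2))."""
    r_c = cell.peak_rate(geometry.nodes)
    return r_c * np.exp(-(geometry.distance**2) / (2 * cell.sigma**2))


def preferred_phase(geometry: FieldGeometry, cell: GridCellParams) -> np.ndarray:
    """Location-dependent preferred firing phase, wrapped to (-pi, pi].

    Precession: phi = 2*pi*(d_phi / scale + 1/2), so the phase sweeps a
    full cycle earlier as a field is traversed along the travel direction
    and equals pi at the field centre.  Locking: phi = pi everywhere.
    """
    if cell.phase_mode == "locking":
        return np.full(np.shape(geometry.distance), np.pi)
    phi = 2 * np.pi * (geometry.projected / cell.scale + 0.5)
    wrapped = np.angle(np.exp(1j * phi))
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def phase_factor(pref_phase: np.ndarray, lfp_phase: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Phase code: r_phi = exp(k * cos(phi - theta))."""
    return np.exp(k * np.cos(pref_phase - lfp_phase))


def _enumerate_nodes(cell: GridCellParams, trajectory: Trajectory) -> np.ndarray:
    """Integer coordinates of lattice nodes within reach of the environment."""
    margin = 2 * cell.scale
    if trajectory.ndim == 1:
        off = float(np.atleast_1d(cell.offset)[0])
        lo = int(np.floor((-margin - off) / cell.scale))
        hi = int(np.ceil((trajectory.extent + margin - off) / cell.scale))
        return np.arange(lo, hi + 1)[:, None]
    basis = _lattice_basis(cell.scale, cell.orientation)
    inv = np.linalg.inv(basis.T)
    corners = np.array(
        [
            [-margin, -margin],
            [trajectory.extent + margin, -margin],
            [-margin, trajectory.extent + margin],
            [trajectory.extent + margin, trajectory.extent + margin],
        ]
    )
    frac = (corners - cell.offset) @ inv.T
    lo = np.floor(frac.min(axis=0)).astype(int) - 1
    hi = np.ceil(frac.max(axis=0)).astype(int) + 1
    ii, jj = np.meshgrid(np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij")
    ij = np.stack([ii.ravel(), jj.ravel()], axis=1)
    nodes = ij @ basis + cell.offset
    inside = np.all((nodes >= -margin) & (nodes <= trajectory.extent + margin), axis=1)
    return ij[inside]


def assign_field_peaks(
    cell: GridCellParams,
    trajectory: Trajectory,
    heterogeneous: bool,
    seed: int | None = None,
) -> GridCellParams:
    """Assign per-field peak firing rates, fixed for the session.

    Uniform mode sets every r_c to 1; heterogeneous mode draws each field's
    peak independently from a Normal(1, 1) rectified at zero, emulating the
    stable in-field rate differences observed in vivo.
    """
    cell._peak_cache = None
    if not heterogeneous:
        cell.peak_rates = None
        return cell
    rng = np.random.default_rng(seed)
    nodes = _enumerate_nodes(cell, trajectory)
    draws = np.maximum(0.0, rng.normal(1.0, 1.0, size=len(nodes)))
    cell.peak_rates = {tuple(n): float(v) for n, v in zip(nodes, draws)}
    return cell


def build_population(
    config: PopulationConfig,
    trajectory: Trajectory,
    seed: int | None = None,
) -> list[GridCellParams]:
    """Create the population's per-cell parameters.

    Cells are divided equally among modules; spatial phase offsets are
    uniform over one lattice period (1D) or the rhombic unit cell (2D);
    per-module orientation is 0 by default.
    """
    rng = np.random.default_rng(seed)
    per_module = config.n_cells // config.n_modules
    cells = []
    for m, scale in enumerate(config.scales):
        for j in range(per_module):
            cid = m * per_module + j
            if trajectory.ndim == 1:
                offset = np.array([rng.uniform(0, scale)])
            else:
                frac = rng.uniform(0, 1, size=2)
                offset = frac @ _lattice_basis(scale, 0.0)
            cell = GridCellParams(
                cell_id=cid,
                module=m,
                scale=float(scale),
                offset=offset,
                orientation=0.0,
                phase_mode=config.phase_mode,
                k=config.phase_concentration,
                m_v=config.speed_gain,
            )
            assign_field_peaks(
                cell,
                trajectory,
                config.heterogeneous,
                seed=rng.integers(2**31 - 1),
            )
            cells.append(cell)
    return cells


def cell_rates(
    trajectory: Trajectory,
    phase_series: PhaseSeries,
    cell: GridCellParams,
    mean_rate: float = 2.0,
) -> RateSeries:
    """Deterministic rate components of one cell along the trajectory.

    R(t) = r_x * r_phi * f(t) * m_v * v(t); r_tot is R normalized so the
    expected session-mean firing rate equals ``mean_rate`` (the
    normalization integral runs over the full session, including
    sub-threshold-speed samples).
    """
    n = min(trajectory.n, phase_series.n)
    pos = trajectory.positions[:n]
    head = trajectory.headings[:n]
    geom = nearest_node(pos, head, cell)
    speeds = trajectory.speeds[:n]
    d_phi = np.where(speeds > 0, geom.projected, 0.0)
    geom = FieldGeometry(geom.distance, geom.displacement, d_phi, geom.nodes)
    r_x = rate_code(geom, cell)
    phi = preferred_phase(geom, cell)
    # spikes are jittered uniformly within each bin, so drive the phase
    # code with the mid-bin phase (circular midpoint of adjacent samples)
    # to keep spike phases unbiased around the preferred phase
    z = np.exp(1j * phase_series.phase[:n])
    z_next = np.exp(1j * phase_series.phase[1 : n + 1])
    if len(z_next) < n:
        z_next = np.append(z_next, z[-1])
    mid = np.angle(z + z_next)
    r_phi = phase_factor(phi, mid, cell.k)
    r_g = r_x * r_phi
    big_r = r_g * phase_series.frequency[:n] * cell.m_v * speeds
    total = big_r.sum() * trajectory.dt
    if total <= 0:
        raise ValueError("rate integral is zero (agent never moves?)")
    duration = n * trajectory.dt
    r_tot = mean_rate * duration * big_r / total
    return RateSeries(r_x=r_x, r_phi=r_phi, r_g=r_g, big_r=big_r, r_tot=r_tot, dt=trajectory.dt)


def simulate_cell(
    trajectory: Trajectory,
    phase_series: PhaseSeries,
    cell: GridCellParams,
    seed: int | None = None,
    mean_rate: float = 2.0,
    return_rates: bool = False,
):
    """Draw one cell's spike train from an inhomogeneous Poisson process.

    Spikes are drawn per 5 ms bin with mean r_tot * dt and jittered
    uniformly within the bin (statistically equivalent to thinning at this
    resolution).
    """
    rates = cell_rates(trajectory, phase_series, cell, mean_rate=mean_rate)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates.r_tot * rates.dt)
    idx = np.repeat(np.arange(len(counts)), counts)
    times = (idx + rng.uniform(0, 1, size=len(idx))) * rates.dt
    times.sort()
    train = SpikeTrain(cell_id=cell.cell_id, times=times)
    if return_rates:
        return rates, train
    return train


def simulate_population(
    trajectory: Trajectory,
    phase_series: PhaseSeries,
    cells: list[GridCellParams],
    seed: int | None = None,
    mean_rate: float = 2.0,
) -> list[SpikeTrain]:
    """Simulate spike trains for every cell (seeds derived per cell)."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(cells))
    return [
        simulate_cell(trajectory, phase_series, cell, seed=child[i], mean_rate=mean_rate)
        for i, cell in enumerate(cells)
    ]


def spikes_to_csv(trains: list[SpikeTrain], path) -> None:
    rows = [(tr.cell_id, t) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["cell_id", "t_s"]).to_csv(path, index=False)


def spikes_from_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(cell_id=int(cid), times=np.sort(grp["t_s"].to_numpy(float)))
        for cid, grp in df.groupby("cell_id")
    ]
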