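import numpy as np
import pytest
from scipy import stats

from phasegrid import grid_model as gm
from phasegrid import signals as sg


@pytest.fixture(scope="module")
def cell_1d():
    return gm.GridCellParams(cell_id=0, module=0, scale=30.0, offset=np.array([0.0]))


@pytest.fixture(scope="module")
def cell_2d():
    return gm.GridCellParams(cell_id=0, module=2, scale=58.8, offset=np.array([7.3, 21.2]))


class TestNearestNode:
    def test_on_node(self, cell_1d):
        g = gm.nearest_node(np.array([30.0]), np.array([1.0]), cell_1d)
        assert g.distance[0] == 0.0
        assert g.projected[0] == 0.0

    def test_1d_projection_sign(self, cell_1d):
        g = gm.nearest_node(np.array([25.0]), np.array([1.0]), cell_1d)
        assert g.distance[0] == 5.0
        assert g.projected[0] == 5.0
        g = gm.nearest_node(np.array([25.0]), np.array([-1.0]), cell_1d)
        assert g.projected[0] == -5.0

    def test_2d_matches_brute_force(self, cell_2d):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-100, 200, size=(500, 2))
        head = rng.normal(size=(500, 2))
        head /= np.linalg.norm(head, axis=1)[:, None]
        g = gm.nearest_node(pos, head, cell_2d)
        basis = gm._lattice_basis(cell_2d.scale, 0.0)
        ii, jj = np.meshgrid(np.arange(-8, 10), np.arange(-8, 10), indexing="ij")
        nodes = np.stack([ii.ravel(), jj.ravel()], axis=1) @ basis + cell_2d.offset
        brute = np.sqrt(((pos[:, None, :] - nodes[None]) ** 2).sum(-1)).min(1)
        np.testing.assert_allclose(g.distance, brute, atol=1e-9)

    def test_deep_hole_bound(self, cell_2d):
        """Max distance to the nearest node of a 60-degree lattice is s/sqrt(3)."""
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 200, size=(20_000, 2))
        g = gm.nearest_node(pos, np.zeros((len(pos), 2)), cell_2d)
        assert g.distance.max() <= cell_2d.scale / np.sqrt(3) + 1e-9
        assert g.distance.max() > 0.95 * cell_2d.scale / np.sqrt(3)

    def test_projection_bounded_by_distance(self, cell_2d):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 100, size=(200, 2))
        head = rng.normal(size=(200, 2))
        head /= np.linalg.norm(head, axis=1)[:, None]
        g = gm.nearest_node(pos, head, cell_2d)
        assert np.all(np.abs(g.projected) <= g.distance + 1e-9)


class TestRateCode:
    @pytest.mark.parametrize(
        "d_over_sigma,expected",
        [(0.0, 1.0), (1.0, np.exp(-0.5)), (3.0, np.exp(-4.5))],
    )
    def test_gaussian_profile(self, cell_1d, d_over_sigma, expected):
        d = d_over_sigma * cell_1d.sigma
        geom = gm.FieldGeometry(
            distance=np.array([d]), displacement=np.array([d]),
            projected=np.array([d]), nodes=np.array([[0]]),
        )
        np.testing.assert_allclose(gm.rate_code(geom, cell_1d), [expected], rtol=1e-12)

    def test_sigma_is_scale_over_ten(self, cell_2d):
        assert cell_2d.sigma == cell_2d.scale / 10.0


class TestPreferredPhase:
    def _geom(self, d_phi):
        return gm.FieldGeometry(
            distance=np.abs(np.atleast_1d(d_phi)),
            displacement=np.atleast_1d(d_phi),
            projected=np.atleast_1d(d_phi),
            nodes=np.zeros((np.size(d_phi), 1), dtype=int),
        )

    def test_field_center_fires_at_pi(self, cell_1d):
        phi = gm.preferred_phase(self._geom(0.0), cell_1d)
        np.testing.assert_allclose(phi, [np.pi])

    def test_quarter_scale_past_center(self, cell_1d):
        phi = gm.preferred_phase(self._geom(-cell_1d.scale / 4), cell_1d)
        np.testing.assert_allclose(phi, [np.pi / 2])

    def test_traversal_sweeps_earlier_phases(self, cell_1d):
        """Across a field, the (unwrapped) preferred phase falls by 2*pi."""
        d_phi = np.linspace(cell_1d.scale / 2 - 1e-9, -cell_1d.scale / 2 + 1e-9, 101)
        phi = gm.preferred_phase(self._geom(d_phi), cell_1d)
        unwrapped = np.unwrap(phi)
        assert np.all(np.diff(unwrapped) < 0)
        assert unwrapped[0] - unwrapped[-1] == pytest.approx(2 * np.pi, rel=1e-6)

    def test_locking_mode_constant_pi(self, cell_1d):
        locked = gm.GridCellParams(0, 0, 30.0, np.array([0.0]), phase_mode="locking")
        phi = gm.preferred_phase(self._geom(np.linspace(-15, 15, 7)), locked)
        np.testing.assert_allclose(phi, np.pi)


class TestPhaseFactor:
    def test_values(self):
        assert gm.phase_factor(0.0, 0.0, 1.5) == pytest.approx(np.exp(1.5))
        assert gm.phase_factor(np.pi, 0.0, 1.5) == pytest.approx(np.exp(-1.5))

    def test_circular_spread_at_k(self):
        """Von Mises k=1.5 gives angular deviation ~0.9 rad."""
        from scipy.special import i0, i1

        r = i1(1.5) / i0(1.5)
        assert np.sqrt(2 * (1 - r)) == pytest.approx(0.90, abs=0.01)


class TestFieldPeaks:
    def test_uniform_mode(self, traj2d, cell_2d):
        cell = gm.assign_field_peaks(cell_2d, traj2d, heterogeneous=False)
        assert cell.peak_rates is None
        geom = gm.nearest_node(np.array([[50.0, 50.0]]), np.zeros((1, 2)), cell)
        np.testing.assert_allclose(cell.peak_rate(geom.nodes), [1.0])

    def test_rectified_normal_mean(self, traj1d):
        """Mean peak over many fields ~ E[max(0, N(1,1))] ~ 1.083."""
        cell = gm.GridCellParams(0, 0, 30.0, np.array([0.0]))
        # oracle by quadrature: E[max(0, X)], X ~ N(1, 1)
        oracle = 1.0 * stats.norm.cdf(1.0) + stats.norm.pdf(1.0)
        peaks = []
        for seed in range(30):
            c = gm.assign_field_peaks(cell, traj1d, heterogeneous=True, seed=seed)
            peaks.extend(c.peak_rates.values())
        assert np.mean(peaks) == pytest.approx(oracle, abs=0.05)

    def test_deterministic_under_seed(self, traj1d):
        cell = gm.GridCellParams(0, 0, 30.0, np.array([0.0]))
        a = dict(gm.assign_field_peaks(cell, traj1d, True, seed=5).peak_rates)
        b = dict(gm.assign_field_peaks(cell, traj1d, True, seed=5).peak_rates)
        assert a == b


class TestSimulateCell:
    def test_mean_rate_normalization(self, traj2d, phase_bb, cells40):
        counts = [
            gm.simulate_cell(traj2d, phase_bb, cells40[i], seed=50 + i).n
            for i in range(0, 40, 4)
        ]
        mean_rate = np.mean(counts) / traj2d.duration
        # r_bar = 2 Hz +- 3 SE
        se = np.sqrt(np.mean(counts)) / traj2d.duration / np.sqrt(len(counts))
        assert abs(mean_rate - 2.0) < 3 * max(se, 0.02)

    def test_deterministic_under_seed(self, traj1d, cells40):
        ps = sg.preprocess_lfp(sg.gen_broadband_lfp(121.1, 512, 8, 8))
        a = gm.simulate_cell(traj1d, ps, cells40[0], seed=1)
        b = gm.simulate_cell(traj1d, ps, cells40[0], seed=1)
        np.testing.assert_array_equal(a.times, b.times)

    def test_rate_proportional_to_speed(self, phase_bb):
        """R ~ v: a stationary agent emits no expected spikes."""
        n = phase_bb.n
        speeds = np.zeros(n)
        speeds[n // 2 : n // 2 + 2000] = 10.0
        pos = np.concatenate([[0.0], np.cumsum(speeds[:-1]) * 0.005])
        traj = sg.Trajectory(0.005, pos, speeds, np.ones(n), extent=float(pos.max()) + 1)
        cell = gm.GridCellParams(0, 0, 30.0, np.array([0.0]))
        rates = gm.cell_rates(traj, phase_bb, cell)
        moving = speeds > 0
        assert rates.r_tot[~moving].sum() == 0.0
        assert rates.r_tot[moving].sum() > 0

    def test_zero_rate_integral_raises(self, phase_bb):
        n = phase_bb.n
        traj = sg.Trajectory(0.005, np.zeros(n), np.zeros(n), np.ones(n), extent=10.0)
        cell = gm.GridCellParams(0, 0, 30.0, np.array([0.0]))
        with pytest.raises(ValueError):
            gm.cell_rates(traj, phase_bb, cell)

    def test_expected_count_oracle(self):
        """Empirical spike counts per spatial bin match the rate integral.

        Chi-square goodness of fit of pooled counts over seeds against the
        deterministic expectation integral(r_tot dt) per 2-cm bin.
        """
        traj = sg.gen_trajectory_1d(30.0, seed=7)
        ps = sg.preprocess_lfp(sg.gen_broadband_lfp(31.1, 512, 8, 8))
        cell = gm.GridCellParams(0, 0, 30.0, np.array([0.0]))
        rates = gm.cell_rates(traj, ps, cell)
        nb = int(np.ceil(traj.extent / 2.0))
        bins = np.clip((traj.positions / 2.0).astype(int), 0, nb - 1)
        expected_1 = np.bincount(bins, weights=rates.r_tot * traj.dt, minlength=nb)
        n_seeds = 400
        observed = np.zeros(nb)
        for seed in range(n_seeds):
            tr = gm.simulate_cell(traj, ps, cell, seed=1000 + seed)
            idx = np.clip(np.round(tr.times / traj.dt).astype(int), 0, traj.n - 1)
            observed += np.bincount(bins[idx], minlength=nb)
        expected = expected_1 * n_seeds
        keep = expected >= 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        dof = keep.sum() - 1
        p = stats.chi2.sf(chi2, dof)
        assert p > 0.01

    def test_precession_negative_phase_distance_correlation(self, traj2d, phase8, cells40):
        from phasegrid import circstats, spatial, temporal

        tr = gm.simulate_cell(traj2d, phase8, cells40[0], seed=9)
        rm = spatial.rate_map(tr.times, traj2d)
        fs = spatial.detect_fields(rm)
        pr = temporal.precession(tr.times, traj2d, fs, phase8, n_shuffles=100, seed=1, n_grid=201)
        assert pr.rho < 0

    def test_phase_slope_speed_invariance(self, traj2d, phase8, cells40):
        """Precession depends on distance, not on running speed.

        Pools in-field spikes across one module; the phase-vs-normalized-
        distance slope from slow traversals matches that from fast ones.
        """
        from phasegrid import circstats, spatial, temporal

        dist_all, speed_all, phase_all = [], [], []
        for ci in range(8, 16):  # module 1
            tr = gm.simulate_cell(traj2d, phase8, cells40[ci], seed=11 + ci)
            rm = spatial.rate_map(tr.times, traj2d)
            fs = spatial.detect_fields(rm)
            dist, keep = temporal.field_traversal_distances(tr.times, traj2d, fs)
            dist_all.append(dist[keep])
            speed_all.append(tr.speeds(traj2d)[keep])
            phase_all.append(tr.phases(phase8)[keep])
        dist = np.concatenate(dist_all)
        speed = np.concatenate(speed_all)
        phase = np.concatenate(phase_all)
        slopes = []
        for lo, hi in [(5, 15), (15, 30)]:
            sel = (speed >= lo) & (speed < hi)
            res = circstats.circ_linear_corr(phase[sel], dist[sel], n_shuffles=0, n_grid=401)
            slopes.append(res.slope)
        assert slopes[0] < 0 and slopes[1] < 0
        assert abs(slopes[0] - slopes[1]) < 0.3 * max(abs(slopes[0]), abs(slopes[1]))


class TestPopulation:
    def test_module_scales(self):
        cfg = gm.PopulationConfig()
        np.testing.assert_allclose(cfg.scales, [30.0, 42.0, 58.8, 82.32, 115.248])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            gm.PopulationConfig(n_cells=7, n_modules=5)
        with pytest.raises(ValueError):
            gm.PopulationConfig(phase_mode="wiggle")

    def test_locking_population_mean_phase(self, traj2d, phase_bb, trains40_locking):
        from phasegrid import circstats

        phases = np.concatenate([t.phases(phase_bb) for t in trains40_locking])
        r, mu = circstats.resultant(phases)
        assert abs(np.angle(np.exp(1j * (mu - np.pi)))) < 0.05

    def test_spike_csv_round_trip(self, tmp_path, trains40):
        p = tmp_path / "spikes.csv"
        gm.spikes_to_csv(trains40[:3], p)
        back = gm.spikes_from_csv(p)
        assert [t.cell_id for t in back] == [t.cell_id for t in trains40[:3]]
        np.testing.assert_allclose(back[0].times, trains40[0].times, atol=1e-9)
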