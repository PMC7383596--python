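import numpy as np
import pytest

from phasegrid import decoding as dc
from phasegrid import grid_model as gm
from phasegrid import signals as sg


@pytest.fixture(scope="module")
def session(traj2d, phase_bb, cells40, trains40):
    cycles = sg.segment_cycles(phase_bb, traj2d)
    pop = dc.population_vectors(trains40, cycles, phase_bb)
    expected = dc.expected_rate_maps(cells40, traj2d)
    return cycles, pop, expected


class TestPopulationVectors:
    def test_phase_bins_have_equal_pooled_counts(self, session):
        _, pop, _ = session
        totals = pop.counts_phase.sum(axis=(0, 1))
        assert totals.max() - totals.min() <= 0.02 * totals.mean() + pop.n_phase_bins

    def test_phase_bins_partition_cycle_counts(self, session):
        _, pop, _ = session
        np.testing.assert_array_equal(pop.counts_phase.sum(axis=2), pop.counts)

    def test_uniform_phase_density_gives_72_degree_bins(self):
        """With uniform spike phases the quantile edges fall 2*pi/5 apart."""

        class _FakeTrain:
            def __init__(self, times):
                self.times = times
                self.n = len(times)

        n = 40_000
        rng = np.random.default_rng(0)
        phase = np.angle(np.exp(1j * np.cumsum(np.full(n, 2 * np.pi * 8 * 0.005))))
        ps = sg.PhaseSeries(phase, np.full(n, 8.0), 0.005)
        traj = sg.Trajectory(0.005, np.cumsum(np.full(n, 0.05)), np.full(n, 10.0), np.ones(n), extent=2000.0)
        cycles = sg.segment_cycles(ps, traj)
        trains = [_FakeTrain(np.sort(rng.uniform(1, (n - 200) * 0.005, 20_000)))]
        pop = dc.population_vectors(trains, cycles, ps)
        widths = np.diff(pop.phase_edges)
        np.testing.assert_allclose(widths, 2 * np.pi / 5, atol=0.1)


class TestDecodeSpeed:
    def test_exactly_linear_counts_give_zero_error(self, session):
        cycles, pop, _ = session
        move = pop.movement
        fake = pop.counts.copy()
        fake[:, :] = 0
        fake[:, 0] = np.round(10 * cycles.mean_speeds).astype(int)
        pop2 = dc.PopulationVectors(
            counts=fake, counts_phase=pop.counts_phase, phase_edges=pop.phase_edges,
            mean_cycle_s=pop.mean_cycle_s, mean_bin_s=pop.mean_bin_s, cycles=cycles,
            sample_bins=pop.sample_bins,
        )
        res = dc.decode_speed(pop2)
        assert res.errors.max() < 0.1

    def test_simulated_population_decodes_speed(self, session):
        _, pop, _ = session
        res = dc.decode_speed(pop)
        # 40 cells: noisier than the full population but clearly informative
        assert res.fraction_within(5.0) > 0.5
        assert res.extra["slope"] > 0


class TestDecodeLocationRate:
    def test_toy_two_location_oracle(self):
        """Argmax matches a hand-computed Poisson log-likelihood."""
        lam = np.array([[2.0, 0.1], [0.1, 2.0]])  # (cells, locations)
        k = np.array([[3.0, 0.0]])  # cycle observed counts per cell
        ll = dc._poisson_loglik(k, lam.T)
        manual = [
            sum(k[0][c] * np.log(lam[c, b]) - lam[c, b] for c in range(2))
            for b in range(2)
        ]
        np.testing.assert_allclose(ll[0], manual, rtol=1e-12)
        assert np.argmax(ll[0]) == 0

    def test_decoding_at_expectation_returns_generating_bin(self, session):
        _, pop, expected = session
        mu = expected.rates * pop.mean_cycle_s
        b = 1234  # arbitrary location bin
        k = mu[:, b][None, :]
        ll = dc._poisson_loglik(k, mu.T)
        assert np.argmax(ll[0]) == b

    def test_log_domain_matches_product_form(self):
        """Likelihood ratios equal the explicit Poisson product to 1e-9."""
        from scipy.stats import poisson

        rng = np.random.default_rng(1)
        lam = rng.uniform(0.1, 3.0, size=(4, 6))  # (cells, bins)
        k = rng.poisson(1.0, size=(3, 4)).astype(float)
        ll = dc._poisson_loglik(k, lam.T)
        for i in range(3):
            for b in range(5):
                explicit = np.prod(poisson.pmf(k[i], lam[:, b])) / np.prod(
                    poisson.pmf(k[i], lam[:, b + 1])
                )
                log_ratio = ll[i, b] - ll[i, b + 1]
                np.testing.assert_allclose(np.exp(log_ratio), explicit, rtol=1e-9)

    def test_brute_force_equivalence_on_simulation(self, session, traj2d):
        """Vectorized argmax equals a per-cycle brute-force scan."""
        _, pop, expected = session
        res = dc.decode_location_rate(pop, expected, traj2d)
        move = pop.movement
        counts = pop.counts[move].astype(float)
        mu = (expected.rates * pop.mean_cycle_s).T
        logmu = np.log(np.maximum(mu, 1e-9))
        for i in range(0, move.sum(), 250):
            scores = [counts[i] @ logmu[b] - mu[b].sum() for b in range(mu.shape[0])]
            assert np.argmax(scores) == np.argmax(
                dc._poisson_loglik(counts[i : i + 1], mu)[0]
            )

    def test_median_error_small_2d(self, session, traj2d):
        _, pop, expected = session
        res = dc.decode_location_rate(pop, expected, traj2d)
        # 40 cells: error larger than the 200-cell case but still local
        assert res.median_error < 10.0

    def test_error_decreases_with_population_size(self, traj2d, phase_bb):
        medians = []
        for n_cells in (15, 60):
            cfg = gm.PopulationConfig(n_cells=n_cells, n_modules=5)
            cells = gm.build_population(cfg, traj2d, seed=200)
            trains = gm.simulate_population(traj2d, phase_bb, cells, seed=201)
            cycles = sg.segment_cycles(phase_bb, traj2d)
            pop = dc.population_vectors(trains, cycles, phase_bb)
            expected = dc.expected_rate_maps(cells, traj2d)
            medians.append(dc.decode_location_rate(pop, expected, traj2d).median_error)
        assert medians[1] < medians[0]


class TestDecodeCycle:
    def test_self_expectation_decodes_own_cycle(self, session, traj2d, phase_bb, cells40):
        _, pop, _ = session
        mu = dc.expected_cycle_counts(cells40, traj2d, phase_bb, pop)
        move = pop.movement
        k = mu[move][:50]
        ll = dc._poisson_loglik(
            k.reshape(50, -1), mu[move].reshape(move.sum(), -1)
        )
        hits = np.mean(np.argmax(ll, axis=1) == np.arange(50))
        assert hits > 0.9

    def test_phase_information_reduces_catastrophic_errors_1d(self):
        """Rate+phase cycle decoding beats rate-only on the long track."""
        traj = sg.gen_trajectory_1d(300.0, seed=301)
        ps = sg.preprocess_lfp(sg.gen_broadband_lfp(301.1, 512, 2, 20, seed=302))
        cfg = gm.PopulationConfig(n_cells=60, n_modules=5)
        cells = gm.build_population(cfg, traj, seed=303)
        trains = gm.simulate_population(traj, ps, cells, seed=304)
        cycles = sg.segment_cycles(ps, traj)
        pop = dc.population_vectors(trains, cycles, ps)
        mu_gp = dc.expected_cycle_counts(cells, traj, ps, pop, mode="rate+phase")
        mu_r = dc.expected_cycle_counts(cells, traj, ps, pop, mode="rate")
        res_gp = dc.decode_cycle(pop, mu_gp, mode="rate+phase")
        res_r = dc.decode_cycle(pop, mu_r, mode="rate")
        assert res_gp.catastrophic_rate <= res_r.catastrophic_rate


class TestDecodeDirection:
    def test_collinear_east_sequence(self):
        """Decoded locations marching east give direction 0."""
        xs = np.array([10.0, 12.0, 14.0, 16.0, 18.0])
        from scipy import stats

        slope_x = stats.linregress(np.arange(5.0), xs).slope
        slope_y = stats.linregress(np.arange(5.0), np.zeros(5)).slope
        assert np.arctan2(slope_y, slope_x) == pytest.approx(0.0)

    def test_direction_better_than_chance_with_precession(self, session, traj2d):
        _, pop, expected = session
        res = dc.decode_direction(pop, expected, traj2d)
        # chance level for +-30 deg is 1/6; with only 40 cells (~2 spikes
        # per phase bin) the sequence signal is weak but clearly present
        assert res.extra["fraction_within_tol"] > 0.2


class TestDecodeCycleVariable:
    def test_frequency_encoded_variable_recovered(self, session, phase_bb):
        _, pop, _ = session
        z = (phase_bb.frequency - 2.0) / 18.0
        res = dc.decode_cycle_variable(pop, z)
        assert res.extra["fraction_within_tol"] > 0.7

    def test_independent_variable_at_chance(self, session, phase_bb):
        _, pop, _ = session
        rng = np.random.default_rng(7)
        smooth = np.convolve(rng.normal(size=phase_bb.n), np.ones(400) / 400, mode="same")
        z = (smooth - smooth.min()) / np.ptp(smooth)
        res = dc.decode_cycle_variable(pop, z)
        chance = dc.decode_cycle_variable(pop, z[::-1].copy())
        assert res.extra["fraction_within_tol"] < 0.5

    def test_constant_durations_rejected(self, session, phase_bb):
        cycles, pop, _ = session
        const = dc.PopulationVectors(
            counts=pop.counts, counts_phase=pop.counts_phase, phase_edges=pop.phase_edges,
            mean_cycle_s=pop.mean_cycle_s, mean_bin_s=pop.mean_bin_s,
            cycles=sg.CycleSegmentation(
                starts=cycles.starts, ends=cycles.ends,
                durations=np.full_like(cycles.durations, 0.125),
                mean_speeds=cycles.mean_speeds, mean_positions=cycles.mean_positions,
                movement=cycles.movement, dt=cycles.dt,
            ),
            sample_bins=pop.sample_bins,
        )
        with pytest.raises(ValueError):
            dc.decode_cycle_variable(const, np.zeros(100_000))


class TestInformedVsNaive:
    def test_informed_decoder_beats_naive_with_heterogeneous_fields(self):
        """Knowing the true per-field peak rates reduces catastrophic errors."""
        traj = sg.gen_trajectory_1d(300.0, seed=401)
        ps = sg.preprocess_lfp(sg.gen_broadband_lfp(301.1, 512, 2, 20, seed=402))
        cfg = gm.PopulationConfig(n_cells=60, n_modules=5, heterogeneous=True)
        cells = gm.build_population(cfg, traj, seed=403)
        trains = gm.simulate_population(traj, ps, cells, seed=404)
        cycles = sg.segment_cycles(ps, traj)
        pop = dc.population_vectors(trains, cycles, ps)
        informed = dc.expected_rate_maps(cells, traj, informed=True)
        naive = dc.expected_rate_maps(cells, traj, informed=False)
        res_i = dc.decode_location_rate(pop, informed, traj)
        res_n = dc.decode_location_rate(pop, naive, traj)
        assert res_i.catastrophic_rate <= res_n.catastrophic_rate
        assert res_i.median_error <= res_n.median_error + 0.5
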