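"""Transmitter: gene kinetics, storage pools, release and arrival convolution."""

import numpy as np
import pytest
from scipy import integrate
from scipy.integrate import solve_ivp
from scipy.special import expit

from phytomc import (
    ChannelParams,
    ConfigurationError,
    EmissionProfile,
    GeneNode,
    PoolParams,
    PoolState,
    arrived_mass_profile,
    emission_rate,
    gene_expression_rate,
    hit_density,
    hit_probability,
    simulate_pools,
    synthesis_timeseries,
    update_pools,
)


class TestGeneExpressionRate:
    def test_sigmoid_midpoint(self):
        node = GeneNode("x", basal_rate=0.0, max_rate=1.0, decay_rate=0.1,
                        expression_level=0.0)
        assert gene_expression_rate(node, {}) == pytest.approx(0.5)

    def test_saturated_fixed_point(self):
        # a_x0 -> +inf saturates the sigmoid; G* = eta1/eta2 is then a zero of the rate
        node = GeneNode("x", basal_rate=500.0, max_rate=1.0, decay_rate=0.1,
                        expression_level=10.0)
        assert gene_expression_rate(node, {}) == pytest.approx(0.0, abs=1e-12)

    def test_missing_regulator_is_config_error(self):
        node = GeneNode("x", regulator_weights={"y": 1.0})
        with pytest.raises(ConfigurationError):
            gene_expression_rate(node, {})

    def test_nan_level_rejected(self):
        node = GeneNode("x", regulator_weights={"y": 1.0})
        with pytest.raises(ValueError):
            gene_expression_rate(node, {"y": float("nan")})

    def test_no_autoregulation(self):
        with pytest.raises(ConfigurationError):
            GeneNode("x", regulator_weights={"x": 1.0})

    def test_monotone_in_positive_regulator_level(self):
        node = GeneNode("x", regulator_weights={"y": 2.0})
        rates = [gene_expression_rate(node, {"y": g}) for g in np.linspace(-3, 3, 13)]
        assert np.all(np.diff(rates) > 0)


class TestSynthesisTimeseries:
    def test_no_production(self):
        nodes = [GeneNode("x", max_rate=0.0, decay_rate=0.1)]
        traj = synthesis_timeseries(nodes, np.linspace(0, 5, 11))
        np.testing.assert_array_equal(traj.synthesis, 0.0)

    def test_trajectory_matches_independent_integrator(self):
        node = GeneNode("x", basal_rate=0.0, max_rate=1.0, decay_rate=0.1)
        t = np.linspace(0, 2, 21)
        traj = synthesis_timeseries([node], t)
        sol = solve_ivp(
            lambda _, G: expit(0.0) * 1.0 - 0.1 * G, (0, 2), [0.0],
            rtol=1e-11, atol=1e-13, dense_output=True,
        )
        np.testing.assert_allclose(traj.levels[0], sol.sol(t)[0], rtol=1e-6, atol=1e-10)

    def test_fixed_point_gives_constant_rate(self):
        # at G* the drift vanishes, so xi stays 0 along the grid
        g_star = 1.0 * expit(0.8) / 0.1
        node = GeneNode("x", basal_rate=0.8, max_rate=1.0, decay_rate=0.1,
                        expression_level=g_star)
        traj = synthesis_timeseries([node], np.linspace(0, 10, 21))
        np.testing.assert_allclose(traj.synthesis[0], 0.0, atol=1e-12)

    def test_mutual_activation_matches_half_step_reintegration(self):
        nodes = [
            GeneNode("x", basal_rate=-1.0, max_rate=1.0, decay_rate=0.2,
                     regulator_weights={"y": 2.0}),
            GeneNode("y", basal_rate=-1.0, max_rate=1.0, decay_rate=0.2,
                     regulator_weights={"x": 2.0}),
        ]
        coarse_grid = np.linspace(0, 5, 11)
        fine_grid = np.linspace(0, 5, 21)  # halves every internal step
        coarse = synthesis_timeseries(nodes, coarse_grid)
        fine = synthesis_timeseries(nodes, fine_grid)
        np.testing.assert_allclose(
            coarse.levels, fine.levels[:, ::2], rtol=1e-5, atol=1e-12
        )

    def test_bad_grid_rejected(self):
        node = GeneNode("x")
        with pytest.raises(ConfigurationError):
            synthesis_timeseries([node], [1.0, 2.0])  # does not start at 0


class TestPools:
    def test_steady_state_identities(self):
        pp = PoolParams(eta=0.5, u_a=0.1, u_l=0.1, u_g=0.05)
        xi = 0.01
        state = PoolState()
        # 20 time constants of the slowest pool
        for _ in range(400):
            state = update_pools(state, xi, pp, 1.0)
        assert state.Q_a == pytest.approx(pp.eta * xi / pp.u_a, rel=1e-8)
        assert state.Q_l == pytest.approx((1 - pp.eta) * xi / pp.u_l, rel=1e-8)
        assert emission_rate(state, pp) == pytest.approx(xi, rel=1e-8)

    def test_pure_decay_closed_form(self):
        pp = PoolParams(eta=0.5, u_a=0.25, u_l=0.1, u_g=0.05)
        state = PoolState(Q_a=1.0)
        state = update_pools(state, 0.0, pp, 3.0)
        assert state.Q_a == pytest.approx(np.exp(-0.25 * 3.0), rel=1e-12)

    def test_conservation_audit(self):
        pp = PoolParams()
        traj = simulate_pools(np.full(101, 0.01), np.linspace(0, 10, 101), pp)
        produced = traj.produced[-1]
        assert produced == pytest.approx(0.1, rel=1e-12)
        assert np.all(np.abs(traj.balance_residual) / max(produced, 1e-300) < 1e-6)

    def test_emission_rate_linear_in_gas_pool(self):
        pp = PoolParams()
        s1 = PoolState(Q_g=0.2)
        assert emission_rate(PoolState(), pp) == 0.0
        assert emission_rate(PoolState(Q_g=0.4), pp) == pytest.approx(
            2 * emission_rate(s1, pp), rel=1e-12
        )

    def test_negative_pool_guard(self):
        pp = PoolParams()
        with pytest.raises(Exception):
            update_pools(PoolState(), -1.0, pp, 10.0)


class TestArrivedMassProfile:
    def test_zero_rate_profile(self, fast_channel):
        prof = EmissionProfile.from_timeseries(np.linspace(0, 4, 5), np.zeros(5))
        assert arrived_mass_profile(prof, fast_channel, 3.0) == 0.0

    def test_impulse_equals_hit_probability(self, fast_channel):
        prof = EmissionProfile.impulse(1.0)
        for t in (0.5, 1.0, 3.0):
            assert arrived_mass_profile(prof, fast_channel, t) == pytest.approx(
                hit_probability(t, fast_channel), rel=1e-12
            )

    def test_rectangular_profile_matches_double_quadrature(self, fast_channel):
        # rectangle 0.001 mg/s on [0, 1 s], sharp edge via a near-degenerate knot
        tg = np.array([0.0, 1.0, 1.0 + 1e-9, 4.0])
        J = np.array([0.001, 0.001, 0.0, 0.0])
        prof = EmissionProfile.from_timeseries(tg, J)
        val = arrived_mass_profile(prof, fast_channel, 3.0)
        oracle, _ = integrate.dblquad(
            lambda u, delta: 0.001 * hit_density(u, fast_channel),
            0.0, 1.0, 0.0, lambda delta: 3.0 - delta, epsabs=1e-13, epsrel=1e-10,
        )
        assert val == pytest.approx(oracle, rel=1e-4)

    def test_profile_shorter_than_query_rejected(self, fast_channel):
        prof = EmissionProfile.from_timeseries([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ConfigurationError):
            arrived_mass_profile(prof, fast_channel, 2.0)


def test_end_to_end_emission_chain(fast_channel):
    """Gene network -> pools -> release profile -> arrival is finite and positive."""
    node = GeneNode("x", basal_rate=0.5, max_rate=0.01, decay_rate=0.2)
    grid = np.linspace(0, 4, 81)
    traj = synthesis_timeseries([node], grid)
    pools = simulate_pools(traj.synthesis[0], grid, PoolParams())
    prof = EmissionProfile.from_timeseries(grid, pools.J)
    arrived = arrived_mass_profile(prof, fast_channel, 4.0)
    assert 0.0 < arrived < pools.emitted[-1]
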