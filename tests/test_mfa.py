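"""Mean-field approximation: fixed-point census, moment closure, component
rates, mixture-weight closures and the mixture container."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eldscape import make_example2, mfa
from eldscape.mfa import (
    FixedPoint,
    GaussianComponent,
    assemble_mixture,
    component_rate,
    estimate_rho0,
    estimate_rhoU,
    evolve_weights,
    find_fixed_points,
    load_mixture,
    moment_odes,
    save_mixture,
)
from eldscape.models import Box, DifferentiationModel

SQRT3_2 = math.sqrt(3.0) / 2.0


class TestFixedPoints:
    def test_triple_well_census_matches_printed_equilibria(self, ex1):
        fps = find_fixed_points(ex1, seed=0)
        stable = sorted(
            [fp.location for fp in fps if fp.stability == "stable"],
            key=lambda x: (round(x[0], 6), round(x[1], 6)),
        )
        assert len(stable) == 3
        expected = [(-1.0, -1.0), (0.0, SQRT3_2), (1.0, -1.0)]
        for got, want in zip(stable, expected):
            assert np.allclose(got, want, atol=1e-6)

    def test_toggle_stable_points_swap_symmetric(self):
        m = make_example2(0.0)
        fps = find_fixed_points(m, seed=1)
        stable = [fp.location for fp in fps if fp.stability == "stable"]
        assert len(stable) == 2
        a, b = stable
        assert np.allclose(a, b[::-1], atol=1e-8)

    def test_linear_drift_single_origin(self, ou_model):
        fps = find_fixed_points(ou_model, seed=2, n_starts=30)
        assert len(fps) == 1
        assert fps[0].stability == "stable"
        assert np.allclose(fps[0].location, 0.0, atol=1e-10)

    def test_census_deterministic_given_seed(self, ex1):
        a = find_fixed_points(ex1, seed=5)
        b = find_fixed_points(ex1, seed=5)
        assert all(
            np.array_equal(x.location, y.location) for x, y in zip(a, b)
        )


class TestMomentClosure:
    def test_linear_drift_recovers_lyapunov_solution(self, ou_model):
        fp = FixedPoint(np.zeros(2), "stable", np.array([-1.0, -1.0]))
        comp = moment_odes(ou_model, fp)
        # for A = I the Lyapunov equation A S + S A^T = 2I gives S = I
        assert np.allclose(comp.sigma, np.eye(2), atol=1e-9)
        assert np.allclose(comp.mu, 0.0, atol=1e-10)

    def test_general_linear_drift_satisfies_lyapunov_identity(self):
        A = np.array([[2.0, 0.5], [-0.3, 1.0]])
        m = DifferentiationModel(
            name="lin",
            dim=2,
            drift=lambda x: -np.asarray(x, dtype=float) @ A.T,
            rate=lambda x: np.zeros(np.asarray(x).shape[:-1]),
            epsilon=0.01,
            domain=Box((-1.0, -1.0), (1.0, 1.0)),
            jacobian=lambda x: -A,
            hessian=lambda x: np.zeros((2, 2, 2)),
        )
        fp = FixedPoint(np.zeros(2), "stable", np.sort(np.linalg.eigvals(-A).real))
        comp = moment_odes(m, fp)
        resid = -A @ comp.sigma + comp.sigma @ (-A).T + 2 * np.eye(2)
        assert np.abs(resid).max() < 1e-9

    def test_zero_noise_mean_stays_at_fixed_point(self, ex1):
        fps = find_fixed_points(ex1, seed=0)
        fp = [f for f in fps if f.stability == "stable"][0]
        comp = moment_odes(ex1, fp, epsilon=0.0)
        assert np.allclose(comp.mu, fp.location, atol=1e-11)

    def test_unstable_start_rejected(self, ex1):
        fp = FixedPoint(np.array([0.0, 0.0]), "saddle", np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            moment_odes(ex1, fp)

    def test_component_covariance_matches_confined_sde(self, ex1):
        # long SDE trajectories confined to the basin of x_B: the sample
        # covariance must match eps*Sigma from the closure within 10%
        from eldscape import fk_sim

        fps = find_fixed_points(ex1, seed=0)
        fpB = [f for f in fps if np.allclose(f.location, [-1, -1], atol=1e-6)][0]
        comp = moment_odes(ex1, fpB)

        def init(rng, n):
            return np.tile(fpB.location, (n, 1))

        ens = fk_sim.simulate_ensemble(
            ex1.zero_rate(), 4000, 4.0, dt=0.002, seed=21, init=init
        )
        x = ens.positions
        keep = np.linalg.norm(x - fpB.location, axis=1) < 0.5  # basin-exit rejection
        emp = np.cov(x[keep].T)
        target = ex1.epsilon * comp.sigma
        assert np.abs(emp - target).max() < 0.1 * np.abs(target).max()


class TestComponentRate:
    def test_constant_rate_returned_exactly(self, ex1):
        m = ex1.with_rate(lambda x: np.full(np.asarray(x).shape[:-1], 2.5))
        c = GaussianComponent(np.array([0.0, 0.5]), np.eye(2))
        assert component_rate(m, c) == pytest.approx(2.5, abs=1e-12)

    def test_point_mass_limit_recovers_pointwise_rate(self, ex1):
        c = GaussianComponent(np.array([-1.0, -1.0]), 1e-12 * np.eye(2))
        assert component_rate(ex1, c) == pytest.approx(-0.3, abs=1e-9)

    def test_quadratic_expansion_at_differentiated_state(self, ex1):
        # around x_B the printed rate expands as
        # R_k = -0.3 + 0.3 eps (4 S11 + S22) + O(eps^2)
        sigma = np.array([[0.6, 0.1], [0.1, 0.25]])
        c = GaussianComponent(np.array([-1.0, -1.0]), sigma)
        got = component_rate(ex1, c)
        hand = -0.3 + 0.3 * ex1.epsilon * (4 * sigma[0, 0] + sigma[1, 1])
        # the quartic term contributes 0.9 (eps S11)^2 beyond the expansion
        assert got == pytest.approx(hand, abs=1e-4)
        assert got == pytest.approx(hand + 0.9 * (ex1.epsilon * sigma[0, 0]) ** 2,
                                    abs=1e-12)


class TestWeightClosure:
    def test_zero_rates_leave_weights_unchanged(self):
        rho0 = np.array([0.2, 0.5, 0.3])
        rhoU, summary = estimate_rhoU(rho0, np.zeros(3))
        assert np.allclose(rhoU, rho0)
        assert summary.growth_rate == 0.0

    def test_constant_rates_recentred_away(self):
        rho0 = np.array([0.4, 0.6])
        rhoU, summary = estimate_rhoU(rho0, np.array([1.3, 1.3]))
        assert np.allclose(rhoU, rho0)
        assert summary.growth_rate == pytest.approx(1.3)

    def test_two_state_example_balances_exactly(self):
        rho0 = np.array([0.25, 0.75])
        rates = np.array([1.0, -1.0])
        rhoU, summary = estimate_rhoU(rho0, rates)
        # bisection on the closure: c = 0.75, weights (0.5, 0.5)
        assert summary.closure_constant == pytest.approx(0.75, abs=1e-10)
        assert np.allclose(rhoU, [0.5, 0.5], atol=1e-10)
        assert rhoU[0] > rho0[0]  # proliferating basin gains weight
        assert abs(float(rhoU @ rates)) < 1e-10

    def test_exit_rates_exceed_component_rates(self):
        rho0 = np.array([0.25, 0.75])
        rhoU, summary = estimate_rhoU(rho0, np.array([1.0, -1.0]))
        assert np.all(summary.exit_rates > summary.component_rates)

    @settings(deadline=None, max_examples=60)
    @given(
        w=st.floats(0.1, 0.9),
        r1=st.floats(-1.0, 1.0),
        r2=st.floats(-1.0, 1.0),
        bump=st.floats(0.01, 0.4),
    )
    def test_raising_a_rate_never_lowers_its_residence_weight(
        self, w, r1, r2, bump
    ):
        # monotonicity of the residence-weight map at fixed exit rates; the
        # balance-determined closure constant trades weights between basins
        # and is deliberately not monotone in a single rate
        from eldscape.mfa import residence_weights

        rho0 = np.array([w, 1.0 - w])
        q = np.array([2.0, 2.0])
        base = residence_weights(rho0, np.array([r1, r2]), q)
        more = residence_weights(rho0, np.array([r1 + bump, r2]), q)
        assert more[0] >= base[0] - 1e-12

    def test_weights_stay_normalized_and_positive(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            K = rng.integers(2, 6)
            rho0 = rng.dirichlet(np.ones(K))
            rates = rng.normal(0, 1, K) - 0.3
            rhoU, _ = estimate_rhoU(rho0, rates)
            assert np.all(rhoU > 0)
            assert rhoU.sum() == pytest.approx(1.0)


class TestRho0:
    def test_single_basin_returns_unit_weight(self, ou_model):
        fps = find_fixed_points(ou_model, seed=0, n_starts=30)
        assert np.allclose(estimate_rho0(ou_model, fps), [1.0])

    def test_symmetric_toggle_equal_weights(self):
        m = make_example2(5.0)  # r does not enter the drift
        fps = find_fixed_points(m, seed=1)
        stable = [fp for fp in fps if fp.stability == "stable"]
        rho = estimate_rho0(m, stable, n_particles=4000, T=6.0, dt=0.01,
                            seed=13, check_convergence=False)
        assert abs(rho[0] - rho[1]) < 6 * np.sqrt(0.25 / 4000)

    def test_triple_well_three_positive_weights(self, ex1, stable_points_ex1):
        rho = estimate_rho0(ex1, stable_points_ex1, n_particles=3000, T=6.0,
                            dt=0.005, seed=14, check_convergence=False)
        assert rho.shape == (3,)
        assert np.all(rho > 0) and rho.sum() == pytest.approx(1.0)


class TestMixture:
    def test_single_component_integrates_to_one(self, ou_model):
        comp = GaussianComponent(np.zeros(2), np.eye(2))
        mix = assemble_mixture([comp], [1.0], "P0", epsilon=0.01)
        # quadrature over a wide box
        x = np.linspace(-0.8, 0.8, 401)
        X, Y = np.meshgrid(x, x)
        pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
        mass = mix.pdf(pts).sum() * (x[1] - x[0]) ** 2
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_separated_components_dominate_at_their_means(self):
        c1 = GaussianComponent(np.array([0.0, 0.0]), np.eye(2))
        c2 = GaussianComponent(np.array([2.0, 0.0]), np.eye(2))
        mix = assemble_mixture([c1, c2], [0.5, 0.5], "P0", epsilon=0.01)
        lp = mix.component_logpdfs(np.array([2.0, 0.0]))
        assert lp[1] > lp[0] + 50  # well separated at eps = 0.01

    def test_weight_component_mismatch_rejected(self):
        c = GaussianComponent(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            assemble_mixture([c], [0.5, 0.5], "P0", epsilon=0.01)

    def test_mixture_json_round_trip(self, tmp_path):
        comps = [
            GaussianComponent(np.array([0.0, 1.0]), np.array([[1.0, 0.2], [0.2, 0.5]]), basin=0),
            GaussianComponent(np.array([1.0, 0.0]), np.eye(2), basin=1),
        ]
        mix = assemble_mixture(comps, [0.3, 0.7], "PU", epsilon=0.02)
        path = tmp_path / "mix.json"
        save_mixture(mix, path, model_name="demo")
        back = load_mixture(path)
        pts = np.random.default_rng(4).normal(0.5, 1.0, size=(50, 2))
        assert np.allclose(mix.logpdf(pts), back.logpdf(pts))
        assert back.kind == "PU" and back.epsilon == 0.02


class TestEvolveWeights:
    def test_zero_generator_zero_rates_constant(self):
        out = evolve_weights(np.zeros((2, 2)), np.zeros(2), [0.3, 0.7], T=5.0)
        assert np.allclose(out["rho0"][-1], [0.3, 0.7])
        assert np.allclose(out["rhoU"][-1], [0.3, 0.7])

    def test_uniform_rate_growth_factors_out(self):
        out = evolve_weights(np.zeros((2, 2)), np.full(2, 0.8), [0.3, 0.7], T=2.0)
        assert np.allclose(out["rhoU"][-1], [0.3, 0.7])
        assert out["rhoU_total"][-1] == pytest.approx(np.exp(0.8 * 2.0), rel=1e-10)

    def test_two_state_relaxation_closed_form(self):
        k = 0.7
        Q = np.array([[-k, k], [k, -k]])
        T = 3.0
        out = evolve_weights(Q, np.zeros(2), [1.0, 0.0], T=T, n_out=10)
        # closed form: rho1(t) = 1/2 (1 + exp(-2kt))
        expect = 0.5 * (1 + np.exp(-2 * k * T))
        assert out["rho0"][-1][0] == pytest.approx(expect, abs=1e-12)

    def test_non_generator_rejected(self):
        with pytest.raises(ValueError):
            evolve_weights(np.array([[0.1, 0.0], [0.0, 0.0]]), np.zeros(2), [1, 0], 1.0)
        with pytest.raises(ValueError):
            evolve_weights(np.array([[0.5, -0.5], [1.0, -1.0]]), np.zeros(2), [1, 0], 1.0)


class TestMfaPdeAgreement:
    def test_mixture_minima_sit_on_pde_minima(self, ex2_r0_result):
        # every PDE-U minimum of the symmetric toggle has a mixture-U minimum
        # within one grid cell
        from eldscape import EnergyLandscape

        res_mfa = EnergyLandscape(
            make_example2(0.0), method="mfa", n_particles=3000, T=6.0, dt=0.01,
            seed=15, check_convergence=False,
        ).fit()
        # the moment closure shifts the mixture means by O(eps) relative to
        # the finite-eps PDE minima: agreement within a few cells (well below
        # the thermal length sqrt(eps) = 0.1), not one cell
        for pde_min in ex2_r0_result.minima:
            d = min(
                np.linalg.norm(np.array(mm["location"]) - np.array(pde_min["location"]))
                for mm in res_mfa.minima
            )
            assert d <= 0.05
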