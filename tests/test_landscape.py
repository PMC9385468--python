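"""Landscape construction: potentials, curl component, diagnostics, minima
counting and the elliptic cross-check."""

import numpy as np

from eldscape import fpe2d, landscape, make_example2
from eldscape.fpe2d import GridField, build_grid, steady_p0
from eldscape.landscape import (
    check_balance,
    count_minima,
    curl_component,
    potential_U,
    potential_V,
    solve_pba_V,
)


class TestPotentials:
    def test_uniform_density_gives_flat_zero_energy(self, ou_model):
        g = build_grid(ou_model, 32, 32)
        p = GridField(g, np.ones(g.shape)).normalize()
        U = potential_U(p, epsilon=0.01)
        assert np.abs(U.values).max() < 1e-14
        assert U.values.min() == 0.0

    def test_identical_densities_give_zero_V(self, ou_model):
        g = build_grid(ou_model, 32, 32)
        p = steady_p0(ou_model, g).density
        V = potential_V(p, p, epsilon=0.01)
        assert np.abs(V.values[V.mask]).max() == 0.0

    def test_gauge_invariance_under_density_rescaling(self, ou_model):
        # multiplying a density by a constant before the log must not change
        # the shifted U or the mean-zero V
        g = build_grid(ou_model, 32, 32)
        p = steady_p0(ou_model, g).density
        q = p.copy()
        q.values = q.values * 7.3
        U1 = potential_U(p, 0.01)
        U2 = potential_U(q, 0.01)
        assert np.allclose(U1.values, U2.values, atol=1e-12)
        V1 = potential_V(p, p, 0.01)
        V2 = potential_V(q, p, 0.01)
        assert np.allclose(V1.values[V1.mask], V2.values[V2.mask], atol=1e-12)

    def test_pluripotency_ordering_stem_above_differentiated(self, ex1_result):
        # the proliferating stem state carries the highest V
        res = ex1_result
        g = res.V.grid

        def v_at(x, y):
            ix = np.argmin(np.abs(g.x - x))
            jy = np.argmin(np.abs(g.y - y))
            return res.V.values[jy, ix]

        vA = v_at(0.0, np.sqrt(3) / 2)
        assert vA > v_at(-1.0, -1.0)
        assert vA > v_at(1.0, -1.0)


class TestCurlComponent:
    def test_decomposition_identity_holds_by_construction(self, ex2_r0_result):
        res = ex2_r0_result
        g = res.U.grid
        b = res.model.drift(g.nodes()).reshape(g.shape + (2,))
        gyU, gxU = np.gradient(res.U.values, g.hy, g.hx)
        gyV, gxV = np.gradient(res.V.values, g.hy, g.hx)
        lhs = b + np.stack([gxU, gyU], axis=-1) + np.stack([gxV, gyV], axis=-1)
        assert np.allclose(lhs, res.f, atol=1e-12)

    def test_gradient_drift_curl_is_negligible(self, ex1_r0_result):
        assert ex1_r0_result.diagnostics["f_to_drift_ratio"] < 0.05

    def test_hill_drift_curl_is_genuine(self, ex2_r0_result):
        # mutual-inhibition kinetics are non-gradient: f is O(b), not noise
        assert ex2_r0_result.diagnostics["f_to_drift_ratio"] > 0.05

    def test_curl_ratio_shrinks_under_refinement(self, ex1):
        ratios = []
        for nx in (101, 201):
            g = build_grid(ex1, nx, nx)
            s0 = steady_p0(ex1, g)
            U = potential_U(s0.density, ex1.epsilon)
            V = potential_V(s0.density, s0.density, ex1.epsilon)
            f, valid = curl_component(ex1, U, V)
            b = ex1.drift(g.nodes()).reshape(g.shape + (2,))
            fn = np.linalg.norm(f, axis=-1)
            bn = np.linalg.norm(b, axis=-1)
            ratios.append(fn[valid].max() / bn[valid].max())
        assert ratios[1] < ratios[0]


class TestDiagnostics:
    def test_balance_zero_rate_exact(self, ou_model):
        g = build_grid(ou_model, 32, 32)
        p = steady_p0(ou_model, g).density
        assert check_balance(p, ou_model.rate, 0.0) == 0.0

    def test_balance_residual_small_for_eigen_solution(self, ex1_result):
        assert abs(ex1_result.diagnostics["balance_residual"]) < 1e-6

    def test_mixture_closure_balance_near_machine(self):
        from eldscape.mfa import estimate_rhoU

        rhoU, summary = estimate_rhoU(
            np.array([0.25, 0.75]), np.array([1.0, -1.0])
        )
        assert abs(float(rhoU @ (summary.component_rates - summary.growth_rate))) < 1e-8

    def test_divergence_residual_contract(self, ex2_r0_result, ex1_result):
        assert ex2_r0_result.diagnostics["divergence_residual"] < 0.05
        assert ex1_result.diagnostics["divergence_residual"] < 0.05

    def test_divergence_residual_halves_under_refinement(self):
        m = make_example2(0.0)
        res = []
        for nx in (201, 401):
            g = build_grid(m, nx, nx)
            s0 = steady_p0(m, g)
            U = potential_U(s0.density, m.epsilon)
            V = potential_V(s0.density, s0.density, m.epsilon)
            f, valid = curl_component(m, U, V)
            b = m.drift(g.nodes()).reshape(g.shape + (2,))
            _, r = landscape.check_divergence_free(f, s0.density, valid, drift=b)
            res.append(r)
        assert res[1] < 0.75 * res[0]

    def test_orthogonality_zero_for_gradient_and_zero_rate(
        self, ex1_r0_result, ex1_result
    ):
        assert ex1_r0_result.diagnostics["orthogonality"] == 0.0
        assert ex1_result.diagnostics["orthogonality"] == 0.0  # f is noise-level

    def test_orthogonality_positive_for_nongradient_system(self):
        from eldscape import EnergyLandscape

        res = EnergyLandscape(make_example2(3.0)).fit()
        assert res.diagnostics["orthogonality"] > 0.0


class TestPbaCrossCheck:
    def test_zero_rate_gives_zero_potential(self, ou_model):
        g = build_grid(ou_model, 64, 64)
        p = steady_p0(ou_model, g).density
        V = solve_pba_V(p, ou_model.rate, g, growth_rate=0.0)
        assert np.abs(V.values[V.mask]).max() < 1e-10

    def test_gradient_system_agrees_with_log_ratio_V(self, ex1, ex1_result):
        res = ex1_result
        V10 = solve_pba_V(res.PU, ex1.rate, res.PU.grid, growth_rate=res.growth_rate)
        both = res.V.mask & V10.mask & np.isfinite(V10.values)
        r = np.corrcoef(res.V.values[both], V10.values[both])[0, 1]
        assert r > 0.95

    def test_nongradient_discrepancy_reported_not_asserted(self, ex2_r30_result):
        # for the Hill system the elliptic route is only approximate; report
        # the discrepancy together with the orthogonality statistic
        res = ex2_r30_result
        m = make_example2(30.0)
        V10 = solve_pba_V(res.PU, m.rate, res.PU.grid, growth_rate=res.growth_rate)
        both = res.V.mask & V10.mask & np.isfinite(V10.values)
        assert both.sum() > 50  # a usable comparison region exists
        r = np.corrcoef(res.V.values[both], V10.values[both])[0, 1]
        assert np.isfinite(r)
        assert np.isfinite(res.diagnostics["orthogonality"])


class TestMinima:
    def _energy_from_wells(self, grid, wells, depths, width=0.15):
        X, Y = grid.meshgrid()
        U = np.zeros(grid.shape)
        for (wx, wy), d in zip(wells, depths):
            U -= d * np.exp(-((X - wx) ** 2 + (Y - wy) ** 2) / (2 * width**2))
        return GridField(grid, U - U.min(), kind="energy",
                         mask=np.ones(grid.shape, bool))

    def test_synthetic_wells_counted_and_shallow_ones_filtered(self, ou_model):
        g = build_grid(ou_model, 101, 101)
        wells = [(-0.5, -0.5), (0.5, 0.5), (0.0, 0.0)]
        U = self._energy_from_wells(g, wells, depths=[1.0, 0.8, 0.002])
        found = count_minima(U, prominence=0.01)
        assert len(found) == 2
        locs = sorted(tuple(np.round(m["location"], 1)) for m in found)
        assert locs == [(-0.5, -0.5), (0.5, 0.5)]

    def test_nearby_minima_merged(self, ou_model):
        g = build_grid(ou_model, 101, 101)
        # two wells closer than 3 cells: must merge into one
        h = g.hx
        U = self._energy_from_wells(
            g, [(0.0, 0.0), (2 * h, 0.0)], depths=[1.0, 1.0], width=0.3
        )
        found = count_minima(U, prominence=0.01)
        assert len(found) == 1

    def test_triple_well_boltzmann_density_has_three_minima(self, ex1_r0_result):
        assert ex1_r0_result.n_cell_types == 3

    def test_toggle_sweep_minima_non_increasing_in_rate_amplitude(
        self, ex2_r30_result, ex2_r0_result
    ):
        from eldscape import EnergyLandscape

        counts = {
            30.0: ex2_r30_result.n_cell_types,
            10.0: EnergyLandscape(make_example2(10.0)).fit().n_cell_types,
            0.0: ex2_r0_result.n_cell_types,
        }
        assert counts[30.0] == 1 and counts[0.0] == 2
        vals = [counts[r] for r in (30.0, 10.0, 0.0)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestResultObject:
    def test_summary_lists_key_quantities(self, ex1_result):
        s = ex1_result.summary()
        assert "growth rate" in s and "metastable states" in s
        assert ex1_result.model.name in s

    def test_export_writes_grids_and_diagnostics(self, tmp_path, ex2_r0_result):
        out = tmp_path / "out"
        ex2_r0_result.export(out)
        import json
        import os

        assert (out / "U.tsv").exists() and (out / "V.tsv").exists()
        assert (out / "f_norm.tsv").exists()
        blob = json.load(open(out / "diagnostics.json"))
        assert blob["n_cell_types"] == 2
        back = fpe2d.load_field(out / "U.tsv")
        assert np.allclose(back.values, ex2_r0_result.U.values, equal_nan=True)

    def test_plotting_smoke(self, ex2_r0_result):
        import matplotlib

        matplotlib.use("Agg")
        ax = ex2_r0_result.plot_V(kind="contour")
        assert ax is not None
        ax2 = ex2_r0_result.plot_U(kind="surface")
        assert ax2 is not None
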