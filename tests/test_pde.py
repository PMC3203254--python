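import numpy as np
import pytest

from rtasim import (
    SolverSettings,
    advance,
    build_grid,
    derived_constants,
    grid_convergence_study,
    psi_sat_pde,
    psi_timecourse,
    reaction_terms,
    simulate,
    surface_flux,
    window_of_opportunity,
)
from rtasim.pde import Fields, _initial_fields


class TestGrid:
    def test_three_node_grid(self, params):
        g = build_grid(params.geom, 3)
        assert np.allclose(g.rho, [0.1, 1.05, 2.0])

    def test_spacing(self):
        from rtasim import Geometry

        g = build_grid(Geometry(rho_c=0.1, rho_e=5.0, r0_bar=1.0), 491)
        assert g.h == pytest.approx((5.0 - 0.1) / 490)

    def test_too_few_nodes(self, params):
        with pytest.raises(ValueError):
            build_grid(params.geom, 2)


class TestReactionTerms:
    def test_initial_source(self, params):
        uT = np.array([0.5])
        uA = np.array([1.0])
        uC = np.array([0.0])
        sT, sA, sC = reaction_terms(uT, uA, uC, params)
        assert sT[0] == pytest.approx(-6.5e-3)

    def test_detailed_balance(self, params):
        r = params.rates
        uT = np.linspace(0.1, 0.5, 5)
        uA = np.linspace(0.2, 1.0, 5)
        uC = r.k1 / r.k_m1 * uT * uA
        sT, sA, sC = reaction_terms(uT, uA, uC, params)
        assert np.allclose(sT, 0.0, atol=1e-18)

    def test_antisymmetry_exact(self, params):
        rng = np.random.default_rng(7)
        uT, uA, uC = rng.random((3, 50))
        sT, sA, sC = reaction_terms(uT, uA, uC, params)
        assert np.all(sT + sC == 0.0)
        assert np.all(sA + sC == 0.0)


class TestSurfaceFlux:
    def test_binding_equilibrium_is_fluxless(self, params):
        r = params.rates
        uT = 0.3
        theta_eq = r.k2 * uT / (r.k2 * uT + r.k_m2)
        s, _ = surface_flux(uT, theta_eq, params)
        assert s == pytest.approx(0.0, abs=1e-18)

    def test_initial_binding_rate(self, params):
        s, theta_dot = surface_flux(0.5, 0.0, params)
        assert s == pytest.approx(6.25e-3)
        assert theta_dot == pytest.approx(6.25e-3)

    def test_pure_unbinding(self, params):
        s, _ = surface_flux(0.0, 1.0, params)
        assert s == pytest.approx(-params.rates.k_m2)


class TestAdvance:
    def test_dirichlet_enforced_exactly(self, params):
        settings = SolverSettings(N=51, dt=1.0)
        f0 = _initial_fields(params, build_grid(params.geom, 51))
        f1 = advance(f0, 1.0, params, settings)
        assert f1.uT[-1] == params.ib.uT0
        assert f1.uA[-1] == params.ib.uA0
        assert f1.uC[-1] == 0.0

    def test_antibody_free_subsystem_stays_zero(self, params):
        p = params.replace(uA0=0.0)
        settings = SolverSettings(N=51, dt=1.0)
        f = _initial_fields(p, build_grid(p.geom, 51))
        for _ in range(5):
            f = advance(f, 1.0, p, settings)
        assert np.all(f.uA == 0.0)
        assert np.all(np.abs(f.uC) < 1e-15)

    def test_inner_iteration_budget_enforced(self, params):
        settings = SolverSettings(N=21, dt=1.0, max_inner_iters=1, nonlinear_tol=1e-15)
        f0 = _initial_fields(params, build_grid(params.geom, 21))
        with pytest.raises(RuntimeError, match="Picard"):
            advance(f0, 1.0, params, settings)


class TestSimulate:
    def test_zero_horizon_keeps_initial_snapshot(self, params, fast_settings):
        sol = simulate(params, fast_settings, t_end=0.0)
        assert len(sol.snapshots) == 1
        assert sol.snapshots[0].t == 0.0
        assert np.all(sol.snapshots[0].uT == params.ib.uT0)

    def test_determinism_bit_identical(self, params, fast_settings):
        a = simulate(params, fast_settings, t_end=50.0)
        b = simulate(params, fast_settings, t_end=50.0)
        assert np.array_equal(a.theta_series, b.theta_series)
        assert np.array_equal(a.snapshots[-1].uT, b.snapshots[-1].uT)

    def test_positivity_and_occupancy_bounds(self, params, fast_settings):
        sol = simulate(params, fast_settings, t_end=500.0, record_times=[250.0, 500.0])
        assert np.all(sol.theta_series >= 0.0)
        assert np.all(sol.theta_series <= 1.0)
        for snap in sol.snapshots:
            for arr in (snap.uT, snap.uA, snap.uC):
                assert arr.min() > -1e-10

    def test_large_diffusivity_limit_matches_analytic_occupancy(self, params):
        # kappa >> 1 pins the fields at the boundary values, so theta obeys
        # dtheta/dt = k2 uT0 (1-theta) - (k_m2 + k3) theta exactly
        p = params.replace(kappa_T=1e3, kappa_A=1e3, kappa_C=1e3, uA0=0.0)
        sol = simulate(p, SolverSettings(N=101, dt=0.1), t_end=200.0)
        lam = p.rates.k2 * 0.5 + p.rates.k_m2 + p.rates.k3
        th_inf = p.rates.k2 * 0.5 / lam
        analytic = th_inf * (1.0 - np.exp(-lam * sol.theta_times))
        assert np.max(np.abs(sol.theta_series - analytic)) < 1e-3
        # fields stay spatially uniform
        snap = sol.snapshots[-1]
        assert np.ptp(snap.uT) < 1e-4

    def test_steady_state_flux_balance(self, params):
        # at (near) steady state the internalization flux through the cell
        # surface balances the diffusive influx of total toxin (uT + uC)
        # through the outer boundary
        sol = simulate(params, SolverSettings(N=201, dt=1.0), 1e4, record_times=[1e4])
        snap = sol.snapshots[-1]
        g = sol.grid
        Sc = 4 * np.pi * params.geom.rho_c**2
        Se = 4 * np.pi * params.geom.rho_e**2
        internal = params.geom.r0_bar * params.rates.k3 * snap.theta * Sc
        h = g.h
        gT = (3 * snap.uT[-1] - 4 * snap.uT[-2] + snap.uT[-3]) / (2 * h)
        gC = (3 * snap.uC[-1] - 4 * snap.uC[-2] + snap.uC[-3]) / (2 * h)
        influx = Se * (params.diff.kappa_T * gT + params.diff.kappa_C * gC)
        assert influx == pytest.approx(internal, rel=0.01)

    def test_crank_nicolson_agrees_with_backward_euler(self, params):
        be = simulate(params, SolverSettings(N=101, dt=1.0), 200.0)
        cn = simulate(
            params, SolverSettings(N=101, dt=1.0, scheme="crank_nicolson"), 200.0
        )
        assert cn.theta_series[-1] == pytest.approx(be.theta_series[-1], abs=1e-3)


class TestProtectionCurve:
    def test_identical_runs_give_unity(self, params, fast_settings):
        a = simulate(params, fast_settings, 100.0)
        b = simulate(params, fast_settings, 100.0)
        curve = psi_timecourse(a, b)
        assert np.allclose(curve.psi, 1.0)

    def test_short_time_limit_is_unity(self, params, fast_settings):
        a = simulate(params, fast_settings, 20.0)
        b = simulate(params.replace(uA0=0.0), fast_settings, 20.0)
        curve = psi_timecourse(a, b)
        assert curve.psi[0] == 1.0
        # both occupancies grow as k2 uT0 t to first order
        assert curve.psi[1] == pytest.approx(1.0, abs=0.05)

    def test_mismatched_runs_rejected(self, params, fast_settings):
        a = simulate(params, fast_settings, 10.0)
        b = simulate(params.replace(uT0=0.1), fast_settings, 10.0)
        with pytest.raises(ValueError):
            psi_timecourse(a, b)

    def test_diffusivity_switches_monotonicity(self, params):
        # fast toxin diffusion: boundary resupply lifts psi after an early
        # interior minimum (the window of opportunity); slow toxin diffusion:
        # psi declines monotonically over the same window
        s = SolverSettings(N=101, dt=1.0)
        shapes = {}
        for kT in (1e-2, 1e-4):
            p = params.replace(kappa_T=kT)
            a = simulate(p, s, 1e3)
            b = simulate(p.replace(uA0=0.0), s, 1e3)
            shapes[kT] = window_of_opportunity(psi_timecourse(a, b))
        assert shapes[1e-2]["interior"] != shapes[1e-4]["interior"]


class TestPsiSatPde:
    def test_isotherm_vanishes_without_toxin(self, params):
        d = derived_constants(params)
        assert 0.0 / (0.0 + d.K2 + d.b) == 0.0

    def test_variants_validated(self, params, fast_settings):
        with pytest.raises(ValueError):
            psi_sat_pde(params, fast_settings, variant="psi9")


class TestConvergenceStudy:
    def test_requires_two_settings(self, params):
        with pytest.raises(ValueError):
            grid_convergence_study(params, [SolverSettings(N=51, dt=2.0)])

    def test_changes_shrink_with_refinement(self, params):
        p = params.replace(kappa_T=1e-3)
        rows = grid_convergence_study(
            p,
            [
                SolverSettings(N=51, dt=2.0),
                SolverSettings(N=101, dt=2.0),
                SolverSettings(N=201, dt=2.0),
            ],
        )
        assert rows[0]["change"] is None
        assert rows[2]["change"] < rows[1]["change"]
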