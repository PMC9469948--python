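"""Delay integration: steady-state persistence, determinism, delay
consistency, non-dimensional round trip, and convergence."""

import numpy as np
import pytest

from israpop.params import default_params
from israpop.ratelaws import RhsSwitches, make_rhs
from israpop.solver import (AnalyticDrugHistory, SimulationError, SolverConfig,
                            pow2_scales, simulate)
from israpop.states import IDX, N_STATES
from israpop.trajectory import Protocol


class TestScaling:
    def test_round_trip_is_exact(self, steady_state):
        s = pow2_scales(steady_state)
        y = np.asarray(steady_state)
        assert np.array_equal((y / s) * s, y)

    def test_scales_track_dose(self):
        proto = Protocol(venetoclax_nM=400.0)
        s = pow2_scales(np.zeros(N_STATES), proto)
        assert s[IDX["venetoclax_ext"]] == 512.0   # nearest power of two


class TestAnalyticDrugHistory:
    def test_matches_numerical_uptake(self, params, fast_solver):
        """Closed-form intracellular concentration equals the integrated
        drug pool along a simulated protocol."""
        proto = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                         horizon_h=96.0, output_points=300)
        traj = simulate(params, proto, fast_solver)
        hist = AnalyticDrugHistory(params, proto.events())
        for i in (20, 80, 150, traj.t.size - 1):
            t = traj.t[i]
            for name in ("venetoclax_int", "tedizolid_int"):
                sim = traj.state(name)[i]
                exact = hist.value(IDX[name], t)
                assert sim == pytest.approx(exact, rel=1e-4)

    def test_zero_before_administration(self, params):
        hist = AnalyticDrugHistory(params, [(10.0, "venetoclax_ext", 400.0)])
        assert hist.value(IDX["venetoclax_int"], 5.0) == 0.0


class TestSimulate:
    def test_untreated_observables_constant(self, condition_trajectories):
        traj = condition_trajectories["untreated"]
        for prot in ("bcl2", "mcl1", "bim", "bax", "bak"):
            series = traj.protein_total(prot)
            assert np.max(np.abs(series / series[0] - 1.0)) < 1e-3

    def test_zero_dose_equals_untreated(self, params, steady_state, fast_solver):
        a = simulate(params, Protocol(venetoclax_nM=0.0, output_points=200),
                     fast_solver, steady_state=steady_state)
        b = simulate(params, Protocol(output_points=200), fast_solver,
                     steady_state=steady_state)
        assert np.array_equal(a.y, b.y)

    def test_bitwise_reproducible(self, params, steady_state, fast_solver):
        proto = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                         output_points=200)
        a = simulate(params, proto, fast_solver, steady_state=steady_state)
        b = simulate(params, proto, fast_solver, steady_state=steady_state)
        assert np.array_equal(a.y, b.y)

    def test_no_state_below_negativity_floor(self, condition_trajectories,
                                             fast_solver):
        floor = -10.0 * fast_solver.atol
        for traj in condition_trajectories.values():
            assert traj.y.min() >= floor

    def test_trajectory_grid_extends_with_pretreatment(self, params):
        base = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                        output_points=1200)
        pre = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                       tedizolid_time_h=-60.0, output_points=1200)
        assert pre.n_grid() == int(round(1200 * 180.0 / 120.0))
        assert base.n_grid() == 1200

    def test_delay_solver_agrees_with_plain_ode_at_zero_delay(
            self, params, steady_state):
        """With all delays zero the method of steps must reduce to a plain
        stiff ODE solve (day-5 viability within 0.1% relative)."""
        from scipy.integrate import solve_ivp
        p = params.copy()
        for name in ("myc_ven_tau", "myc_ted_tau", "chop_ven_tau", "chop_ted_tau"):
            p[name] = 0.0
        proto = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                         output_points=400)
        traj = simulate(p, proto, SolverConfig(), steady_state=steady_state)
        v_steps = traj.viability[-1]

        rhs = make_rhs(p)
        y0 = np.array(steady_state, dtype=float)
        y0[IDX["n_live"]] = p["n_live_0"]
        y0[IDX["n_dead"]] = p["n_dead_0"]
        y0[IDX["venetoclax_ext"]] += 400.0
        y0[IDX["tedizolid_ext"]] += 5000.0

        def fun(t, y):
            d = {"myc_ven": y[IDX["venetoclax_int"]],
                 "myc_ted": y[IDX["tedizolid_int"]],
                 "chop_ven": y[IDX["venetoclax_int"]],
                 "chop_ted": y[IDX["tedizolid_int"]]}
            return rhs(t, y, d)

        sol = solve_ivp(fun, (0.0, 120.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-11)
        yf = sol.y[:, -1]
        v_plain = yf[IDX["n_live"]] / (yf[IDX["n_live"]] + yf[IDX["n_dead"]])
        assert v_steps == pytest.approx(v_plain, rel=1e-3)

    def test_interpolated_history_matches_analytic_delays(
            self, params, steady_state):
        """The generic dense-output history and the closed-form drug delays
        give the same trajectory."""
        proto = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                         output_points=200)
        a = simulate(params, proto, SolverConfig(analytic_drug_delays=True),
                     steady_state=steady_state)
        b = simulate(params, proto, SolverConfig(analytic_drug_delays=False),
                     steady_state=steady_state)
        assert a.viability[-1] == pytest.approx(b.viability[-1], rel=1e-4)

    def test_tolerance_halving_converged(self, params, steady_state):
        proto = Protocol(venetoclax_nM=400.0, tedizolid_nM=5000.0,
                         output_points=200)
        v = {}
        for rtol, atol in [(1e-6, 1e-9), (5e-7, 5e-10)]:
            traj = simulate(params, proto, SolverConfig(rtol=rtol, atol=atol),
                            steady_state=steady_state)
            v[rtol] = traj.viability[-1]
        assert v[1e-6] == pytest.approx(v[5e-7], rel=1e-3)


class TestConservation:
    def test_totals_conserved_over_100h_without_turnover(self, params,
                                                         steady_state):
        """Pure binding/caspase dynamics: every protein total drifts by less
        than 1e-6 relative over 100 h."""
        from israpop.solver import integrate
        from israpop.states import total
        sw = RhsSwitches(synthesis=False, degradation=False, activation=False,
                         cleavage=False, drugs=False, population=False)
        y0 = np.asarray(steady_state).copy()
        cfg = SolverConfig(rtol=1e-10, atol=1e-13)
        hist = integrate(params, y0, 0.0, 100.0, cfg=cfg, switches=sw)
        y_end = hist.state(100.0)
        for prot in ("bcl2", "mcl1", "bim", "bax", "bak", "casp3"):
            t0 = total(y0, prot)
            t1 = total(y_end, prot)
            assert abs(t1 - t0) / t0 < 1e-6
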