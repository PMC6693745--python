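"""Steady-state solver: residual assembly, Newton iteration on toy
circuits with closed-form solutions, conservation identities, collapse
detection and onset search."""

import numpy as np
import pytest

from eyebrain0d import (REFERENCE, assemble_residuals, default_parameters,
                        make_scenario, solve_steady_state)
from eyebrain0d.core import NODE_INDEX, NODE_NAMES, PressureState
from eyebrain0d.fixtures import (filtration_loop, fixture_circuits,
                                 resistive_ladder, starling_edge_table)
from eyebrain0d.solver import (OnsetResult, compartment_margin,
                               continuation_sweep, detect_collapse,
                               find_collapse_onset,
                               global_conservation_residual, newton_solve)


class TestToyCircuits:
    @pytest.mark.parametrize("circuit", fixture_circuits(),
                             ids=lambda c: c.name)
    def test_newton_matches_closed_form(self, circuit):
        x, n_iter, norm = newton_solve(circuit.fun, circuit.x0, tol=1e-12)
        np.testing.assert_allclose(x, circuit.exact, rtol=1e-10)
        assert norm <= 1e-12

    def test_two_equal_resistors_give_boundary_average(self):
        c = resistive_ladder(1, 10.0, 0.0)
        x, _, _ = newton_solve(c.fun, c.x0, tol=1e-13)
        assert x[0] == pytest.approx(5.0, abs=1e-12)

    def test_ladder_has_linear_pressure_profile(self):
        c = resistive_ladder(7, 80.0, 5.0, R=2.5)
        x, _, _ = newton_solve(c.fun, c.x0, tol=1e-12)
        diffs = np.diff(np.concatenate(([80.0], x, [5.0])))
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-10)

    def test_filtration_loop_matches_hand_algebra(self):
        # symbolic elimination gives q = K(Pa-Pb-sigma*dpi)/(1+K(Ra+Rb));
        # frozen instance: q = 1/3, P1 = 29.333..., P2 = 6.0
        c = filtration_loop()
        x, _, _ = newton_solve(c.fun, c.x0, tol=1e-13)
        np.testing.assert_allclose(x, [88.0 / 3.0, 6.0], rtol=1e-12)

    def test_starling_edge_table_is_decreasing(self, params):
        dps = np.linspace(-10, 10, 41)
        table = starling_edge_table(params.venules["cl"], dps)
        assert np.all(np.diff(table) < 0)


class TestResidualAssembly:
    def test_printed_state_residuals_within_audited_bounds(self, params):
        # at the printed operating point the residuals are exactly the
        # documented table inconsistencies: a few ml/min at the l/min-scale
        # brain nodes, below 0.01 ml/min everywhere in the eye
        res = assemble_residuals(REFERENCE.pressure_state(), params,
                                 make_scenario("EARTH", 25.0))
        by_node = res.by_node()
        for node in ("P_I", "P_C", "P_S", "P_B", "P_F", "P_T"):
            assert abs(by_node[node]) < 3.5
        for node, val in by_node.items():
            if node not in ("P_I", "P_C", "P_S", "P_B", "P_F", "P_T"):
                assert abs(val) < 0.01, node

    def test_perturbation_is_local(self, params, earth_solution):
        # circuit locality: nudging one interior choroid node only moves
        # the residuals of that node and its two chain neighbors
        sc = earth_solution.scenario
        x0 = earth_solution.state.as_array()
        r0 = assemble_residuals(x0, params, sc).values
        x1 = x0.copy()
        x1[NODE_INDEX["P_ch_a"]] += 0.5
        r1 = assemble_residuals(x1, params, sc).values
        changed = {NODE_NAMES[i] for i in np.nonzero(
            np.abs(r1 - r0) > 1e-12)[0]}
        assert changed == {"P_ch_in", "P_ch_a", "P_ch_c"}

    def test_non_finite_state_rejected(self, params):
        from eyebrain0d.solver import SolverError
        x = REFERENCE.pressure_state().as_array()
        x[0] = np.nan
        with pytest.raises(SolverError):
            assemble_residuals(x, params, make_scenario("EARTH", 25.0))


class TestSteadyState:
    def test_earth_baseline_anchors(self, earth_solution):
        assert earth_solution.residual_norm <= 1e-9
        assert earth_solution.state.IOP == pytest.approx(14.9662, rel=0.02)
        assert earth_solution.state.P_F == pytest.approx(11.2125, rel=0.02)

    def test_restart_from_solution_is_immediate(self, params,
                                                earth_solution):
        sol = solve_steady_state(params, earth_solution.scenario,
                                 guess=earth_solution.state)
        assert sol.n_iter <= 2
        assert sol.state.IOP == pytest.approx(earth_solution.state.IOP,
                                              abs=1e-9)

    def test_global_conservation(self, params, earth_solution):
        assert abs(global_conservation_residual(
            earth_solution, params)) < 1e-8

    def test_eye_throughput_identity(self, earth_solution):
        # derivable from the five aqueous/ocular balances: the eye returns
        # what it receives, minus the uveoscleral leak, plus the secretion
        f = earth_solution.flows
        assert f.Q_Eye_out - f.Q_Eye_in == pytest.approx(
            f.J_secr - f.J_uv, abs=1e-8)

    def test_flow_balances_hold_at_solution(self, earth_solution):
        f = earth_solution.flows
        assert f.Q_cl == pytest.approx(f.Q_cl_v + f.J_uf, abs=1e-8)
        assert f.J_ah == pytest.approx(f.J_uf + f.J_secr, abs=1e-12)
        assert f.J_ah == pytest.approx(f.J_tm + f.J_uv, abs=1e-8)
        assert f.Q_OA == pytest.approx(2.0 * f.Q_Eye_in, abs=1e-8)
        assert f.Q_CvS == pytest.approx(2.0 * f.Q_Eye_out, abs=1e-8)


class TestCollapseDetection:
    def test_baseline_has_no_collapse(self, earth_solution):
        assert not any(earth_solution.collapse.values())

    def test_zero_transmural_pressure_is_open(self, earth_solution):
        from copy import deepcopy
        sol = deepcopy(earth_solution)
        sol.transmural.dp_cl_v = 0.0
        flags = detect_collapse(sol)
        assert flags["cl_venule"] is False
        sol.transmural.dp_cl_v = -1e-12
        assert detect_collapse(sol)["cl_venule"] is True

    def test_collapsed_element_resistance_exceeds_neutral(self, params):
        sols = continuation_sweep(
            params, "LHDT", np.round(np.arange(25.0, 19.45, -0.05), 6))
        collapsed = [s for s in sols if s.collapse["cl_venule"]]
        assert collapsed, "sweep should reach ciliary collapse"
        for s in collapsed:
            assert s.resistances["R_cl_v"] > params.venules["cl"].alpha


class TestContinuation:
    def test_single_point_grid_reduces_to_plain_solve(self, params,
                                                      earth_solution):
        sols = continuation_sweep(params, "EARTH", [25.0])
        assert len(sols) == 1
        assert sols[0].state.IOP == pytest.approx(
            earth_solution.state.IOP, abs=1e-9)

    def test_non_monotone_grid_rejected(self, params):
        with pytest.raises(ValueError):
            continuation_sweep(params, "EARTH", [25.0, 24.0, 24.5])

    def test_no_hysteresis_on_the_smooth_branch(self, params):
        # ascending and descending sweeps agree wherever no collapse
        # transition is crossed (the branch is unique there)
        grid = np.round(np.arange(25.0, 20.0 - 1e-9, -0.25), 6)
        down = continuation_sweep(params, "LHDT", grid)
        up = continuation_sweep(params, "LHDT", grid[::-1])
        iop_down = [s.state.IOP for s in down]
        iop_up = [s.state.IOP for s in up][::-1]
        np.testing.assert_allclose(iop_down, iop_up, atol=1e-8)


class TestOnsetSearch:
    def test_never_collapsing_compartment_is_not_found(self, params,
                                                       experiment):
        res = experiment.collapse.onset("LHDT", "r_venule")
        assert isinstance(res, OnsetResult)
        assert res.pi_c_star is None
        assert res.status == "never-collapsed"

    def test_onset_brackets_the_sign_change(self, params, experiment):
        res = experiment.collapse.onset("LHDT", "cl_venule")
        assert res.status == "found"
        sols = experiment.solutions["LHDT"]
        for s in sols:
            margin = compartment_margin(s, "cl_venule")
            if s.scenario.pi_c > res.pi_c_star + 1e-3:
                assert margin >= 0.0
            elif s.scenario.pi_c < res.pi_c_star - 1e-3:
                assert margin < 0.0
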