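"""Steady-state solution of the nonlinear eye-brain circuit.

The unknowns are the 31 node pressures of :data:`eyebrain0d.core.NODE_NAMES`.
At each node a Kirchhoff mass balance is written; the edge fluxes follow
from the constitutive laws (Ohm, Starling-resistor, Starling-Landis,
aqueous drainage).  The two eyes are identical by construction, so a single
eye is represented and the factor of two lives only in the coupling
balances (ophthalmic-artery supply and cavernous-sinus drainage).

The resulting nonlinear algebraic system is solved by a damped Newton
iteration with a finite-difference Jacobian; continuation (warm-starting
along a descending oncotic-pressure grid) keeps iterates near the solution
branch across the venous-collapse transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, root

from .core import (NODE_NAMES, FlowSet, PressureState,
                   TransmuralSet, trabecular_outflow, uveoscleral_outflow)
from .lamina import lamina_radial_stress
from .params import REFERENCE, ModelParameters

#: Compliant compartments reported by the collapse detector.
COLLAPSIBLE_COMPARTMENTS = (
    "cl_venule", "ch_venule", "r_venule",
    "crv_seg1", "crv_seg2", "crv_seg3", "crv_seg4",
    "crv_prelaminar", "crv_postlaminar",
)


class SolverError(RuntimeError):
    """Newton iteration failed; carries the last iterate and residual."""

    def __init__(self, message: str, last_state=None, residual_norm=None):
        super().__init__(message)
        self.last_state = last_state
        self.residual_norm = residual_norm


@dataclass
class Residuals:
    """Mass-balance residuals [ml/min], one per unknown node, in the
    canonical node order."""

    values: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.max(np.abs(self.values)))

    def by_node(self) -> dict:
        return {n: float(self.values[i]) for i, n in enumerate(NODE_NAMES)}


@dataclass
class Solution:
    """A converged steady state."""

    state: PressureState
    flows: FlowSet
    transmural: TransmuralSet
    resistances: dict
    P_LC: float
    collapse: dict
    residual_norm: float
    n_iter: int
    scenario: object

    def to_dict(self) -> dict:
        return {"pressures": self.state.to_dict(),
                "flows": self.flows.to_dict(),
                "transmural": self.transmural.to_dict(),
                "resistances": dict(self.resistances),
                "P_LC": self.P_LC,
                "collapse": dict(self.collapse),
                "residual_norm": self.residual_norm,
                "n_iter": self.n_iter}


# ---------------------------------------------------------------------------
# Network evaluation
# ---------------------------------------------------------------------------

#: Switchable Starling elements, in branch-vector order.
BRANCH_ELEMENTS = ("r_v", "ch_v", "cl_v",
                   "crv_1", "crv_2", "crv_3", "crv_4")


def _branch_resistance(elem, dp: float, collapsed: bool | None) -> float:
    """Starling resistance with an optionally frozen branch.

    The tube law is continuous but not differentiable at zero transmural
    pressure; freezing the branch makes the system smooth for Newton, and an
    outer active-set loop (see :func:`solve_steady_state`) flips branches
    until the assumed signs agree with the solution.  A guard keeps the
    frozen-collapse base positive for slightly positive transmural
    pressures encountered mid-iteration."""
    if collapsed is None:
        return elem.resistance(dp)
    if collapsed:
        base = 1.0 - dp / elem.k_p
        if base < 1e-3:
            base = 1e-3
        return elem.alpha * base ** (4.0 / 3.0)
    base = 1.0 + dp / (elem.k_p * elem.k_L)
    if base < 1e-9:
        base = 1e-9
    return elem.alpha * base ** -4


def _network(x: np.ndarray, p: ModelParameters, sc, full: bool = False,
             branches: tuple | None = None):
    """Residual vector (and, when ``full``, every derived quantity) at the
    pressure vector ``x``.  ``branches`` optionally freezes the tube-law
    branch (collapsed or distended) of each switchable element."""
    (P_I, P_C, P_S, P_B, P_F, P_T, P_Eye_in,
     P_cra_in, P_cra_1, P_cra_2, P_cra_3, P_cra_4,
     P_r_a, P_r_c, P_r_v,
     P_crv_1, P_crv_2, P_crv_3, P_crv_4, P_crv_out,
     P_ch_in, P_ch_a, P_ch_c, P_ch_v, P_ch_out,
     P_cl_in, P_cl_a, P_cl_c, P_cl_v, P_cl_out, IOP) = x

    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite pressure state during evaluation")

    br, aq = p.brain, p.aqueous
    P_LC = lamina_radial_stress(IOP, P_T, p.lamina)

    # transmural pressures of the deformable segments
    dp_cra1 = 0.5 * (P_cra_in + P_cra_1) - P_T
    dp_cra2 = 0.5 * (P_cra_1 + P_cra_2) - P_T
    dp_cra3 = 0.5 * (P_cra_2 + P_cra_3) - P_LC
    dp_cra4 = (0.5 * (P_cra_3 + P_cra_4) - IOP) if p.cra4_midpoint \
        else (P_cra_4 - IOP)
    dp_crv1 = 0.5 * (P_crv_1 + P_crv_2) - IOP
    dp_crv2 = 0.5 * (P_crv_2 + P_crv_3) - P_LC
    dp_crv3 = 0.5 * (P_crv_3 + P_crv_4) - P_T
    dp_crv4 = 0.5 * (P_crv_4 + P_crv_out) - P_T
    dp_rv = P_r_v - IOP
    dp_chv = P_ch_v - IOP
    dp_clv = P_cl_v - IOP

    cra, crv = p.cra, p.crv
    R_cra = tuple(cra.resistance(n + 1, dp)
                  for n, dp in enumerate((dp_cra1, dp_cra2, dp_cra3, dp_cra4)))
    b = branches if branches is not None else (None,) * 7
    R_crv = tuple(
        _branch_resistance(crv.segment(n + 1), dp, b[3 + n])
        for n, dp in enumerate((dp_crv1, dp_crv2, dp_crv3, dp_crv4)))
    R_rv = _branch_resistance(p.venules["r"], dp_rv, b[0])
    R_chv = _branch_resistance(p.venules["ch"], dp_chv, b[1])
    R_clv = _branch_resistance(p.venules["cl"], dp_clv, b[2])

    # edge fluxes -- brain and coupling
    q_A = (sc.P_A - P_I) / p.R_A_edge
    q_IC = (P_I - P_C) / (br.R_I + br.R_C)
    q_CS = (P_C - P_S) / (br.R_C + br.R_S)
    Q_CB = sc.K_CB * ((P_C - P_B) - sc.sigma_CB * sc.delta_pi_CB)
    q_BT = (P_B - P_T) / br.R_BT
    q_FT = (P_F - P_T) / br.R_FT
    q_FB = (P_F - P_B) / br.R_FB
    q_TS = (P_T - P_S) / br.R_TS
    q_TV = (P_T - sc.P_V) / p.R_TV
    q_SV = (P_S - sc.P_V) / p.R_SV_edge
    q_oa = (P_I - P_Eye_in) / p.R_I_OA          # total, both eyes

    # edge fluxes -- one eye, retinal pathway
    q_ri = (P_Eye_in - P_cra_in) / p.R_cra_in
    q_c1 = (P_cra_in - P_cra_1) / R_cra[0]
    q_c2 = (P_cra_1 - P_cra_2) / R_cra[1]
    q_c3 = (P_cra_2 - P_cra_3) / R_cra[2]
    q_c4 = (P_cra_3 - P_cra_4) / R_cra[3]
    q_ra = (P_cra_4 - P_r_a) / p.R_r_a1
    q_rb = (P_r_a - P_r_c) / (p.R_r_a2 + p.R_r_c1)
    q_rc = (P_r_c - P_r_v) / (p.R_r_c2 + R_rv)
    q_rd = (P_r_v - P_crv_1) / R_rv
    q_v1 = (P_crv_1 - P_crv_2) / R_crv[0]
    q_v2 = (P_crv_2 - P_crv_3) / R_crv[1]
    q_v3 = (P_crv_3 - P_crv_4) / R_crv[2]
    q_v4 = (P_crv_4 - P_crv_out) / R_crv[3]
    q_ro = (P_crv_out - P_S) / p.R_crv_out

    # choroid
    q_hi = (P_Eye_in - P_ch_in) / p.R_ch_in
    q_ha = (P_ch_in - P_ch_a) / p.R_ch_a1
    q_hb = (P_ch_a - P_ch_c) / (p.R_ch_a2 + p.R_ch_c1)
    q_hc = (P_ch_c - P_ch_v) / (p.R_ch_c2 + R_chv)
    q_hd = (P_ch_v - P_ch_out) / R_chv
    q_ho = (P_ch_out - P_S) / p.R_ch_out

    # ciliary body
    q_li = (P_Eye_in - P_cl_in) / p.R_cl_in
    q_la = (P_cl_in - P_cl_a) / p.R_cl_a1
    q_lb = (P_cl_a - P_cl_c) / (p.R_cl_a2 + p.R_cl_c1)
    q_lc = (P_cl_c - P_cl_v) / (p.R_cl_c2 + R_clv)
    q_ld = (P_cl_v - P_cl_out) / R_clv
    q_lo = (P_cl_out - P_S) / p.R_cl_out

    # aqueous humor
    J_uf = aq.L_in * ((P_cl_c - IOP) - aq.sigma_p * sc.delta_pi_p)
    R_tm, J_tm = trabecular_outflow(IOP, P_S, aq)
    R_uv, J_uv = uveoscleral_outflow(IOP, aq)

    res = np.array((
        q_A - q_IC - q_oa,                                   # I
        q_IC - Q_CB - q_CS - p.Q_CF,                         # C
        q_CS + q_TS + 2.0 * (q_ro + q_ho + q_lo + J_tm) - q_SV,   # S
        q_FB + Q_CB - q_BT,                                  # B
        p.Q_CF - q_FT - q_FB,                                # F
        q_FT + q_BT - q_TV - q_TS,                           # T
        0.5 * q_oa - q_ri - q_hi - q_li,                     # Eye_in
        q_ri - q_c1,                                         # cra_in
        q_c1 - q_c2, q_c2 - q_c3, q_c3 - q_c4, q_c4 - q_ra,  # cra 1..4
        q_ra - q_rb, q_rb - q_rc, q_rc - q_rd,               # r_a, r_c, r_v
        q_rd - q_v1, q_v1 - q_v2, q_v2 - q_v3, q_v3 - q_v4,  # crv 1..4
        q_v4 - q_ro,                                         # crv_out
        q_hi - q_ha, q_ha - q_hb, q_hb - q_hc, q_hc - q_hd,  # ch chain
        q_hd - q_ho,                                         # ch_out
        q_li - q_la, q_la - q_lb, q_lb - q_lc - J_uf,        # cl chain
        q_lc - q_ld, q_ld - q_lo,                            # cl_v, cl_out
        J_uf + aq.J_secr - J_tm - J_uv,                      # IOP
    ))

    if not full:
        return res, None

    state = PressureState.from_array(x)
    transmural = TransmuralSet(
        dp_r_v=dp_rv, dp_ch_v=dp_chv, dp_cl_v=dp_clv,
        dp_cra=(dp_cra1, dp_cra2, dp_cra3, dp_cra4),
        dp_crv=(dp_crv1, dp_crv2, dp_crv3, dp_crv4))
    Q_Eye_in = q_ri + q_hi + q_li
    Q_Eye_out = q_ro + q_ho + q_lo + J_tm
    flows = FlowSet(
        Q_A=q_A, Q_IC=q_IC, Q_CB=Q_CB, Q_CS=q_CS, Q_FB=q_FB, Q_FT=q_FT,
        Q_BT=q_BT, Q_TS=q_TS, Q_TV=q_TV, Q_SV=q_SV,
        Q_OA=q_oa, Q_CvS=2.0 * Q_Eye_out,
        Q_Eye_in=Q_Eye_in, Q_Eye_out=Q_Eye_out,
        Q_r=q_ri, Q_ch=q_hi, Q_cl=q_li, Q_cl_v=q_ld,
        J_uf=J_uf, J_secr=aq.J_secr, J_ah=J_uf + aq.J_secr,
        J_tm=J_tm, J_uv=J_uv)
    resistances = {
        "R_cra_1": R_cra[0], "R_cra_2": R_cra[1],
        "R_cra_3": R_cra[2], "R_cra_4": R_cra[3],
        "R_crv_1": R_crv[0], "R_crv_2": R_crv[1],
        "R_crv_3": R_crv[2], "R_crv_4": R_crv[3],
        "R_r_v": R_rv, "R_ch_v": R_chv, "R_cl_v": R_clv,
        "R_tm": R_tm, "R_uv": R_uv,
    }
    extras = {"state": state, "transmural": transmural, "flows": flows,
              "resistances": resistances, "P_LC": P_LC}
    return res, extras


def assemble_residuals(state, params: ModelParameters, scenario) -> Residuals:
    """Kirchhoff mass-balance residuals at an arbitrary pressure state."""
    x = state.as_array() if isinstance(state, PressureState) \
        else np.asarray(state, dtype=float)
    res, _ = _network(x, params, scenario)
    return Residuals(values=res)


# ---------------------------------------------------------------------------
# Damped Newton iteration
# ---------------------------------------------------------------------------

def newton_solve(fun, x0, tol: float = 1e-9, max_iter: int = 80,
                 max_halvings: int = 30, max_step: float = 5.0,
                 bound: float = 1e3):
    """Damped Newton on a generic square system ``fun(x) -> residuals``.

    The Jacobian is built by central finite differences.  Each step is
    capped at ``max_step`` (infinity norm) and halved (up to
    ``max_halvings`` times) until the residual infinity norm decreases;
    iterates leaving the physically sensible box ``|x| < bound`` are
    rejected, which keeps the iteration away from the degenerate
    pinched-off configuration of a fully collapsed vessel (both adjacent
    resistances infinite, node pressure unbounded).  Returns
    ``(x, n_iter, residual_norm)``.
    """
    x = np.array(x0, dtype=float)
    f = np.asarray(fun(x), dtype=float)
    norm = float(np.max(np.abs(f)))
    merit = float(f @ f)
    n = x.size
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return x, it - 1, norm
        # central differences: the tube-law curvature near a pinned
        # (just-collapsed) venule is large enough that first-order forward
        # differences give a Jacobian too inaccurate for Newton to descend
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-6 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += h
            xm = x.copy()
            xm[j] -= h
            J[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular Jacobian at iteration {it}",
                              last_state=x, residual_norm=norm) from exc
        m = float(np.max(np.abs(dx)))
        if m > max_step:
            dx *= max_step / m
        # line search on the least-squares merit (the Newton direction is a
        # descent direction for it); convergence is still judged in the
        # infinity norm
        step = 1.0
        for _ in range(max_halvings + 1):
            x_new = x + step * dx
            merit_new = math.inf
            if np.max(np.abs(x_new)) < bound:
                try:
                    f_new = np.asarray(fun(x_new), dtype=float)
                    merit_new = float(f_new @ f_new)
                except (SolverError, FloatingPointError, ValueError):
                    merit_new = math.inf
            if merit_new < merit:
                break
            step *= 0.5
        else:
            raise SolverError(
                f"damping failed at iteration {it} (residual {norm:.3e})",
                last_state=x, residual_norm=norm)
        x, f, merit = x_new, f_new, merit_new
        norm = float(np.max(np.abs(f)))
    if norm <= tol:
        return x, max_iter, norm
    raise SolverError(
        f"no convergence after {max_iter} iterations (residual {norm:.3e})",
        last_state=x, residual_norm=norm)


def _solve_frozen(fun, x0: np.ndarray, tol: float, max_iter: int,
                  use_fallback: bool = True):
    """Solve one frozen-branch (smooth) system.

    Damped Newton handles the vast majority of points in one or two
    iterations.  Near a collapse transition the system becomes extremely
    stiff (the venule buckling pressures are of order 0.01 mmHg, so the
    collapsed elements pin their transmural pressures within microns of
    mercury of zero); there the Newton line search can stall, and the
    solve falls back to a bounded trust-region least-squares pass followed
    by a Powell-hybrid polish.  The bounds also exclude the degenerate
    pinched-off configuration (unbounded node pressure between two
    infinite resistances)."""
    try:
        return newton_solve(fun, x0, tol=tol, max_iter=max_iter)
    except SolverError as first:
        if not use_fallback:
            raise
        # restart the fallback from the warm start, not from the stalled
        # iterate: continuation must follow the branch connected to the
        # previous point, and the stalled iterate may already have drifted
        # toward a coexisting (deep-collapse) solution
        lb = np.full(x0.size, -20.0)
        ub = np.full(x0.size, 150.0)
        res = least_squares(fun, np.clip(x0, lb, ub), jac="2-point",
                            method="trf",
                            bounds=(lb, ub), xtol=3e-16, ftol=3e-16,
                            gtol=3e-16, x_scale="jac")
        x = res.x
        norm = float(np.max(np.abs(fun(x))))
        if norm > tol:
            polished = root(fun, x, method="hybr", options={"xtol": 1e-15})
            pnorm = float(np.max(np.abs(fun(polished.x))))
            if pnorm < norm:
                x, norm = polished.x, pnorm
        if norm > tol:
            raise SolverError(
                f"fallback solvers stalled at residual {norm:.3e}",
                last_state=x, residual_norm=norm) from first
        return x, -1, norm


def _branch_signs(x: np.ndarray, p: ModelParameters, sc,
                  dead_band: float = 1e-9) -> tuple:
    """Collapse flags of the switchable elements at ``x`` (None within a
    dead band of zero transmural pressure, where both branches coincide)."""
    _, extras = _network(x, p, sc, full=True)
    t = extras["transmural"]
    dps = (t.dp_r_v, t.dp_ch_v, t.dp_cl_v) + tuple(t.dp_crv)
    return tuple(None if abs(dp) <= dead_band else (dp < 0.0) for dp in dps)


def solve_steady_state(params: ModelParameters, scenario,
                       guess: PressureState | None = None,
                       tol: float = 1e-9, max_iter: int = 30,
                       max_branch_flips: int = 20,
                       use_fallback: bool = True) -> Solution:
    """Solve the full network to a mass-balance residual infinity norm of
    ``tol`` [ml/min].  The default initial guess is the packaged reference
    operating point; pass a previous :class:`Solution` state to warm-start
    a continuation.

    The tube law is continuous but has a derivative kink at zero transmural
    pressure, which defeats a plain Newton iteration exactly at a collapse
    transition.  The solve therefore runs an active-set loop: each
    switchable element's branch is frozen (making the system smooth), the
    damped Newton iteration converges, and any element whose transmural
    pressure sign disagrees with its assumed branch is flipped before
    re-solving from the converged point.  At the transition itself both
    branches coincide, so the loop terminates."""
    x0 = (guess or REFERENCE.pressure_state()).as_array()

    branches = _branch_signs(x0, params, scenario)
    x, n_iter, norm = x0, 0, math.inf
    for _flip in range(max_branch_flips):
        def fun(x_, b=branches):
            res, _ = _network(x_, params, scenario, branches=b)
            return res

        x, it, norm = _solve_frozen(fun, x0, tol=tol, max_iter=max_iter,
                                    use_fallback=use_fallback)
        n_iter += max(it, 1)
        actual = _branch_signs(x, params, scenario)
        consistent = all(a is None or b is None or a == b
                         for a, b in zip(actual, branches))
        if consistent:
            break
        branches = tuple(b if a is None else a
                         for a, b in zip(actual, branches))
        x0 = x
    else:
        raise SolverError(
            "tube-law branch assignment did not settle",
            last_state=x, residual_norm=norm)
    res_free, _ = _network(x, params, scenario)
    norm = float(np.max(np.abs(res_free)))
    _, extras = _network(x, params, scenario, full=True)
    sol = Solution(
        state=extras["state"], flows=extras["flows"],
        transmural=extras["transmural"], resistances=extras["resistances"],
        P_LC=extras["P_LC"], collapse={}, residual_norm=norm,
        n_iter=n_iter, scenario=scenario)
    sol.collapse = detect_collapse(sol)
    return sol


# ---------------------------------------------------------------------------
# Collapse detection and continuation
# ---------------------------------------------------------------------------

def compartment_margin(sol: Solution, compartment: str) -> float:
    """Transmural pressure of a compliant compartment (minimum over the
    member segments for the grouped pre-/post-laminar vein labels); the
    compartment is collapsed exactly when this is negative."""
    t = sol.transmural
    if compartment == "cl_venule":
        return t.dp_cl_v
    if compartment == "ch_venule":
        return t.dp_ch_v
    if compartment == "r_venule":
        return t.dp_r_v
    if compartment.startswith("crv_seg"):
        return t.dp_crv[int(compartment[-1]) - 1]
    if compartment == "crv_prelaminar":
        return min(t.dp_crv[0], t.dp_crv[1])
    if compartment == "crv_postlaminar":
        return min(t.dp_crv[2], t.dp_crv[3])
    raise KeyError(compartment)


def detect_collapse(sol: Solution) -> dict:
    """Collapse flags per compliant compartment: strictly negative
    transmural pressure.  Zero transmural pressure is *not* collapsed.
    The prelaminar group is vein segments 1-2 (intraocular side, external
    pressure IOP / lamina stress), the postlaminar group segments 3-4
    (retrobulbar side, external pressure extraventricular CSF)."""
    return {c: bool(compartment_margin(sol, c) < 0.0)
            for c in COLLAPSIBLE_COMPARTMENTS}


def continuation_sweep(params: ModelParameters, scenario_kind: str,
                       pi_c_grid, tol: float = 1e-9,
                       **scenario_kwargs) -> list[Solution]:
    """Solve sequentially along an oncotic-pressure grid, warm-starting
    each point from the previous solution.  The grid must be strictly
    monotone (descending is the canonical order; ascending gives identical
    solutions -- there is no hysteresis on the single solution branch)."""
    from .scenarios import make_scenario

    grid = [float(v) for v in pi_c_grid]
    if len(grid) > 1:
        diffs = np.diff(grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("pi_c grid must be strictly monotone")
    solutions: list[Solution] = []
    prev: tuple[float, Solution] | None = None
    for pi_c in grid:
        sol = _solve_continued(params, scenario_kind, pi_c, prev, tol,
                               scenario_kwargs)
        solutions.append(sol)
        prev = (pi_c, sol)
    return solutions


def _solve_continued(params: ModelParameters, scenario_kind: str,
                     pi_c: float, prev: tuple[float, "Solution"] | None,
                     tol: float, scenario_kwargs: dict,
                     min_step: float = 1e-5) -> "Solution":
    """Solve at ``pi_c`` warm-started from ``prev`` = (pi_prev, solution),
    recursively inserting intermediate oncotic pressures when the direct
    solve fails (the solution branch is near-vertical at a collapse
    transition, so a fixed grid step can overshoot the basin of
    attraction)."""
    from .scenarios import make_scenario

    def attempt(target: float, guess, use_fallback: bool):
        sc = make_scenario(scenario_kind, target, **scenario_kwargs)
        return solve_steady_state(params, sc, guess=guess, tol=tol,
                                  use_fallback=use_fallback)

    if prev is None:
        return attempt(pi_c, None, True)
    pi_prev, sol_prev = prev
    step = abs(pi_c - pi_prev)
    try:
        # while the recursion is still free to refine, let a hard point
        # fail fast; the expensive trust-region fallback is reserved for
        # steps already near the refinement floor
        return attempt(pi_c, sol_prev.state, step <= 100.0 * min_step)
    except SolverError as exc:
        if abs(pi_c - pi_prev) <= min_step:
            raise SolverError(
                f"{scenario_kind} continuation failed at pi_c={pi_c}: {exc}",
                last_state=exc.last_state,
                residual_norm=exc.residual_norm) from exc
        mid = 0.5 * (pi_prev + pi_c)
        sol_mid = _solve_continued(params, scenario_kind, mid, prev, tol,
                                   scenario_kwargs, min_step)
        return _solve_continued(params, scenario_kind, pi_c, (mid, sol_mid),
                                tol, scenario_kwargs, min_step)


@dataclass
class OnsetResult:
    """Outcome of a collapse-onset search.

    ``pi_c_star`` is the largest oncotic pressure at which the compartment
    is collapsed (None when the transmural pressure does not change sign in
    the search interval); ``status`` is one of ``found``,
    ``never-collapsed`` or ``always-collapsed``.
    """

    compartment: str
    pi_c_star: float | None
    status: str


def find_collapse_onset(params: ModelParameters, scenario_kind: str,
                        compartment: str, pi_lo: float = 18.5,
                        pi_hi: float = 25.0, xtol: float = 1e-3,
                        sweep: list[Solution] | None = None,
                        **scenario_kwargs) -> OnsetResult:
    """Bisection for the oncotic pressure at which a compartment's
    transmural pressure first becomes negative, each evaluation being a
    warm-started steady-state solve.

    ``sweep`` may supply previously computed solutions of the same scenario
    (descending continuation); they seed the solution cache so the search
    only has to bisect within one grid interval."""
    from .scenarios import make_scenario

    cache: dict[float, Solution] = {}
    if sweep:
        for s_ in sweep:
            if pi_lo <= s_.scenario.pi_c <= pi_hi:
                cache[float(s_.scenario.pi_c)] = s_

    def solve_at(pi_c: float) -> Solution:
        if pi_c in cache:
            return cache[pi_c]
        prev = None
        if cache:
            nearest = min(cache, key=lambda k: abs(k - pi_c))
            prev = (nearest, cache[nearest])
        sol = _solve_continued(params, scenario_kind, pi_c, prev, 1e-9,
                               scenario_kwargs)
        cache[pi_c] = sol
        return sol

    g_hi = compartment_margin(solve_at(pi_hi), compartment)
    g_lo = compartment_margin(solve_at(pi_lo), compartment)
    if g_hi < 0.0:
        return OnsetResult(compartment, None, "always-collapsed")
    if g_lo >= 0.0:
        return OnsetResult(compartment, None, "never-collapsed")
    lo, hi = pi_lo, pi_hi  # margin < 0 at lo, >= 0 at hi
    for k in sorted(cache):
        if compartment_margin(cache[k], compartment) < 0.0:
            lo = max(lo, k)
        elif k < hi:
            hi = min(hi, k)
    lo, hi = min(lo, hi), max(lo, hi)
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if compartment_margin(solve_at(mid), compartment) < 0.0:
            lo = mid
        else:
            hi = mid
    return OnsetResult(compartment, lo, "found")


# ---------------------------------------------------------------------------
# Conservation diagnostics
# ---------------------------------------------------------------------------

def global_conservation_residual(sol: Solution,
                                 params: ModelParameters | None = None
                                 ) -> float:
    """Net volume imbalance of the whole network [ml/min]: arterial inflow
    plus the aqueous secretion sources (one per eye) minus the outflow to
    the central veins and the uveoscleral leaks.  CSF production does not
    appear: it is an internal transfer, extracted from the cerebral
    capillaries and injected into the ventricular compartment.  Zero to
    solver tolerance at any converged solution."""
    f = sol.flows
    return f.Q_A + 2.0 * f.J_secr - f.Q_SV - f.Q_TV - 2.0 * f.J_uv
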