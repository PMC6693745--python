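"""Environment scenarios: Earth, head-down tilt and microgravity.

The fluid-shift environments are encoded as boundary-condition and
blood-brain-barrier modifications of the baseline supine-Earth model:

EARTH
    baseline central pressures, intact barrier;
LHDT (long head-down tilt, 6 degrees)
    both central boundary pressures raised by the hydrostatic column
    G*sin(theta), with G = rho*g*H the pressure equivalent of the
    heart-to-head height H; intact barrier;
M0
    microgravity, intact blood-brain barrier: zero hydrostatic offsets and
    central venous pressure set to zero;
M1 / M2
    microgravity with a progressively weakened blood-brain barrier
    (filtration coefficient K_CB raised, reflection coefficient sigma_CB
    lowered).

The severity of the cephalad fluid shift is swept through the blood
(colloid) oncotic pressure pi_c, which enters the two filtration laws as
delta_pi_p = pi_c - pi_ah (aqueous ultrafiltration, pi_ah ~ 0) and
delta_pi_CB = pi_c - pi_B (blood-brain barrier, interstitial pi_B = 4 mmHg
so that the physiological pi_c = 25 mmHg reproduces the baseline
difference of 21 mmHg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as tables
from .core import InvalidParameterError
from .params import ModelParameters
from .solver import (COLLAPSIBLE_COMPARTMENTS, OnsetResult, Solution,
                     continuation_sweep, find_collapse_onset)

SCENARIO_KINDS = ("EARTH", "LHDT", "M0", "M1", "M2")

#: Barrier coefficients (K_CB [ml/mmHg/min], sigma_CB [-]) per environment.
BARRIER = {
    "EARTH": (0.0665, 1.0),
    "LHDT": (0.0665, 1.0),
    "M0": (0.0665, 1.0),
    "M1": (0.1164, 0.5714),
    "M2": (0.1330, 0.5),
}

PI_AH = 0.0   # aqueous oncotic pressure [mmHg]
PI_B = 4.0    # brain interstitial oncotic pressure [mmHg]

#: Default hydrostatic coefficient G = rho*g*H [mmHg] and tilt angle [deg].
G_DEFAULT = 24.0
THETA_DEFAULT = 6.0


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation environment."""

    kind: str
    pi_c: float
    P_A: float
    P_V: float
    K_CB: float
    sigma_CB: float
    delta_pi_p: float
    delta_pi_CB: float
    G: float = G_DEFAULT
    theta: float = THETA_DEFAULT


def oncotic_offsets(pi_c: float) -> tuple[float, float]:
    """Oncotic pressure differences (delta_pi_p, delta_pi_CB) [mmHg] for a
    blood oncotic pressure ``pi_c``."""
    if not pi_c > 0.0:
        raise InvalidParameterError(f"pi_c must be positive, got {pi_c}")
    return pi_c - PI_AH, pi_c - PI_B


def make_scenario(kind: str, pi_c: float = 25.0, G: float = G_DEFAULT,
                  theta: float = THETA_DEFAULT,
                  P_A: float | None = None,
                  P_V: float | None = None) -> Scenario:
    """Scenario factory.  ``kind`` determines the central boundary
    pressures and barrier coefficients; ``pi_c`` sets the oncotic
    differences.  ``P_A``/``P_V`` override the *pre-offset* central
    pressures; the barrier coefficients are derived fields and cannot be
    overridden here (use a custom :class:`Scenario` for that)."""
    kind = kind.upper()
    if kind not in SCENARIO_KINDS:
        raise InvalidParameterError(
            f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    if not 10.0 <= pi_c <= 30.0:
        raise InvalidParameterError(
            f"pi_c = {pi_c} mmHg outside the sane range [10, 30]")
    base_PA = tables.P_A_BASE if P_A is None else float(P_A)
    base_PV = tables.P_V_BASE if P_V is None else float(P_V)
    offset = G * math.sin(math.radians(theta)) if kind == "LHDT" else 0.0
    if kind in ("M0", "M1", "M2"):
        P_A_eff, P_V_eff = base_PA, 0.0
    else:
        P_A_eff, P_V_eff = base_PA + offset, base_PV + offset
    K_CB, sigma_CB = BARRIER[kind]
    dpp, dpcb = oncotic_offsets(pi_c)
    return Scenario(kind=kind, pi_c=pi_c, P_A=P_A_eff, P_V=P_V_eff,
                    K_CB=K_CB, sigma_CB=sigma_CB,
                    delta_pi_p=dpp, delta_pi_CB=dpcb, G=G, theta=theta)


def normalized_flows(solution: Solution, baseline: Solution) -> dict:
    """Perfusion of each ocular bed relative to its baseline value."""
    out = {}
    for bed, attr in (("r", "Q_r"), ("ch", "Q_ch"), ("cl", "Q_cl")):
        qb = getattr(baseline.flows, attr)
        if qb == 0.0:
            raise ZeroDivisionError(f"baseline {attr} is zero")
        out[bed] = getattr(solution.flows, attr) / qb
    return out


@dataclass
class CollapseReport:
    """Collapse onsets per scenario and compartment: the largest oncotic
    pressure at which each compartment is collapsed."""

    onsets: dict = field(default_factory=dict)  # (kind, compartment) -> OnsetResult

    def onset(self, kind: str, compartment: str) -> OnsetResult:
        return self.onsets[(kind, compartment)]

    def to_json_dict(self) -> dict:
        out: dict = {}
        for (kind, comp), res in self.onsets.items():
            out.setdefault(kind, {})[comp] = {
                "pi_c_star": res.pi_c_star, "status": res.status}
        return out


@dataclass
class ExperimentResult:
    """Sweep tables and collapse report for a set of scenarios."""

    sweep: pd.DataFrame
    collapse: CollapseReport
    baseline: Solution
    solutions: dict  # kind -> list[Solution], descending pi_c


def run_experiment(params: ModelParameters,
                   kinds=("LHDT", "M0", "M1", "M2"),
                   pi_c_grid=None, G: float = G_DEFAULT,
                   theta: float = THETA_DEFAULT,
                   onset_compartments=("cl_venule", "ch_venule", "r_venule",
                                       "crv_prelaminar", "crv_postlaminar"),
                   ) -> ExperimentResult:
    """Run continuation sweeps over the oncotic-pressure grid for each
    scenario kind, normalize the ocular perfusions against the Earth
    baseline (pi_c = 25 mmHg), and locate every collapse onset.

    The default grid descends from 25 to 18.5 mmHg in steps of 0.05 mmHg,
    fine enough to localize the collapse transitions.
    """
    if pi_c_grid is None:
        pi_c_grid = np.round(np.arange(25.0, 18.5 - 1e-9, -0.05), 6)
    grid = [float(v) for v in pi_c_grid]
    if len(grid) > 1 and grid[0] < grid[-1]:
        grid = grid[::-1]

    baseline = continuation_sweep(params, "EARTH", [25.0], G=G, theta=theta)[0]

    rows = []
    solutions: dict[str, list[Solution]] = {}
    report = CollapseReport()
    for kind in kinds:
        sols = continuation_sweep(params, kind, grid, G=G, theta=theta)
        solutions[kind] = sols
        for sol in sols:
            ratios = normalized_flows(sol, baseline)
            row = {
                "scenario": kind, "pi_c": sol.scenario.pi_c,
                "IOP": sol.state.IOP, "ICP": sol.state.P_F,
                "CSFp": sol.state.P_T, "P_LC": sol.P_LC,
                "Q_r": sol.flows.Q_r, "Q_ch": sol.flows.Q_ch,
                "Q_cl": sol.flows.Q_cl,
                "Q_r_norm": ratios["r"], "Q_ch_norm": ratios["ch"],
                "Q_cl_norm": ratios["cl"],
            }
            for comp in COLLAPSIBLE_COMPARTMENTS:
                row[f"collapsed_{comp}"] = sol.collapse[comp]
            rows.append(row)
        for comp in onset_compartments:
            report.onsets[(kind, comp)] = find_collapse_onset(
                params, kind, comp, pi_lo=min(grid), pi_hi=max(grid),
                sweep=sols, G=G, theta=theta)
    sweep = pd.DataFrame(rows)
    return ExperimentResult(sweep=sweep, collapse=report, baseline=baseline,
                            solutions=solutions)
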