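"""Toy hydraulic networks with closed-form solutions.

These serve as independent oracles for the nonlinear solver: if the Newton
machinery cannot reproduce a resistive ladder or a two-compartment
filtration loop whose answer is known by hand, nothing downstream can be
trusted.  They are part of the public surface so that users extending the
solver can re-run the same checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StarlingElement


@dataclass
class ToyCircuit:
    """A residual function with its known solution."""

    name: str
    fun: object               # callable: x (n,) -> residuals (n,)
    x0: np.ndarray            # a reasonable initial guess
    exact: np.ndarray         # the analytic solution


def resistive_ladder(n_interior: int, P_left: float, P_right: float,
                     R: float = 1.0) -> ToyCircuit:
    """A chain of ``n_interior + 1`` equal resistors between two fixed
    boundary pressures.  The interior node pressures are the linear
    interpolation between the boundaries; with one interior node the
    solution is exactly the boundary average."""
    n_edges = n_interior + 1

    def fun(x):
        p = np.concatenate(([P_left], np.asarray(x, float), [P_right]))
        q = (p[:-1] - p[1:]) / R
        return q[:-1] - q[1:]

    exact = P_left + (P_right - P_left) * np.arange(1, n_edges) / n_edges
    x0 = np.full(n_interior, 0.5 * (P_left + P_right))
    return ToyCircuit("ladder", fun, x0, exact)


def starling_edge_table(elem: StarlingElement, dps) -> np.ndarray:
    """Tabulated resistance of a single Starling element over a grid of
    transmural pressures (an oracle for interpolation-free spot checks)."""
    return np.array([elem.resistance(float(dp)) for dp in dps])


def filtration_loop(P_a: float = 30.0, P_b: float = 5.0, R_a: float = 2.0,
                    R_b: float = 3.0, K: float = 0.1, sigma: float = 1.0,
                    dpi: float = 20.0) -> ToyCircuit:
    """Two nodes in series: boundary -> resistor -> filtration barrier ->
    resistor -> boundary.  At equilibrium one flux q runs through the whole
    chain, and eliminating the node pressures by hand gives

        q = K*(P_a - P_b - sigma*dpi) / (1 + K*(R_a + R_b)),
        P_1 = P_a - q*R_a,   P_2 = P_b + q*R_b.
    """

    def fun(x):
        p1, p2 = x
        q_in = (P_a - p1) / R_a
        q_f = K * ((p1 - p2) - sigma * dpi)
        q_out = (p2 - P_b) / R_b
        return np.array([q_in - q_f, q_f - q_out])

    q = K * (P_a - P_b - sigma * dpi) / (1.0 + K * (R_a + R_b))
    exact = np.array([P_a - q * R_a, P_b + q * R_b])
    x0 = np.array([P_a, P_b])
    return ToyCircuit("filtration-loop", fun, x0, exact)


def fixture_circuits() -> list[ToyCircuit]:
    """The standard set of solver oracles."""
    return [
        resistive_ladder(1, 10.0, 0.0),
        resistive_ladder(7, 80.0, 5.0, R=2.5),
        filtration_loop(),
    ]
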