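"""Constitutive elements of the 0-D eye-brain fluid network.

This module holds the domain types and the pure constitutive laws of the
model -- Poiseuille resistances, the Starling-resistor tube law for
collapsible venous segments, Starling-Landis transcapillary filtration, the
hydraulic analogue of Ohm's law, and the pressure-dependent aqueous-humor
drainage laws (trabecular and uveoscleral).  There is no solver logic here:
everything is a deterministic function of its arguments.

Unit system: mmHg, ml, min (see :mod:`eyebrain0d.units`).  Viscosities are
stored internally in mmHg*min; constructors accept the conventional mmHg*s
with an explicit conversion.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, fields

from .units import SECONDS_PER_MINUTE


class InvalidParameterError(ValueError):
    """A physical parameter violates its admissible range."""


class DegenerateStateError(RuntimeError):
    """A pressure state puts a constitutive law outside its valid regime."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties of blood in a vessel compartment.

    Parameters
    ----------
    mu : float
        Dynamic viscosity in mmHg*min.  Density enters the Poiseuille
        resistance only through the combination 8*pi*mu/rho multiplied back
        by rho, so it cancels and is not stored.
    """

    mu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0 and math.isfinite(self.mu)):
            raise InvalidParameterError(f"viscosity must be positive, got {self.mu}")

    @classmethod
    def from_mmhg_s(cls, mu_mmhg_s: float) -> "FluidProperties":
        """Build from a viscosity quoted in mmHg*s (the usual convention)."""
        return cls(mu=mu_mmhg_s / SECONDS_PER_MINUTE)

    @property
    def mu_mmhg_s(self) -> float:
        return self.mu * SECONDS_PER_MINUTE


@dataclass(frozen=True)
class VesselWall:
    """Elastic properties of a deformable vessel wall.

    E : Young's modulus [mmHg]; h : wall thickness [cm]; nu : Poisson ratio.
    """

    E: float
    h: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0.0:
            raise InvalidParameterError(f"Young's modulus must be positive, got {self.E}")
        if not self.h > 0.0:
            raise InvalidParameterError(f"wall thickness must be positive, got {self.h}")
        if not (-1.0 < self.nu < 0.5):
            raise InvalidParameterError(
                f"Poisson ratio must lie in (-1, 0.5), got {self.nu}")


@dataclass(frozen=True)
class VesselGeometry:
    """Representative cross-sectional area A [cm^2] and length L [cm]."""

    A: float
    L: float

    def __post_init__(self) -> None:
        if not self.A > 0.0:
            raise InvalidParameterError(f"area must be positive, got {self.A}")
        if not self.L > 0.0:
            raise InvalidParameterError(f"length must be positive, got {self.L}")


@dataclass(frozen=True)
class AqueousParameters:
    """Aqueous-humor production and drainage parameters (internal ml units).

    L_in : ultrafiltration conductance [ml/min/mmHg]
    sigma_p : protein reflection coefficient [-]
    delta_pi_p : oncotic pressure difference plasma - aqueous [mmHg]
    k1 [ml/min], k2 [mmHg] : uveoscleral saturation constants
    R0 [mmHg*min/ml], kappa [1/mmHg] : trabecular resistance law
    J_secr [ml/min] : active ionic secretion rate
    """

    L_in: float
    sigma_p: float
    delta_pi_p: float
    k1: float
    k2: float
    R0: float
    kappa: float
    J_secr: float

    def __post_init__(self) -> None:
        for name in ("L_in", "k1", "k2", "R0", "kappa", "J_secr"):
            if not getattr(self, name) > 0.0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 <= self.sigma_p <= 1.0:
            raise InvalidParameterError("sigma_p must lie in [0, 1]")
        if self.delta_pi_p < 0.0:
            raise InvalidParameterError("delta_pi_p must be >= 0")


@dataclass(frozen=True)
class BrainParameters:
    """Cerebral blood / CSF / interstitial network constants (ml units)."""

    R_I: float
    R_C: float
    R_S: float
    K_CB: float
    sigma_CB: float
    delta_pi_CB: float
    R_BT: float
    R_FT: float
    R_FB: float
    R_TS: float
    Q_CF: float

    def __post_init__(self) -> None:
        for name in ("R_I", "R_C", "R_S", "R_BT", "R_FT", "R_FB", "R_TS"):
            if not getattr(self, name) > 0.0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 <= self.sigma_CB <= 1.0:
            raise InvalidParameterError("sigma_CB must lie in [0, 1]")
        if not self.Q_CF > 0.0:
            raise InvalidParameterError("Q_CF must be positive")


#: Unknown node pressures, in canonical solver order.
NODE_NAMES: tuple[str, ...] = (
    # brain
    "P_I", "P_C", "P_S", "P_B", "P_F", "P_T",
    # eye-brain coupling
    "P_Eye_in",
    # retinal pathway
    "P_cra_in", "P_cra_1", "P_cra_2", "P_cra_3", "P_cra_4",
    "P_r_a", "P_r_c", "P_r_v",
    "P_crv_1", "P_crv_2", "P_crv_3", "P_crv_4", "P_crv_out",
    # choroid
    "P_ch_in", "P_ch_a", "P_ch_c", "P_ch_v", "P_ch_out",
    # ciliary body
    "P_cl_in", "P_cl_a", "P_cl_c", "P_cl_v", "P_cl_out",
    # aqueous chamber
    "IOP",
)

NODE_INDEX = {name: i for i, name in enumerate(NODE_NAMES)}


@dataclass
class PressureState:
    """The vector of unknown node pressures [mmHg].

    The venous output of the eye and the episcleral veins are not unknowns:
    they coincide with the intracranial venous sinus pressure, exposed here
    as the derived aliases ``P_Eye_out`` and ``P_evp``.
    """

    P_I: float
    P_C: float
    P_S: float
    P_B: float
    P_F: float
    P_T: float
    P_Eye_in: float
    P_cra_in: float
    P_cra_1: float
    P_cra_2: float
    P_cra_3: float
    P_cra_4: float
    P_r_a: float
    P_r_c: float
    P_r_v: float
    P_crv_1: float
    P_crv_2: float
    P_crv_3: float
    P_crv_4: float
    P_crv_out: float
    P_ch_in: float
    P_ch_a: float
    P_ch_c: float
    P_ch_v: float
    P_ch_out: float
    P_cl_in: float
    P_cl_a: float
    P_cl_c: float
    P_cl_v: float
    P_cl_out: float
    IOP: float

    @property
    def P_Eye_out(self) -> float:
        return self.P_S

    @property
    def P_evp(self) -> float:
        return self.P_S

    def as_array(self):
        import numpy as np
        return np.array([getattr(self, n) for n in NODE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "PressureState":
        return cls(**{n: float(x[i]) for i, n in enumerate(NODE_NAMES)})

    @classmethod
    def from_mapping(cls, d) -> "PressureState":
        return cls(**{n: float(d[n]) for n in NODE_NAMES})

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in NODE_NAMES}
        d["P_Eye_out"] = self.P_Eye_out
        d["P_evp"] = self.P_evp
        return d

    def is_finite(self) -> bool:
        return all(math.isfinite(getattr(self, f.name)) for f in fields(self))


@dataclass
class FlowSet:
    """Every flux of the network at a given state [ml/min].

    Sign convention: positive in the physiological flow direction.  The
    ultrafiltration flux ``J_uf`` may be negative (net absorption into the
    ciliary capillaries), as it is at the physiological operating point.
    ``Q_OA`` and ``Q_CvS`` are totals over both (identical) eyes; the
    per-eye quantities are ``Q_Eye_in`` and ``Q_Eye_out``.
    """

    Q_A: float
    Q_IC: float
    Q_CB: float
    Q_CS: float
    Q_FB: float
    Q_FT: float
    Q_BT: float
    Q_TS: float
    Q_TV: float
    Q_SV: float
    Q_OA: float
    Q_CvS: float
    Q_Eye_in: float
    Q_Eye_out: float
    Q_r: float
    Q_ch: float
    Q_cl: float
    Q_cl_v: float
    J_uf: float
    J_secr: float
    J_ah: float
    J_tm: float
    J_uv: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TransmuralSet:
    """Transmural pressures of the compliant segments [mmHg].

    Venules: intraluminal mid-compartment pressure minus IOP.  Central
    retinal artery/vein segments: midpoint of the flanking node pressures
    minus the segment's external pressure (extraventricular CSF for the
    retrobulbar segments, the lamina cribrosa radial stress for the
    translaminar segment, IOP for the intraocular segments).
    """

    dp_r_v: float
    dp_ch_v: float
    dp_cl_v: float
    dp_cra: tuple
    dp_crv: tuple

    def to_dict(self) -> dict:
        d = {"r_venule": self.dp_r_v, "ch_venule": self.dp_ch_v,
             "cl_venule": self.dp_cl_v}
        for n in range(4):
            d[f"cra_seg{n + 1}"] = self.dp_cra[n]
            d[f"crv_seg{n + 1}"] = self.dp_crv[n]
        return d


# ---------------------------------------------------------------------------
# Constitutive laws
# ---------------------------------------------------------------------------

def poiseuille_resistance(fluid: FluidProperties, geom: VesselGeometry) -> float:
    """Hydraulic resistance of a rigid compartment, R = 8*pi*mu*L/A^2.

    Linear in length and viscosity, inversely proportional to the square of
    the representative cross-sectional area.  Units: mmHg*min/ml.
    """
    return 8.0 * math.pi * fluid.mu * geom.L / (geom.A * geom.A)


def tube_law_constants(wall: VesselWall, A: float) -> tuple[float, float]:
    """Stiffness constants (k_p [mmHg], k_L [-]) of the collapsible-tube law.

    k_L = 12*A/(pi*h^2);  k_p = E*h^3*pi^(3/2) / (12*(1-nu^2)*A^(3/2)).
    """
    if not A > 0.0:
        raise InvalidParameterError(f"area must be positive, got {A}")
    k_L = 12.0 * A / (math.pi * wall.h * wall.h)
    k_p = (wall.E * wall.h ** 3 * math.pi ** 1.5
           / (12.0 * (1.0 - wall.nu * wall.nu) * A ** 1.5))
    return k_p, k_L


def _starling_factor(delta_p_t: float, k_p: float, k_L: float) -> float:
    """Dimensionless resistance multiplier of a Starling resistor.

    Distension (dp_t > 0): (1 + dp_t/(k_p*k_L))^-4 -- the lumen widens, the
    resistance falls.  Collapse (dp_t <= 0): (1 - dp_t/k_p)^(4/3) -- the
    cross-section buckles and the resistance grows without bound.  The two
    branches join continuously (both equal 1) at dp_t = 0.
    """
    if delta_p_t > 0.0:
        base = 1.0 + delta_p_t / (k_p * k_L)
        return base ** -4
    return (1.0 - delta_p_t / k_p) ** (4.0 / 3.0)


def starling_resistance(delta_p_t: float, fluid: FluidProperties,
                        geom: VesselGeometry, wall: VesselWall) -> float:
    """Resistance of a collapsible (Starling) vessel at transmural pressure
    ``delta_p_t`` [mmHg].  Strictly decreasing in ``delta_p_t``; equals the
    Poiseuille value exactly at zero transmural pressure."""
    R0 = poiseuille_resistance(fluid, geom)
    k_p, k_L = tube_law_constants(wall, geom.A)
    return R0 * _starling_factor(delta_p_t, k_p, k_L)


def distensible_resistance(delta_p_t: float, fluid: FluidProperties,
                           geom: VesselGeometry, wall: VesselWall) -> float:
    """Distension-only variant used for the central retinal artery, whose
    transmural pressure stays positive in the model's regime; no collapse
    branch.  A guard keeps the base positive for wild solver iterates."""
    R0 = poiseuille_resistance(fluid, geom)
    k_p, k_L = tube_law_constants(wall, geom.A)
    base = 1.0 + delta_p_t / (k_p * k_L)
    if base <= 1e-9:
        base = 1e-9
    return R0 * base ** -4


def filtration_flux(K: float, sigma: float, dP: float, dpi: float) -> float:
    """Starling-Landis transcapillary filtration, Q = K*[dP - sigma*dpi].

    Positive means flow from compartment i to compartment j given
    dP = P_i - P_j and dpi = pi_i - pi_j.
    """
    if K < 0.0:
        raise InvalidParameterError("filtration coefficient must be >= 0")
    if not 0.0 <= sigma <= 1.0:
        raise InvalidParameterError("reflection coefficient must lie in [0, 1]")
    return K * (dP - sigma * dpi)


def ohm_flux(P_i: float, P_j: float, R: float) -> float:
    """Pressure-driven flux (P_i - P_j)/R; antisymmetric in (i, j)."""
    if not R > 0.0:
        raise InvalidParameterError(f"resistance must be positive, got {R}")
    return (P_i - P_j) / R


def trabecular_outflow(IOP: float, P_evp: float,
                       aq: AqueousParameters) -> tuple[float, float]:
    """Conventional (trabecular meshwork) aqueous drainage.

    R_tm = R0*(1 + kappa*(IOP - P_evp)), J_tm = (IOP - P_evp)/R_tm.
    Returns (R_tm [mmHg*min/ml], J_tm [ml/min]).
    """
    R_tm = aq.R0 * (1.0 + aq.kappa * (IOP - P_evp))
    if R_tm <= 0.0:
        raise DegenerateStateError(
            f"trabecular resistance non-positive (IOP={IOP}, P_evp={P_evp})")
    return R_tm, (IOP - P_evp) / R_tm


def uveoscleral_outflow(IOP: float, aq: AqueousParameters) -> tuple[float, float]:
    """Unconventional (uveoscleral) aqueous drainage to the zero-pressure
    reference.  R_uv = (k2 + IOP)/k1, so J_uv = k1*IOP/(k2 + IOP) saturates
    at k1 for large IOP.  Returns (R_uv, J_uv)."""
    R_uv = (aq.k2 + IOP) / aq.k1
    return R_uv, IOP / R_uv


def transmural_pressures(state: PressureState, P_LC: float,
                         cra4_midpoint: bool = False) -> TransmuralSet:
    """Transmural pressures of all compliant segments at a pressure state.

    The last arterial segment is exposed to IOP; as printed, its intraluminal
    pressure is the downstream node pressure itself rather than a midpoint.
    Set ``cra4_midpoint=True`` to use the midpoint of the flanking nodes
    instead (the convention every other segment follows).
    """
    dp_cra = (
        0.5 * (state.P_cra_in + state.P_cra_1) - state.P_T,
        0.5 * (state.P_cra_1 + state.P_cra_2) - state.P_T,
        0.5 * (state.P_cra_2 + state.P_cra_3) - P_LC,
        (0.5 * (state.P_cra_3 + state.P_cra_4) - state.IOP) if cra4_midpoint
        else (state.P_cra_4 - state.IOP),
    )
    dp_crv = (
        0.5 * (state.P_crv_1 + state.P_crv_2) - state.IOP,
        0.5 * (state.P_crv_2 + state.P_crv_3) - P_LC,
        0.5 * (state.P_crv_3 + state.P_crv_4) - state.P_T,
        0.5 * (state.P_crv_4 + state.P_crv_out) - state.P_T,
    )
    return TransmuralSet(
        dp_r_v=state.P_r_v - state.IOP,
        dp_ch_v=state.P_ch_v - state.IOP,
        dp_cl_v=state.P_cl_v - state.IOP,
        dp_cra=dp_cra,
        dp_crv=dp_crv,
    )


# ---------------------------------------------------------------------------
# Precomputed circuit elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StarlingElement:
    """A collapsible vessel element with its tube-law constants frozen.

    ``alpha`` is the zero-transmural-pressure (Poiseuille) resistance.
    """

    alpha: float
    k_p: float
    k_L: float
    collapsible: bool = True

    @classmethod
    def from_vessel(cls, fluid: FluidProperties, geom: VesselGeometry,
                    wall: VesselWall, collapsible: bool = True) -> "StarlingElement":
        k_p, k_L = tube_law_constants(wall, geom.A)
        return cls(alpha=poiseuille_resistance(fluid, geom),
                   k_p=k_p, k_L=k_L, collapsible=collapsible)

    def resistance(self, delta_p_t: float) -> float:
        if delta_p_t > 0.0 or self.collapsible:
            return self.alpha * _starling_factor(delta_p_t, self.k_p, self.k_L)
        base = 1.0 + delta_p_t / (self.k_p * self.k_L)
        if base <= 1e-9:
            base = 1e-9
        return self.alpha * base ** -4


@dataclass(frozen=True)
class SegmentedVessel:
    """Central retinal artery or vein: four deformable segments sharing a
    common diameter, wall and viscosity but with individual lengths."""

    fluid: FluidProperties
    wall: VesselWall
    D: float
    lengths: tuple
    collapsible: bool

    @property
    def A(self) -> float:
        return math.pi * self.D * self.D / 4.0

    @functools.lru_cache(maxsize=None)
    def segment(self, n: int) -> StarlingElement:
        """One-based segment index, matching the segment numbering of the
        transmural-pressure definitions."""
        if n not in (1, 2, 3, 4):
            raise InvalidParameterError(f"segment index must be 1..4, got {n}")
        geom = VesselGeometry(A=self.A, L=self.lengths[n - 1])
        return StarlingElement.from_vessel(self.fluid, geom, self.wall,
                                           collapsible=self.collapsible)

    def resistance(self, n: int, delta_p_t: float) -> float:
        return self.segment(n).resistance(delta_p_t)


def cra_crv_segment_resistance(n: int, delta_p: float,
                               vessel: SegmentedVessel) -> float:
    """Resistance of segment ``n`` (1..4) of the central retinal artery or
    vein at transmural pressure ``delta_p``.  The artery uses the distension
    branch for all transmural pressures; the vein switches to the collapse
    branch when the transmural pressure becomes non-positive."""
    return vessel.resistance(n, delta_p)
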