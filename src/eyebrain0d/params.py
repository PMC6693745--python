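"""Model constants and the printed reference operating point.

All numbers in this module are literature values for a healthy supine adult,
taken from the published calibration of the individual circuit blocks
(cerebral fluid network, retinal / ciliary / choroidal vasculature, aqueous
humor dynamics).  They are stored here in their conventional units and
converted once to the internal mmHg/ml/min system when assembled into a
:class:`ModelParameters` (see :mod:`eyebrain0d.calibration` for the two
assembly profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

from .core import (AqueousParameters, BrainParameters, FluidProperties,
                   PressureState, SegmentedVessel, StarlingElement,
                   VesselGeometry, VesselWall)
from .lamina import DEFAULT_COEFFICIENTS, LaminaCoefficients
from .units import resistance_per_ul_to_per_ml, ul_to_ml

# ---------------------------------------------------------------------------
# Boundary inputs (central circulation and fluid production rates)
# ---------------------------------------------------------------------------

P_A_BASE = 92.0          # central arterial pressure [mmHg]
P_V_BASE = 5.4           # central venous pressure [mmHg]
Q_CF = ul_to_ml(299.5)   # CSF production rate [ml/min]
J_SECR_UL = 6.9525       # active aqueous secretion [ul/min]

# ---------------------------------------------------------------------------
# Brain network constants [mmHg*min/ml unless noted]
# ---------------------------------------------------------------------------

R_I = 33.5e-3
R_C = 12.7e-3
R_S = 12.7e-3
K_CB = 0.0665            # blood-brain-barrier filtration [ml/mmHg/min]
SIGMA_CB = 1.0
DELTA_PI_CB = 21.0       # plasma - interstitium oncotic difference [mmHg]
R_BT = 1.55
R_FT = 0.6678
R_FB = 0.9023
R_TS = 9.90

# ---------------------------------------------------------------------------
# Body coupling constants
# ---------------------------------------------------------------------------

R_A_PRINTED = 101.5      # central-artery resistance as printed (see audit)
R_V_PRINTED = 407.99     # central-vein resistance as printed (see audit)
R_TV = 52.38
R_I_OA = 18.27           # intracranial artery -> ophthalmic artery

# ---------------------------------------------------------------------------
# Eye: fixed (arteriolar/capillary and inlet/outlet) resistances
# ---------------------------------------------------------------------------

R_CL_IN = 16.70
R_CL_A1 = R_CL_A2 = 105.26
R_CL_C1 = R_CL_C2 = 33.83
R_CL_OUT = 23.90
R_CRA_IN = 376.76
R_R_A1 = R_R_A2 = 101.0
R_R_C1 = R_R_C2 = 94.33
R_CRV_OUT = 247.25
R_CH_IN = 6.04
R_CH_A1 = R_CH_A2 = 38.12
R_CH_C1 = R_CH_C2 = 12.25
R_CH_OUT = 8.66

# Venule wall/fluid properties (shared by retinal, ciliary, choroidal beds)
E_V = 495.0              # [mmHg]
H_V = 7.73e-4            # [cm]
MU_V_MMHG_S = 2.12e-5    # [mmHg*s]
NU_V = 0.49
L_V = 0.80               # retinal venous compartment length [cm]
A_R_V_PRINTED = 1.55e-4  # [cm^2]
A_CL_V_PRINTED = 2.61e-4
A_CH_V_PRINTED = 5.06e-4

# Central retinal artery
L_CRA = (0.44, 0.44, 0.02, 0.1)   # segment lengths [cm]
D_CRA = 175e-4                    # diameter [cm]
E_CRA = 2250.0
H_CRA = 4e-3
MU_CRA_MMHG_S = 2.25e-5
NU_CRA = 0.49

# Central retinal vein
L_CRV = (0.1, 0.02, 0.44, 0.44)
D_CRV = 238e-4
E_CRV = 4500.0
H_CRV = 10.7e-4
MU_CRV_MMHG_S = 2.43e-5
NU_CRV = 0.49

# ---------------------------------------------------------------------------
# Aqueous humor (conventional ul units; converted on assembly)
# ---------------------------------------------------------------------------

L_IN_UL = 0.3            # [ul/min/mmHg]
SIGMA_P = 1.0
DELTA_PI_P = 25.0        # [mmHg]
K1_UL = 0.4              # [ul/min]
K2 = 5.0                 # [mmHg]
R0_TM_UL = 2.2           # [mmHg*min/ul]
KAPPA_TM = 0.012         # [1/mmHg]

# ---------------------------------------------------------------------------
# Reference values used by the calibration procedure
# ---------------------------------------------------------------------------

QBAR_R = ul_to_ml(40.9)   # retinal blood flow [ml/min]
QBAR_CL = ul_to_ml(133.0)
QBAR_CH = ul_to_ml(368.0)
PBAR_EYE_IN = 62.2
PBAR_EYE_OUT = 8.0
IOP_BAR = 15.0


# ---------------------------------------------------------------------------
# Printed baseline solution (the reference fixture)
# ---------------------------------------------------------------------------

#: Published baseline pressures [mmHg] at the physiological operating point.
REFERENCE_PRESSURES = MappingProxyType({
    "P_I": 81.9956, "P_C": 34.1543, "P_S": 7.8210, "P_B": 11.2125,
    "P_F": 11.2125, "P_T": 11.0119,
    "P_Eye_in": 62.2270,
    "P_cra_in": 46.833, "P_cra_1": 43.9041, "P_cra_2": 40.9753,
    "P_cra_3": 40.8465, "P_cra_4": 40.2141,
    "P_r_a": 36.0875, "P_r_c": 28.1062, "P_r_v": 22.1371,
    "P_crv_1": 20.0226, "P_crv_2": 19.8107, "P_crv_3": 19.7729,
    "P_crv_4": 18.8452, "P_crv_out": 17.9235,
    "P_ch_in": 60.003, "P_ch_a": 45.9777, "P_ch_c": 27.4443,
    "P_ch_v": 16.9714, "P_ch_out": 11.0069,
    "P_cl_in": 60.0213, "P_cl_a": 46.1248, "P_cl_c": 27.7616,
    "P_cl_v": 17.118, "P_cl_out": 11.0651,
    "IOP": 14.9662,
})

#: Published derived pressures that are not solver unknowns.
REFERENCE_DERIVED = MappingProxyType({
    "P_Eye_out": 7.8210, "P_evp": 7.82104, "P_LC": 0.0, "RLTp": 11.0119,
})

#: Published baseline flow rates [ml/min].
REFERENCE_FLOWS = MappingProxyType({
    "Q_A": 1035.0, "Q_IC": 1035.0, "Q_CB": 0.1291, "Q_CS": 1034.5,
    "Q_FT": 0.3004, "Q_FB": 42.42e-3, "Q_BT": 0.1287, "Q_TS": 0.3220,
    "Q_TV": 0.1071, "Q_SV": 1035.0, "Q_V": 1035.0,
    "Q_OA": 0.5407, "Q_CvS": 0.5475,
    "Q_Eye_in": 0.5407, "Q_Eye_out": 0.5475,
    "Q_r": 40.9e-3, "Q_ch": 367.9e-3, "Q_cl": 135.7e-3,
    "J_uf": -3.7e-3, "J_ah": 3.3e-3, "J_uv": 2.9983e-4, "J_tm": 0.003,
})


@dataclass(frozen=True)
class ReferenceState:
    """The printed baseline operating point plus calibration reference
    constants.  Immutable; serves as initial guess, calibration anchor and
    audit fixture."""

    pressures: MappingProxyType = field(
        default_factory=lambda: REFERENCE_PRESSURES)
    derived: MappingProxyType = field(
        default_factory=lambda: REFERENCE_DERIVED)
    flows: MappingProxyType = field(default_factory=lambda: REFERENCE_FLOWS)
    Qbar_r: float = QBAR_R
    Qbar_cl: float = QBAR_CL
    Qbar_ch: float = QBAR_CH
    Pbar_Eye_in: float = PBAR_EYE_IN
    Pbar_Eye_out: float = PBAR_EYE_OUT
    IOP_bar: float = IOP_BAR
    P_A: float = P_A_BASE
    P_V: float = P_V_BASE

    def pressure_state(self) -> PressureState:
        return PressureState.from_mapping(self.pressures)


REFERENCE = ReferenceState()


# ---------------------------------------------------------------------------
# Assembled parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Everything the steady-state solver needs, in internal units.

    ``R_A_edge`` / ``R_SV_edge`` are the *composite* resistances of the
    central-artery->intracranial-artery and venous-sinus->central-vein edges
    (the sum of the two half-compartment resistances each edge comprises).
    """

    brain: BrainParameters
    aqueous: AqueousParameters
    R_A_edge: float
    R_SV_edge: float
    R_TV: float
    R_I_OA: float
    # fixed eye resistances
    R_cl_in: float
    R_cl_a1: float
    R_cl_a2: float
    R_cl_c1: float
    R_cl_c2: float
    R_cl_out: float
    R_cra_in: float
    R_r_a1: float
    R_r_a2: float
    R_r_c1: float
    R_r_c2: float
    R_crv_out: float
    R_ch_in: float
    R_ch_a1: float
    R_ch_a2: float
    R_ch_c1: float
    R_ch_c2: float
    R_ch_out: float
    # collapsible elements
    venules: dict                 # bed -> StarlingElement (half-compartment)
    venule_geometry: dict         # bed -> VesselGeometry (A, L actually used)
    cra: SegmentedVessel
    crv: SegmentedVessel
    # sources and surrogate
    Q_CF: float
    lamina: LaminaCoefficients
    cra4_midpoint: bool = False
    profile: str = "audited"

    def venule_resistance(self, bed: str, delta_p_t: float) -> float:
        return self.venules[bed].resistance(delta_p_t)


def _venule_element(A: float, L: float) -> StarlingElement:
    fluid = FluidProperties.from_mmhg_s(MU_V_MMHG_S)
    wall = VesselWall(E=E_V, h=H_V, nu=NU_V)
    return StarlingElement.from_vessel(fluid, VesselGeometry(A=A, L=L), wall)


def build_parameters(venule_areas: dict, venule_lengths: dict,
                     R_A_edge: float, R_SV_edge: float,
                     lamina: LaminaCoefficients = DEFAULT_COEFFICIENTS,
                     cra4_midpoint: bool = False,
                     profile: str = "audited") -> ModelParameters:
    """Assemble a :class:`ModelParameters` from table constants plus the
    profile-dependent pieces (venule geometry and coupling-edge values)."""
    venules = {bed: _venule_element(venule_areas[bed], venule_lengths[bed])
               for bed in ("r", "ch", "cl")}
    geometry = {bed: VesselGeometry(A=venule_areas[bed], L=venule_lengths[bed])
                for bed in ("r", "ch", "cl")}
    brain = BrainParameters(
        R_I=R_I, R_C=R_C, R_S=R_S, K_CB=K_CB, sigma_CB=SIGMA_CB,
        delta_pi_CB=DELTA_PI_CB, R_BT=R_BT, R_FT=R_FT, R_FB=R_FB,
        R_TS=R_TS, Q_CF=Q_CF)
    aqueous = AqueousParameters(
        L_in=ul_to_ml(L_IN_UL), sigma_p=SIGMA_P, delta_pi_p=DELTA_PI_P,
        k1=ul_to_ml(K1_UL), k2=K2,
        R0=resistance_per_ul_to_per_ml(R0_TM_UL), kappa=KAPPA_TM,
        J_secr=ul_to_ml(J_SECR_UL))
    cra = SegmentedVessel(
        fluid=FluidProperties.from_mmhg_s(MU_CRA_MMHG_S),
        wall=VesselWall(E=E_CRA, h=H_CRA, nu=NU_CRA),
        D=D_CRA, lengths=L_CRA, collapsible=False)
    crv = SegmentedVessel(
        fluid=FluidProperties.from_mmhg_s(MU_CRV_MMHG_S),
        wall=VesselWall(E=E_CRV, h=H_CRV, nu=NU_CRV),
        D=D_CRV, lengths=L_CRV, collapsible=True)
    return ModelParameters(
        brain=brain, aqueous=aqueous,
        R_A_edge=R_A_edge, R_SV_edge=R_SV_edge, R_TV=R_TV, R_I_OA=R_I_OA,
        R_cl_in=R_CL_IN, R_cl_a1=R_CL_A1, R_cl_a2=R_CL_A2,
        R_cl_c1=R_CL_C1, R_cl_c2=R_CL_C2, R_cl_out=R_CL_OUT,
        R_cra_in=R_CRA_IN, R_r_a1=R_R_A1, R_r_a2=R_R_A2,
        R_r_c1=R_R_C1, R_r_c2=R_R_C2, R_crv_out=R_CRV_OUT,
        R_ch_in=R_CH_IN, R_ch_a1=R_CH_A1, R_ch_a2=R_CH_A2,
        R_ch_c1=R_CH_C1, R_ch_c2=R_CH_C2, R_ch_out=R_CH_OUT,
        venules=venules, venule_geometry=geometry, cra=cra, crv=crv,
        Q_CF=Q_CF, lamina=lamina, cra4_midpoint=cra4_midpoint,
        profile=profile)
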