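"""Configuration loading and validation.

The model is fully parameterized by a YAML (or JSON) configuration tree
whose defaults are the packaged literature values.  Every numeric field
carries its units in its name; quantities conventionally quoted per
microlitre are accepted in those units and converted once, on assembly.
Unknown keys are rejected so that typos cannot silently fall back to
defaults.  An empty file (or no file) yields the packaged default model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import params as tables
from .calibration import calibrated_venule_geometry, derive_resistances_from_reference
from .core import (AqueousParameters, BrainParameters, FluidProperties,
                   SegmentedVessel, StarlingElement, VesselGeometry,
                   VesselWall)
from .lamina import DEFAULT_COEFFICIENTS, LaminaCoefficients
from .params import REFERENCE, ModelParameters
from .units import resistance_per_ul_to_per_ml, ul_to_ml


class ConfigError(ValueError):
    """Configuration file invalid; message names the offending key."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class InputsBlock(_Block):
    """Boundary inputs (Earth baseline values)."""

    P_A_mmhg: float = tables.P_A_BASE
    P_V_mmhg: float = tables.P_V_BASE
    Q_CF_ul_min: float = Field(299.5, gt=0)
    J_secr_ul_min: float = Field(tables.J_SECR_UL, gt=0)


class BrainBlock(_Block):
    """Cerebral network resistances [mmHg*min/ml] and barrier coefficients."""

    R_I: float = Field(tables.R_I, gt=0)
    R_C: float = Field(tables.R_C, gt=0)
    R_S: float = Field(tables.R_S, gt=0)
    K_CB_ml_mmhg_min: float = Field(tables.K_CB, ge=0)
    sigma_CB: float = Field(tables.SIGMA_CB, ge=0, le=1)
    R_BT: float = Field(tables.R_BT, gt=0)
    R_FT: float = Field(tables.R_FT, gt=0)
    R_FB: float = Field(tables.R_FB, gt=0)
    R_TS: float = Field(tables.R_TS, gt=0)


class CouplingBlock(_Block):
    """Body coupling resistances [mmHg*min/ml] as printed; the audited
    profile replaces the central edges with Ohm's-law values."""

    R_A: float = Field(tables.R_A_PRINTED, gt=0)
    R_V: float = Field(tables.R_V_PRINTED, gt=0)
    R_TV: float = Field(tables.R_TV, gt=0)
    R_I_OA: float = Field(tables.R_I_OA, gt=0)


class AqueousBlock(_Block):
    """Aqueous humor dynamics, in the conventional microlitre units."""

    L_in_ul_min_mmhg: float = Field(tables.L_IN_UL, gt=0)
    sigma_p: float = Field(tables.SIGMA_P, ge=0, le=1)
    k1_ul_min: float = Field(tables.K1_UL, gt=0)
    k2_mmhg: float = Field(tables.K2, gt=0)
    R0_mmhg_min_ul: float = Field(tables.R0_TM_UL, gt=0)
    kappa_per_mmhg: float = Field(tables.KAPPA_TM, gt=0)


class VenuleBlock(_Block):
    """Shared elastic/viscous venule properties and printed areas [cm^2]."""

    E_mmhg: float = Field(tables.E_V, gt=0)
    h_cm: float = Field(tables.H_V, gt=0)
    nu: float = Field(tables.NU_V, ge=0, lt=0.5)
    mu_mmhg_s: float = Field(tables.MU_V_MMHG_S, gt=0)
    L_v_cm: float = Field(tables.L_V, gt=0)
    A_r_v_cm2: float = Field(tables.A_R_V_PRINTED, gt=0)
    A_cl_v_cm2: float = Field(tables.A_CL_V_PRINTED, gt=0)
    A_ch_v_cm2: float = Field(tables.A_CH_V_PRINTED, gt=0)


class CentralVesselBlock(_Block):
    """A four-segment central retinal vessel."""

    lengths_cm: tuple[float, float, float, float]
    D_cm: float = Field(..., gt=0)
    E_mmhg: float = Field(..., gt=0)
    h_cm: float = Field(..., gt=0)
    nu: float = Field(..., ge=0, lt=0.5)
    mu_mmhg_s: float = Field(..., gt=0)


class EyeResistancesBlock(_Block):
    """Fixed (non-collapsible) ocular resistances [mmHg*min/ml]."""

    R_cl_in: float = Field(tables.R_CL_IN, gt=0)
    R_cl_a: float = Field(tables.R_CL_A1, gt=0)
    R_cl_c: float = Field(tables.R_CL_C1, gt=0)
    R_cl_out: float = Field(tables.R_CL_OUT, gt=0)
    R_cra_in: float = Field(tables.R_CRA_IN, gt=0)
    R_r_a: float = Field(tables.R_R_A1, gt=0)
    R_r_c: float = Field(tables.R_R_C1, gt=0)
    R_crv_out: float = Field(tables.R_CRV_OUT, gt=0)
    R_ch_in: float = Field(tables.R_CH_IN, gt=0)
    R_ch_a: float = Field(tables.R_CH_A1, gt=0)
    R_ch_c: float = Field(tables.R_CH_C1, gt=0)
    R_ch_out: float = Field(tables.R_CH_OUT, gt=0)


class LaminaBlock(_Block):
    """Quadratic stress-surface coefficients (1, IOP, CSFp, IOP^2,
    IOP*CSFp, CSFp^2); mmHg-consistent units."""

    c0: float = DEFAULT_COEFFICIENTS.c0
    c1: float = DEFAULT_COEFFICIENTS.c1
    c2: float = DEFAULT_COEFFICIENTS.c2
    c3: float = DEFAULT_COEFFICIENTS.c3
    c4: float = DEFAULT_COEFFICIENTS.c4
    c5: float = DEFAULT_COEFFICIENTS.c5


class SolverBlock(_Block):
    tol_ml_min: float = Field(1e-9, gt=0)
    max_iter: int = Field(30, gt=0)


class SweepBlock(_Block):
    pi_c_min_mmhg: float = Field(18.5, gt=0)
    pi_c_max_mmhg: float = Field(25.0, gt=0)
    step_mmhg: float = Field(0.05, gt=0)
    scenarios: tuple[str, ...] = ("LHDT", "M0", "M1", "M2")


class GravityBlock(_Block):
    """Hydrostatic column for head-down tilt: G = rho*g*H [mmHg]."""

    G_mmhg: float = Field(24.0, gt=0)
    theta_deg: float = 6.0


def _default_cra() -> CentralVesselBlock:
    return CentralVesselBlock(
        lengths_cm=tables.L_CRA, D_cm=tables.D_CRA, E_mmhg=tables.E_CRA,
        h_cm=tables.H_CRA, nu=tables.NU_CRA, mu_mmhg_s=tables.MU_CRA_MMHG_S)


def _default_crv() -> CentralVesselBlock:
    return CentralVesselBlock(
        lengths_cm=tables.L_CRV, D_cm=tables.D_CRV, E_mmhg=tables.E_CRV,
        h_cm=tables.H_CRV, nu=tables.NU_CRV, mu_mmhg_s=tables.MU_CRV_MMHG_S)


class ModelConfig(_Block):
    """Full validated parameter tree with packaged defaults."""

    profile: Literal["audited", "literal-table5"] = "audited"
    cra4_midpoint: bool = False
    seed: int = 0  # reserved; the model is deterministic
    inputs: InputsBlock = Field(default_factory=InputsBlock)
    brain: BrainBlock = Field(default_factory=BrainBlock)
    coupling: CouplingBlock = Field(default_factory=CouplingBlock)
    aqueous: AqueousBlock = Field(default_factory=AqueousBlock)
    venules: VenuleBlock = Field(default_factory=VenuleBlock)
    cra: CentralVesselBlock = Field(default_factory=_default_cra)
    crv: CentralVesselBlock = Field(default_factory=_default_crv)
    eye_resistances: EyeResistancesBlock = Field(
        default_factory=EyeResistancesBlock)
    lamina: LaminaBlock = Field(default_factory=LaminaBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    gravity: GravityBlock = Field(default_factory=GravityBlock)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML or JSON configuration file.

    ``None`` or an empty file yields the packaged defaults.  Schema
    violations raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return ModelConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ModelConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(
            f"{path}: invalid value for '{loc}': {first['msg']}") from exc


def config_to_parameters(cfg: ModelConfig) -> ModelParameters:
    """Assemble a :class:`~eyebrain0d.params.ModelParameters` from a
    validated configuration, applying the calibration profile and all unit
    conversions."""
    venule_wall = VesselWall(E=cfg.venules.E_mmhg, h=cfg.venules.h_cm,
                             nu=cfg.venules.nu)
    venule_fluid = FluidProperties.from_mmhg_s(cfg.venules.mu_mmhg_s)
    V_rv = cfg.venules.A_r_v_cm2 * cfg.venules.L_v_cm
    ratios = {"r": 1.0, "ch": REFERENCE.Qbar_ch / REFERENCE.Qbar_r,
              "cl": REFERENCE.Qbar_cl / REFERENCE.Qbar_r}

    if cfg.profile == "audited":
        areas, lengths = calibrated_venule_geometry(
            wall=venule_wall, fluid=venule_fluid, V_rv=V_rv)
        overrides = derive_resistances_from_reference()
        R_A_edge = overrides["R_A_edge"]
        R_SV_edge = overrides["R_SV_edge"]
    else:
        areas = {"r": cfg.venules.A_r_v_cm2, "ch": cfg.venules.A_ch_v_cm2,
                 "cl": cfg.venules.A_cl_v_cm2}
        lengths = {bed: ratios[bed] * V_rv / areas[bed] for bed in areas}
        R_A_edge = cfg.coupling.R_A + cfg.brain.R_I
        R_SV_edge = cfg.brain.R_S + cfg.coupling.R_V

    venules = {bed: StarlingElement.from_vessel(
        venule_fluid, VesselGeometry(A=areas[bed], L=lengths[bed]),
        venule_wall) for bed in ("r", "ch", "cl")}
    geometry = {bed: VesselGeometry(A=areas[bed], L=lengths[bed])
                for bed in ("r", "ch", "cl")}

    def central(block: CentralVesselBlock, collapsible: bool) -> SegmentedVessel:
        return SegmentedVessel(
            fluid=FluidProperties.from_mmhg_s(block.mu_mmhg_s),
            wall=VesselWall(E=block.E_mmhg, h=block.h_cm, nu=block.nu),
            D=block.D_cm, lengths=tuple(block.lengths_cm),
            collapsible=collapsible)

    brain = BrainParameters(
        R_I=cfg.brain.R_I, R_C=cfg.brain.R_C, R_S=cfg.brain.R_S,
        K_CB=cfg.brain.K_CB_ml_mmhg_min, sigma_CB=cfg.brain.sigma_CB,
        delta_pi_CB=tables.DELTA_PI_CB, R_BT=cfg.brain.R_BT,
        R_FT=cfg.brain.R_FT, R_FB=cfg.brain.R_FB, R_TS=cfg.brain.R_TS,
        Q_CF=ul_to_ml(cfg.inputs.Q_CF_ul_min))
    aqueous = AqueousParameters(
        L_in=ul_to_ml(cfg.aqueous.L_in_ul_min_mmhg),
        sigma_p=cfg.aqueous.sigma_p, delta_pi_p=tables.DELTA_PI_P,
        k1=ul_to_ml(cfg.aqueous.k1_ul_min), k2=cfg.aqueous.k2_mmhg,
        R0=resistance_per_ul_to_per_ml(cfg.aqueous.R0_mmhg_min_ul),
        kappa=cfg.aqueous.kappa_per_mmhg,
        J_secr=ul_to_ml(cfg.inputs.J_secr_ul_min))
    lam = LaminaCoefficients(
        c0=cfg.lamina.c0, c1=cfg.lamina.c1, c2=cfg.lamina.c2,
        c3=cfg.lamina.c3, c4=cfg.lamina.c4, c5=cfg.lamina.c5)
    er = cfg.eye_resistances
    return ModelParameters(
        brain=brain, aqueous=aqueous,
        R_A_edge=R_A_edge, R_SV_edge=R_SV_edge,
        R_TV=cfg.coupling.R_TV, R_I_OA=cfg.coupling.R_I_OA,
        R_cl_in=er.R_cl_in, R_cl_a1=er.R_cl_a, R_cl_a2=er.R_cl_a,
        R_cl_c1=er.R_cl_c, R_cl_c2=er.R_cl_c, R_cl_out=er.R_cl_out,
        R_cra_in=er.R_cra_in, R_r_a1=er.R_r_a, R_r_a2=er.R_r_a,
        R_r_c1=er.R_r_c, R_r_c2=er.R_r_c, R_crv_out=er.R_crv_out,
        R_ch_in=er.R_ch_in, R_ch_a1=er.R_ch_a, R_ch_a2=er.R_ch_a,
        R_ch_c1=er.R_ch_c, R_ch_c2=er.R_ch_c, R_ch_out=er.R_ch_out,
        venules=venules, venule_geometry=geometry,
        cra=central(cfg.cra, collapsible=False),
        crv=central(cfg.crv, collapsible=True),
        Q_CF=ul_to_ml(cfg.inputs.Q_CF_ul_min), lamina=lam,
        cra4_midpoint=cfg.cra4_midpoint, profile=cfg.profile)
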