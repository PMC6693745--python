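"""Lamina cribrosa radial-stress surrogate.

The collagenous lamina cribrosa is loaded by IOP on its anterior face and by
the retrolaminar cerebrospinal-fluid pressure (CSFp) on its posterior face;
its deformation exerts a radial compressive stress P_LC on the translaminar
segments of the central retinal artery and vein.  A full 3-D nonlinear
elastic computation of that stress is out of scope here; it is replaced by a
configurable second-order polynomial surface

    P_LC(IOP, CSFp) = max(0, c0 + c1*IOP + c2*CSFp
                             + c3*IOP^2 + c4*IOP*CSFp + c5*CSFp^2),

clamped at zero because a compressive stress cannot be negative.

The shipped default is calibrated so that P_LC vanishes (with zero
gradient) at the physiological operating point, stays zero over the whole
pre-collapse operating range of the fluid-shift scenarios (IOP up to about
21 mmHg), and rises sharply beyond:  c3 = 0.25 /mmHg, c0 = -0.25 * 21^2
mmHg, all other coefficients zero, i.e. P_LC = max(0, 0.25*(IOP^2 - 21^2)).
The flat-then-sharp shape is the behaviour reported for the full 3-D
computation (the stress is negligible near the physiological point and
grows steeply at elevated IOP), and it makes the translaminar vein segment
the last to be crushed, slightly after the intraocular venules collapse.
The default surface deliberately carries no CSFp dependence; the
coefficients are a first-class configuration block for users with access
to a fitted surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: Operating box over which the surrogate is considered calibrated [mmHg].
IOP_BOX = (10.0, 40.0)
CSFP_BOX = (0.0, 25.0)


@dataclass(frozen=True)
class LaminaCoefficients:
    """Coefficients of the quadratic stress surface, ordered as
    (1, IOP, CSFp, IOP^2, IOP*CSFp, CSFp^2)."""

    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    c5: float = 0.0

    def as_tuple(self) -> tuple:
        return (self.c0, self.c1, self.c2, self.c3, self.c4, self.c5)


#: Default surface: zero and flat at the physiological point and across the
#: pre-collapse scenario range, sharp quadratic rise beyond IOP ~ 21 mmHg.
DEFAULT_COEFFICIENTS = LaminaCoefficients(c0=-0.25 * 21.0 ** 2, c3=0.25)


def lamina_radial_stress(IOP: float, CSFp: float,
                         coeffs: LaminaCoefficients = DEFAULT_COEFFICIENTS,
                         warn_outside_box: bool = False) -> float:
    """Radial compressive stress P_LC [mmHg] exerted by the lamina cribrosa
    on the translaminar vessel segments.

    Evaluates the quadratic surface and clamps at zero.  Inputs outside the
    calibrated operating box are extrapolated; set ``warn_outside_box`` to
    emit a warning when that happens (off by default because transient
    solver iterates may wander outside the box harmlessly).
    """
    if warn_outside_box and not (IOP_BOX[0] <= IOP <= IOP_BOX[1]
                                 and CSFP_BOX[0] <= CSFp <= CSFP_BOX[1]):
        warnings.warn(
            f"lamina surrogate evaluated outside its calibrated box: "
            f"IOP={IOP:.3g}, CSFp={CSFp:.3g} mmHg (extrapolating)",
            stacklevel=2)
    c0, c1, c2, c3, c4, c5 = coeffs.as_tuple()
    val = (c0 + c1 * IOP + c2 * CSFp
           + c3 * IOP * IOP + c4 * IOP * CSFp + c5 * CSFp * CSFp)
    return val if val > 0.0 else 0.0
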