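"""Unit conventions and conversions.

The internal unit system is mmHg / ml / min everywhere.  Quantities that are
conventionally quoted in other units are converted once, at the parameter
boundary:

* blood viscosities are usually quoted in mmHg*s  -> divide by 60;
* aqueous-humor flows and conductances are usually quoted per microlitre
  (ul/min, mmHg*min/ul, ul/min/mmHg) -> factors of 1e-3 / 1e3.

Keeping a single internal system prevents silent factor-of-1000 errors when
brain flows (order 1000 ml/min) and aqueous flows (order 1e-3 ml/min) meet in
the same mass balance.
"""

SECONDS_PER_MINUTE = 60.0


def viscosity_mmhg_s_to_mmhg_min(mu_mmhg_s: float) -> float:
    """Convert a dynamic viscosity from mmHg*s to mmHg*min."""
    return mu_mmhg_s / SECONDS_PER_MINUTE


def viscosity_mmhg_min_to_mmhg_s(mu_mmhg_min: float) -> float:
    """Inverse of :func:`viscosity_mmhg_s_to_mmhg_min` (exact round trip)."""
    return mu_mmhg_min * SECONDS_PER_MINUTE


def ul_to_ml(x_ul: float) -> float:
    """Microlitres to millilitres (e.g. ul/min -> ml/min)."""
    return x_ul * 1e-3


def ml_to_ul(x_ml: float) -> float:
    return x_ml * 1e3


def resistance_per_ul_to_per_ml(r_ul: float) -> float:
    """mmHg*min/ul -> mmHg*min/ml."""
    return r_ul * 1e3
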