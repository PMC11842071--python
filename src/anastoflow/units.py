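"""Unit conversion constants and helpers.

User-facing surfaces (configs, reports) use clinical units: lengths in mm,
flows in l/min or ml/min, pressures in mmHg, shear stress in Pa. The solver
works in SI (m, m/s, Pa, s). All conversions go through this module.
"""

# Pressure
MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

# Flow rate
LMIN_TO_M3S = 1.0e-3 / 60.0          # l/min -> m^3/s
M3S_TO_LMIN = 1.0 / LMIN_TO_M3S
MLMIN_TO_M3S = 1.0e-6 / 60.0         # ml/min -> m^3/s
M3S_TO_MLMIN = 1.0 / MLMIN_TO_M3S

# Length
MM_TO_M = 1.0e-3
M_TO_MM = 1.0e3

# Vascular resistance: 1 mmHg/(l/min) in Pa.s/m^3
RCLIN_TO_SI = MMHG_TO_PA / LMIN_TO_M3S
RSI_TO_CLIN = 1.0 / RCLIN_TO_SI

# Compliance: 1 l/mmHg in m^3/Pa
CCLIN_TO_SI = 1.0e-3 / MMHG_TO_PA
CSI_TO_CLIN = 1.0 / CCLIN_TO_SI


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p * PA_TO_MMHG


def lmin_to_m3s(q):
    return q * LMIN_TO_M3S


def m3s_to_mlmin(q):
    return q * M3S_TO_MLMIN


def rclin_to_si(r):
    """Resistance mmHg.min/l -> Pa.s/m^3."""
    return r * RCLIN_TO_SI
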