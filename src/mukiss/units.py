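"""Physical constants and unit conversions.

Internal convention: lengths in μm, volumetric flow in nl/s, volumes in fl
(1 fl == 1 μm³), time in s, viscosity in mPa·s. Conversions to SI happen
at the edges, in this module.
"""

K_B = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
ZERO_CELSIUS = 273.15  # K

NL_PER_S_TO_UM3_PER_S = 1.0e6  # 1 nl = 1e6 μm³
UM_TO_M = 1.0e-6
UM2_PER_S_TO_M2_PER_S = 1.0e-12
MPAS_TO_PAS = 1.0e-3


def kelvin(temperature_c: float) -> float:
    """Absolute temperature from °C."""
    return temperature_c + ZERO_CELSIUS
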