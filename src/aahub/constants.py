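"""Physical constants used throughout the package.

Energies are kJ mol⁻¹ and temperatures kelvin internally; file I/O and the
command line speak °C and convert at the boundary.
"""

from typing import Final

#: Gas constant, kJ mol⁻¹ K⁻¹.
R: Final[float] = 8.314e-3

#: 0 °C in kelvin.
ZERO_CELSIUS: Final[float] = 273.15

#: Thermochemical calorie, J.
CAL_TO_J: Final[float] = 4.184


def celsius_to_kelvin(t_celsius):
    """Convert °C to kelvin (array-safe)."""
    return t_celsius + ZERO_CELSIUS


def kelvin_to_celsius(t_kelvin):
    """Convert kelvin to °C (array-safe)."""
    return t_kelvin - ZERO_CELSIUS
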