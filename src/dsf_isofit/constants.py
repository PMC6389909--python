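"""Physical constants and unit conversions.

All thermodynamic math is done in kelvin and kcal; instrument-facing I/O
uses degrees Celsius (the unit plate readers export).
"""

#: Gas constant in kcal mol^-1 K^-1 (matches kcal-based enthalpies).
R_KCAL: float = 1.987204e-3

#: Additive offset between Celsius and kelvin.
CELSIUS_OFFSET: float = 273.15


def c_to_k(t_celsius):
    """Convert temperature from Celsius to kelvin."""
    return t_celsius + CELSIUS_OFFSET


def k_to_c(t_kelvin):
    """Convert temperature from kelvin to Celsius."""
    return t_kelvin - CELSIUS_OFFSET
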