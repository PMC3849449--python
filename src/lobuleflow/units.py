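"""Unit conversion constants.

Internal unit system: lengths in cm, time in min, pressure in kPa,
viscosity in mPa·s (= cP), permeability in cm², concentrations as mole
fractions, molar density in mmol/cm³.
"""

#: 1 Darcy in cm².
DARCY_TO_CM2 = 9.869e-9

#: 1 μm² in cm².
UM2_TO_CM2 = 1.0e-8

#: 1 m²/s in cm²/min.
M2_PER_S_TO_CM2_PER_MIN = 1.0e4 * 60.0

#: Converts K[cm²]·Δp[kPa] / (μ[mPa·s]·L[cm]) to a velocity in cm/min.
#: (kPa/mPa = 1e6, 1/s → 60/min.)
DARCY_VELOCITY_FACTOR = 6.0e7
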