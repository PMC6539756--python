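"""Single registry of physical constants and unit conversions.

Every physical constant used by the package lives here; no module is
allowed to re-define its own copy.
"""

#: Speed of sound in water, m/s (tank-calibrated value used throughout).
SOUND_SPEED_WATER = 1492.0

#: Specific heat capacity of water, J kg^-1 K^-1.
SPECIFIC_HEAT_WATER = 4186.0

#: Mass density of water, kg m^-3.
DENSITY_WATER = 1000.0

#: Volumetric thermal-expansion coefficient of water near 20 degC, K^-1.
THERMAL_EXPANSION_WATER = 2.07e-4

#: 1 MeV in joules.
MEV_TO_J = 1.602e-13

#: 1 MeV/g of absorbed energy expressed in gray (J/kg).
MEV_PER_G_TO_GY = 1.602e-10

#: Default acquisition sample rate, Hz (10 MS/s).
DEFAULT_SAMPLE_RATE = 1.0e7

#: Default acquisition record length, s (500 us).
DEFAULT_RECORD_DURATION = 500e-6
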