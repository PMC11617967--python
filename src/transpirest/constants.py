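"""Physical constants and unit-conversion factors used throughout.

Vapour concentrations are carried in g m^-3, pressures in Pa, transpiration
rates in mg cm^-2 h^-1 and resistances in s cm^-1; every conversion between
those units goes through a named constant below.
"""

#: Specific gas constant of dry air [J kg^-1 K^-1].
R_AIR = 287.058

#: Specific gas constant of water vapour [J kg^-1 K^-1].
R_WATER_VAPOUR = 461.52

#: Ratio of the two gas constants (~0.62198), the molecular-mass ratio of
#: water to dry air that appears in the mixing-ratio relation.
EPSILON = R_AIR / R_WATER_VAPOUR

#: Universal gas constant [J mol^-1 K^-1], for Arrhenius temperature scaling.
R_GAS = 8.314

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15

#: Standard barometric pressure [Pa], the default when no pressure is logged.
STANDARD_PRESSURE_PA = 101325.0

#: Unit factor linking flux and driving force:
#: r [s cm^-1] = RESISTANCE_UNIT_FACTOR * delta_x [g m^-3] / E [mg cm^-2 h^-1].
#: With delta_x in g m^-3 (= ug cm^-3) and E in mg cm^-2 h^-1
#: (= 1000/3600 ug cm^-2 s^-1), the ratio delta_x/E must be multiplied by
#: 3600/1000 = 3.6 to land in s cm^-1.
RESISTANCE_UNIT_FACTOR = 3.6

#: Validity window of the saturation-vapour-pressure approximation [deg C].
PSAT_T_MIN_C = -10.0
PSAT_T_MAX_C = 50.0

#: Default water activity of fresh produce interior (98.5 % equilibrium rH).
DEFAULT_WATER_ACTIVITY = 0.985

#: Default boundary-layer resistance of an individual apple under
#: unrestricted free convection [s cm^-1]; applies to apples only.
DEFAULT_FREE_CONVECTION_RB_APPLE = 4.0
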