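"""Derive the four moist-air properties from temperature/humidity readings.

For a few representative greenhouse conditions, prints the dew point Td
(degC), humidity ratio w (kg water per kg dry air), enthalpy h (kJ/kg) and
specific volume v (m^3/kg) at standard pressure.  Warm, humid air carries far
more energy (h) and moisture (w) than cold air at the same relative humidity
— which is why these derived properties describe the air-vapor mixture
better than the raw readings.
"""

from sensopt import dew_point, enthalpy, humidity_ratio, specific_volume
from sensopt.psychro import vapor_pressure

print(f"{'T (degC)':>9} {'RH (%)':>7} {'Td (degC)':>10} {'w':>9} "
      f"{'h (kJ/kg)':>10} {'v (m3/kg)':>10}")
for T, RH in [(10, 80), (18, 70), (25, 50), (32, 90)]:
    pw = vapor_pressure(T, RH)
    w = humidity_ratio(pw)
    print(f"{T:>9.1f} {RH:>7.0f} {dew_point(T, RH):>10.1f} {w:>9.5f} "
          f"{enthalpy(T, w):>10.2f} {specific_volume(T, pw):>10.4f}")
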