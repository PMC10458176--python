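"""Ice-vapor equilibrium and effective thermophysical properties.

Prints the Goff-Gratch saturation pressures at the process temperatures
and the Krischer effective conductivities of the two reference networks.
"""

from lyopnm import (
    MaterialProps,
    effective_cv_properties,
    kelvin,
    p_sat_ice,
    t_sat_ice,
    vapor_viscosity,
)

mat = MaterialProps()

print("equilibrium vapor pressure over ice:")
for t_C in (-18.0, -28.0, -42.0):
    print(f"  P_eq({t_C:+.0f} degC) = {p_sat_ice(kelvin(t_C)):8.2f} Pa")
print(f"  triple point check: {p_sat_ice(273.16):.2f} Pa (= 6.1071 hPa)")
print(f"saturation temperature at 10 Pa: {t_sat_ice(10.0) - 273.15:.1f} degC")
print(f"vapor viscosity at -28 degC: {vapor_viscosity(kelvin(-28.0)):.3e} Pa s")
print()

print("Krischer effective conductivity at full ice saturation (a = 0.5):")
for label, eps in (("monomodal, eps = 0.58", 0.58), ("bimodal, eps = 0.17", 0.17)):
    lam = float(effective_cv_properties(eps, 1.0, mat).lam)
    print(f"  {label}: lam_eff = {lam:.4f} W/m/K")

# The pressure at the shelf temperature (-18 degC) minus the chamber
# pressure (10 Pa) is the maximum driving force for sublimation; the
# conductivity ratio ~1.71 sets the ratio of initial heat flows.
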