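"""How each model constant responds to temperature.

Evaluates every temperature-correction law between 8 and 30 degC: Arrhenius
power laws for growth/decay, van't Hoff oxygen solubility, Stokes-Einstein
diffusivity scaling, and the membrane permeance Arrhenius law.
"""

from mabrsim import (
    KineticParameterSet,
    TemperatureRuleSet,
    membrane_permeance,
    oxygen_saturation,
    temperature_adjusted,
)

kin = KineticParameterSet()
rules = TemperatureRuleSet()
pO2 = 0.21 * (1.013 + 0.235)  # air at 235 mbar gauge

print(f"{'T':>4} {'mu_AOO':>7} {'mu_NOO':>7} {'O2 sat':>7} {'D_O2':>9} {'perm':>6}")
print(f"{'degC':>4} {'1/d':>7} {'1/d':>7} {'g/m3':>7} {'m2/d':>9} {'m/d':>6}")
for T in (8, 12, 18, 20, 24, 30):
    adj = temperature_adjusted(kin, rules, T)
    sat = oxygen_saturation(T, pO2, rules)
    print(
        f"{T:>4} {adj.mu_AOO:7.3f} {adj.mu_NOO:7.3f} {sat:7.2f} "
        f"{adj.D_water[0]:9.2e} {adj.permeance:6.2f}"
    )

print(
    "\nGrowth accelerates ~7.3x from 8 to 30 degC while oxygen solubility "
    "drops ~35% and\ndiffusivities rise ~1.8x: the opposing trends are why "
    "a transport-limited biofilm\nshows a much weaker temperature response "
    "than its kinetics alone would."
)
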