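"""Local sensitivity of the removal rate to diffusion coefficients.

Perturbs the aqueous diffusivity of oxygen or ammonium by +-25 %,
re-equilibrates the biofilm, and reports the central relative sensitivity
[R(+25%) - R(-25%)] / (0.5 R0) with its regime label (low < 0.200 <
moderately high < 0.600 < high).
"""

from mabrsim import (
    KineticParameterSet,
    Scenario,
    SolverOptions,
    TemperatureRuleSet,
    diffusivity_sensitivity,
)

kin, rules, opts = KineticParameterSet(), TemperatureRuleSet(), SolverOptions()

cases = [
    (Scenario(8.0, 150e-6, 50e-6), "D_O2", "rate_at_35"),
    (Scenario(30.0, 50e-6, 50e-6), "D_O2", "rate_at_35"),
    (Scenario(8.0, 50e-6, 250e-6), "D_NH4", "limiting_slope"),
    (Scenario(8.0, 50e-6, 50e-6), "D_NH4", "limiting_slope"),
]
for sc, target, response in cases:
    r = diffusivity_sensitivity(sc, kin, rules, target=target, response=response,
                                options=opts)
    print(
        f"T={sc.temperature:>4} degC Lf={sc.Lf * 1e6:>3.0f} um "
        f"LBL={sc.L_LBL * 1e6:>3.0f} um  {target:>6} on {response:<14} "
        f"S = {r.sensitivity:+.3f}  ({r.regime})"
    )

print(
    "\nOxygen diffusivity matters most for cold, thick biofilms (internal "
    "transport\ncontrols the rate); ammonium diffusivity dominates when the "
    "bulk is dilute and\nthe boundary layer thick (external transport "
    "controls). Strong transport\nsensitivity is the flip side of weak "
    "temperature sensitivity."
)
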