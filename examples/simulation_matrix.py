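"""The full temperature x thickness x boundary-layer simulation matrix.

Runs all eight scenarios (8/30 degC, 50/150 um biofilm, 50/250 um liquid
boundary layer) with the calibrated default parameters, then summarises the
temperature dependence of the ammonium removal rate as percent change per
degC for each geometry.
"""

from mabrsim import (
    KineticParameterSet,
    SolverOptions,
    TemperatureRuleSet,
    run_simulation_matrix,
)

res = run_simulation_matrix(
    KineticParameterSet(), TemperatureRuleSet(), SolverOptions(),
)

print("rates at 35 mg N/L bulk ammonium (g N m-2 d-1):")
print(res.rates.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\ntemperature sensitivity per geometry:")
print(res.sensitivity.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

thin = res.sensitivity[res.sensitivity.Lf == 50e-6].pct_per_degC_rate35.mean()
thick = res.sensitivity[res.sensitivity.Lf == 150e-6].pct_per_degC_rate35.mean()
print(
    f"\nmean sensitivity at 50 um biofilm:  {thin:.1f} %/degC\n"
    f"mean sensitivity at 150 um biofilm: {thick:.1f} %/degC\n"
    "\nThin biofilms respond strongly to temperature (kinetics-limited); "
    "thick biofilms\nare buffered by oxygen mass transfer, so warming helps "
    "them much less - and at\n8 degC the extra biomass of a thick film wins, "
    "while at 30 degC it loses to\noxygen competition from nitrite oxidisers."
)
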