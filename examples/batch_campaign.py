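"""Synthetic batch campaign and its full analysis pipeline.

Generates a two-run drawdown campaign (30 -> 8 degC and back, duplicate
tests at each temperature, 15-min sampling from 50 mg N/L), estimates
windowed removal rates, averages duplicate runs, fits the Arrhenius-type
temperature coefficient and reports the nitrite accumulation trend.
"""

from mabrsim import (
    CampaignSpec,
    arrhenius_from_campaign,
    generate_campaign,
    nitrite_accumulation,
)

spec = CampaignSpec(theta=1.026, R_T0=3.0, noise_sd=0.2, seed=42)
series, manifest = generate_campaign(spec)
print(f"campaign: {len(series)} batch tests, true theta = {spec.theta}\n")

fit, table = arrhenius_from_campaign(series, window=(10.0, 20.0), T0=20.0)
print("averaged areal rates, 10-20 mg N/L window:")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    f"\nArrhenius fit: theta = {fit.theta:.4f} (+/- {fit.se_theta:.4f}), "
    f"R(20 degC) = {fit.R_T0:.2f} g N m-2 d-1"
)

print("\nnitrite accumulation at the end of each first-run test:")
for s in series[:5]:
    print(f"  {s.temperature:>4} degC: {nitrite_accumulation(s):5.1f} % of oxidised N")

print(
    "\nThe fitted theta is far below suspended-culture growth coefficients "
    "(~1.10):\nmass transfer, not biology, sets the temperature response of "
    "the membrane-aerated\nbiofilm. Nitrite accumulates in the cold because "
    "nitrite oxidation lags ammonia\noxidation at low temperature."
)
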