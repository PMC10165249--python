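# mabrsim

Temperature dependence of nitrification in membrane-aerated biofilm
reactors (MABRs), as a tested, reusable Python library.

In an MABR, nitrifying biofilm grows on the outside of gas-permeable
hollow fibres: oxygen diffuses in from the membrane beneath the biofilm
while ammonium arrives from the bulk liquid above — a *counter-diffusional*
arrangement. A striking property of such biofilms is their weak temperature
response: although nitrifier growth rates roughly double every 8 °C,
measured removal rates in cold water stay high, because mass transfer — not
biology — controls the flux. `mabrsim` packages the two computational tools
needed to study this quantitatively:

1. **A 1D counter-diffusional biofilm model** — two-step nitrification
   (ammonia oxidisers, AOO, and nitrite oxidisers, NOO) with double-Monod
   kinetics, a mixed gas compartment coupled through a diffusive membrane
   link, a stagnant liquid boundary layer (LBL), and Wanner–Gujer biomass
   dynamics under the constant-thickness detachment closure. Every
   temperature-sensitive constant (growth, decay, Henry constant,
   diffusivities, membrane permeance) carries its own correction law.
2. **Batch-test rate analysis** — windowed linear regression of ammonium
   drawdown curves, conversion to membrane-area-specific rates, duplicate
   run averaging, the Arrhenius-type temperature coefficient
   R(T₁) = R(T₀)·θ^(T₁−T₀), the two-point statistic
   100·(R₁−R₀)/R₀/(T₁−T₀) %/°C, and nitrite-accumulation fractions —
   driven by a seeded synthetic campaign generator for testing without
   measurement data.

## Model core

Solutes (O₂, NH₄⁺, NO₂⁻, NO₃⁻) are quasi-steady in the film:

    planar:       D_f S'' + r(S, X) = 0
    cylindrical:  (1/r) (r D_f S')' + r(S, X) = 0

with boundary conditions J = k_M·(C_sat(gas) − S) at the membrane face
(O₂ only; zero flux otherwise) and J = D_w·(S_bulk − S)/L_LBL at the liquid
face. Growth follows r_AOO = μ_AOO(T)·S_NH4/(K_NH4+S_NH4)·S_O2/(K_O2+S_O2)·X
(analogously for NOO on nitrite) with yields Y so that oxygen consumption is
(3.43−Y_AOO)/Y_AOO resp. (1.14−Y_NOO)/Y_NOO g O₂ per g COD. Biomass volume
fractions ε_k(x) advect with the growth-induced velocity and erode at the
surface at exactly the film growth velocity, keeping thickness constant.
All areal rates are referenced to the membrane outer area.

## Worked example

```python
from mabrsim import (KineticParameterSet, TemperatureRuleSet, SolverOptions,
                     run_simulation_matrix)

res = run_simulation_matrix(KineticParameterSet(), TemperatureRuleSet(),
                            SolverOptions())
print(res.rates.head(4).to_string(index=False))
```

prints (g N m⁻² d⁻¹ at 35 mg N/L bulk ammonium; `Lf` film and `L_LBL`
boundary-layer thickness in m):

```
 temperature      Lf   L_LBL  rate_at_35  limiting_slope
           8   5e-05   5e-05        1.75           0.639
          30   5e-05   5e-05        5.73            2.24
           8   5e-05 0.00025        1.78           0.347
          30   5e-05 0.00025        5.02           0.803
```

A thin (50 μm) film at 8 °C removes 1.75 g N m⁻² d⁻¹ and 5.73 at 30 °C —
about 10.3 %/°C. The same comparison for a 150 μm film gives only
~3.7 %/°C: internal oxygen transfer buffers the kinetics. The
`limiting_slope` column is the first-order coefficient of rate versus bulk
ammonium over 0.1–1.0 mg N/L (units m/d), the response used for the
sensitivity analysis under strong donor limitation. Run
`python examples/simulation_matrix.py` for the full matrix, and see the
other scripts in `examples/` (temperature laws, steady-state profiles,
diffusivity sensitivities, synthetic batch campaigns) — each prints its
numbers with a short interpretation.

The batch pipeline on a synthetic campaign
(`python examples/batch_campaign.py`) generates duplicate drawdown tests at
30…8 °C with θ_true = 1.026 and recovers
`theta = 1.0238 (+/- 0.0022)` from the noisy series, alongside the
cold-water nitrite accumulation trend (7.5 % of oxidised N at 30 °C rising
to ~54 % at 8 °C).

A thin CLI wraps the same library:

```bash
mabrsim simulate-matrix --out results/
mabrsim synth-campaign --out campaign/ --seed 3
mabrsim analyze-batch campaign/batch_*.tsv --window 10 20
mabrsim calibrate --free mu_max_AOO --free rho_X
```

## Configuration

Every constant is overridable from a single YAML file (see
`src/mabrsim/data/defaults.yaml` for the shipped defaults and
`mabrsim.config.RunConfig` for the schema). The default kinetic set was
produced by `calibrate_to_matrix`, which fits {μ_max of both guilds, the
solids density ρ_X, the in-biofilm diffusivity ratio} to a set of target
matrix rates by bounded least squares; `docs/methods.md` documents the
model, its assumptions, the parameterisation and its limits.
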