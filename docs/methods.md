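# Methods

This note documents the model equations, the numerical schemes, the
parameterisation, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one defensible option
existed. Units throughout: lengths m, time d, solutes g/m³ (= mg/L),
biomass g COD/m³; temperatures are given in °C and converted to Kelvin only
inside exponential laws.

## 1. Two-step nitrification model

Two autotrophic guilds are modelled: ammonia oxidisers (AOO,
NH₄⁺ → NO₂⁻) and nitrite oxidisers (NOO, NO₂⁻ → NO₃⁻). Four processes
(growth and decay of each guild) act on seven components
(S_O2, S_NH4, S_NO2, S_NO3, X_AOO, X_NOO, X_I) through a Petersen-style
stoichiometry matrix. Per g COD of growth, the oxygen coefficients are
−(3.43−Y_AOO)/Y_AOO and −(1.14−Y_NOO)/Y_NOO; nitrogen incorporation into
biomass is i_N g N/g COD, and nitrogen is conserved within every process to
machine precision (a property test enforces this). Decay routes a fraction
f_I of the biomass to particulate inerts; the remainder is oxidised,
consuming (1−f_I) g O₂ and releasing i_N(1−f_I) g N as ammonium per g COD.

**Oxygen-switched decay.** Endogenous respiration carries an oxygen Monod
switching function (each guild's own K_O2). Without it, decay in the anoxic
outer region of a counter-diffusional film would demand oxygen that cannot
be there, and the quasi-steady oxygen problem has no non-negative solution.
The consequence is that biomass in anoxic zones persists rather than
lysing; since those zones are also inactive, the effect on predicted fluxes
is second-order. Anoxic decay pathways (e.g. on nitrate) are out of scope.

pH and alkalinity limitation, anammox and heterotrophs, and inhibition
kinetics are deliberately excluded.

## 2. Temperature-correction laws

| quantity | law | default |
|---|---|---|
| μ_max, b | Arrhenius power law v·θ^(T−T_ref) | θ_μ,AOO = 1.095, θ_μ,NOO = 1.06, θ_b = 1.04 |
| O₂ solubility | van't Hoff, H(T) = H_ref·exp(K·(1/T_K − 1/T_ref,K)) | H_ref = 43 g m⁻³ bar⁻¹, K = 1700 K |
| aqueous diffusivity | Stokes–Einstein D·(T_K/T_ref,K)·(η_ref/η(T)), Vogel viscosity ln η = −3.7188 + 578.919/(T_K−137.546) | D_ref(20 °C): O₂ 1.98, NH₄ 1.80, NO₂/NO₃ 1.70 ×10⁻⁹ m²/s |
| membrane permeance | Arrhenius in 1/T, exp(−E_a/R·(1/T_K−1/T_ref,K)) | k_M(20 °C) = 2.5 m/d, E_a = 8.4 kJ/mol |

θ_μ,AOO = 1.095 is the classic ~9.5 %/°C growth acceleration of
*Nitrosomonas*-type AOB; NOB are taken less temperature-sensitive
(θ = 1.06). The Stokes–Einstein/Vogel combination yields an effective
diffusivity factor of ≈1.028 per °C over 8–30 °C, squarely in the usual
1.02–1.03 bracket (tested). Oxygen solubility falls ~35 % from 8 to 30 °C.
These opposing trends are the mechanistic heart of the package: a
transport-controlled biofilm inherits the weak temperature dependence of
diffusion and solubility, not the strong one of growth kinetics.

**Membrane permeance.** The membrane flux law is J = k_M(T)·(C_sat − S(0))
with C_sat from Henry's law at the gas-side O₂ partial pressure (default
0.21·(1.013+0.235) bar ≈ 0.262 bar, i.e. air at 235 mbar gauge). The
default k_M = 2.5 m/d is an *effective module-scale* permeance: it caps
oxygen delivery at k_M·C_sat ≈ 25–35 g O₂ m⁻² d⁻¹ over 8–30 °C, the range
actually reported for dense-PDMS MABR modules under air. Ideal
single-fibre permeability estimates (≈600 Barrer through a 135 μm wall,
k_M ≈ 7–10 m/d) overstate module oxygen transfer several-fold; with such
values the model's warm-water rates exceed observed MABR performance by
roughly a factor of two. The wall thickness default (135 μm) follows from
the 280/550 μm fibre diameters.

## 3. Biofilm solver

**Geometry.** 1D through the film, planar or cylindrical (default:
cylindrical, fibre outer radius 275 μm, biofilm on the outside). All
boundary fluxes are reported per membrane outer area; the liquid-face area
exceeds it by (R_m+L_f)/R_m in cylindrical mode, which is why a thick film
"sees" more bulk liquid per fibre.

**Quasi-steady solutes.** With biomass frozen, the steady
reaction–diffusion problem is discretised by finite volumes on a uniform
grid (default 100 cells) and solved by damped Newton with an analytic
block-banded Jacobian (bandwidth 4, direct banded solve). The liquid
boundary layer is a stagnant film in series (flux law at the surface), not
a discretised second domain — equivalent at steady state and cheaper. Both
boundary conductances include the adjacent half-cell diffusive resistance
*and a second-order source correction* −q·Δx²/(8 D_f) in the driving
force; with it the scheme is exact for constant-source parabolic profiles,
which the zero-order-sink oracle test exploits (< 10⁻⁶ relative error on
200 cells against the closed form). Newton iterates to a residual of
10⁻¹⁰ relative to the boundary flux scale, so that steady-state flux
balances close to better than 10⁻⁶ even for minor solutes. Negative
concentrations are clipped inside the rate laws during iteration and
checked (≤ 10⁻⁸ relative) at convergence.

**Biomass dynamics.** Volume fractions ε_k(x) (AOO, NOO, inerts) obey the
Wanner–Gujer mixed-culture formulation

    ∂ε_k/∂t = σ_k ε_k − ∂(u ε_k)/∂x,   u(x) = (1/E)·∫₀ˣ Σ_k σ̃_k ε_k dz

with σ_k = μ_k − b_k, σ̃_k = μ_k − (1−f_I) b_k (volume production including
the inert residue), and E = Σ_k ε_k. The 1/E factor is the incompressible
solid-matrix form of the advection velocity; it is the variant under which
the canonical closure properties hold exactly — a uniform single guild
without decay keeps its total biomass (growth exactly exchanged against
detachment), equal net growth preserves proportions, and the total solids
fraction E is conserved, so Σε ≤ 1 by construction. The film is eroded at
the surface at exactly u(L_f) (advective outflow through the fixed
boundary), which *is* the constant-thickness detachment closure; when
u(L_f) < 0 nothing enters, so thickness is constant in all regimes.

Integration is semi-implicit: given frozen solutes, the update is linear in
ε, solved per guild with first-order upwind advection (tridiagonal,
unconditionally stable), with the advection velocity Picard-iterated to
self-consistency with the updated fractions. The lagged-velocity shortcut
was tried first and rejected: it lets E drift during fast transients,
which manifested as spurious dependence of the steady state on the initial
composition. With the consistent velocity the steady state is independent
of the initial guild split to < 10⁻⁵ relative (tested).

**Steady state.** The solver alternates solute solves and biomass steps,
growing Δt geometrically (cap 2 d, and 8/max|σ|). Every 5 simulated days
it probes the relative change of each guild's depth-integrated biomass and
of the NH₄ removal rate; both below 10⁻⁴ ends the run. A guild whose mean
volume fraction has fallen below 0.1 % counts as washed out (otherwise the
exponential tail of a dying guild blocks the probe for thousands of
simulated days). Default initial condition: ε_AOO = ε_NOO = 0.15 uniform,
solutes at bulk values. Typical cost: 0.1–1 s per scenario.

Because E is conserved, the initial total solids fraction (0.3) fixes the
film's biomass capacity at 0.3·ρ_X. ρ_X is therefore interpreted as the
*solid-phase* density; the calibrated default (141 800 g COD/m³) puts
≈ 42.5 kg COD/m³ of film volume, an ordinary nitrifying-biofilm density.

## 4. Parameterisation and calibration

The two-step kinetic constants behind the original reactor simulations are
not published; the package instead ships a standard nitrification set whose
free members were calibrated against the eight printed matrix rates.
`calibrate_to_matrix` performs bounded least squares (scipy `trf`) on the
relative errors over the scenario matrix with free parameters drawn from
{μ_max,AOO, μ_max,NOO, ρ_X, biofilm diffusivity ratio} inside literature
bounds (0.2–3 /d, 0.1–2.5 /d, 15–150 kg COD/m³, 0.4–1.0).

Two fixed defaults were chosen once, on literature grounds, before the
final calibration: the effective membrane permeance (§2) and the oxygen
half-saturations K_O2,AOO = 0.60, K_O2,NOO = 0.43 g O₂/m³. The latter
encodes a *Nitrospira*-type high-affinity NOB — the genus that dominates
the system this model describes. It matters structurally: with a
low-affinity NOB the nitrite oxidisers wash out of every scenario, whereas
a high-affinity NOB persists in the low-oxygen fringe of thick films,
consumes part of the oxygen budget there, and produces the observed
crossover — thick films outperform thin ones at 8 °C (more biomass,
kinetics-limited) but underperform them at 30 °C (oxygen-limited, with NOO
competing for O₂).

Calibrated defaults: μ_max,AOO = 0.493 /d, μ_max,NOO = 0.699 /d,
ρ_X = 141 800 g COD/m³, diffusivity ratio 0.420 (all at 20 °C). At these
values the eight matrix cells are reproduced with relative errors between
−15 % and +8 % (the thin-film/thick-LBL warm cell is the worst; the
remaining tension is structural — no admissible parameter moves it without
degrading its neighbours). Restarting the calibration from these defaults
does not move them.

## 5. Scenario experiments

* `evaluate_rate_at_bulk` — steady removal rate at a stated bulk ammonium
  concentration with the biomass distribution of the scenario's steady
  state (solutes re-solved, biomass frozen when the concentration differs
  from the scenario's).
* `limiting_rate_slope` — OLS slope of rate versus bulk NH₄ over ten
  evenly spaced points in 0.1–1.0 g/m³, biomass frozen at the scenario
  steady state. The slope (units m/d) is the donor-limited first-order
  coefficient; at one extreme it approaches the LBL film conductance
  D_w/L_LBL (tested against film theory).
* `temperature_sensitivity` — 100·(R_hi−R_lo)/R_lo/(T_hi−T_lo); shared
  with the batch module as `percent_per_degree`. Matrix-level summaries
  average the two LBL settings per thickness; the per-cell values are
  reported too.
* `diffusivity_sensitivity` — central relative sensitivity
  [R(+δ)−R(−δ)]/(2δR₀) with δ = 25 % on the aqueous reference diffusivity
  of O₂ or NH₄ (the in-film value scales along). The biofilm is
  re-equilibrated at each perturbed value by default (the steady-state
  framing implies it); a frozen-biomass mode is exposed via a flag.
  Classification thresholds: 0.200 (moderately high), 0.600 (high).

## 6. Synthetic batch campaigns

The generator emulates the statistical structure the batch analysis
assumes: a feed tank at 50 mg N/L, areal removal R(T) = R_T0·θ^(T−T0)
(defaults 3.0 g N m⁻² d⁻¹ at 20 °C, θ = 1.026) moderated by a bulk Monod
factor C/(K_app+C) with K_app = 1 g/m³ (near zero-order above ~2.5 mg/L),
V = 38.3 L, A = 3.74 m², 15-min sampling down to 1 mg N/L, removed N split
into NO₂/NO₃ by a linear-in-T nitrite fraction anchored at 53.5 % (8 °C)
and 7.4 % (30 °C), and additive Gaussian noise (σ = 0.2 g N/m³, truncated
at zero) on every measured concentration. A campaign is the descending
temperature ladder 30–24–18–12–8 °C followed by its reverse, i.e.
duplicates at each temperature. Sub-seeds derive from (seed, series index)
via `numpy` `SeedSequence`, so each series is reproducible in isolation.

What it does *not* emulate: sensor drift, sampling losses, autocorrelated
noise, pH/alkalinity feedback, or any change of the biofilm between runs.
Passing recovery tests therefore demonstrate estimator correctness under
the assumed error model, not robustness to real-world artefacts. Note one
deliberate property: the Monod factor depresses windowed rates by ~7 %
below R(T) in the 10–20 mg/L window, but identically at every temperature,
so θ estimates are unbiased (the 200-replicate test finds the mean θ̂
within 10⁻⁵ of truth) while absolute rates are window-dependent — the same
window dependence the analysis itself reports. A `rate_model` hook lets
the generator draw fluxes from the biofilm model instead ("mechanistic
mode"); the cheap law is the default for fast tests.

**Batch analysis conventions.** Window membership is inclusive on measured
NH₄; time is counted from the first in-window sample; OLS (not orthogonal)
regression; areal = volumetric·V/A with V and A per-series metadata (the
liquid volume of the original rig is not recoverable, so V is always an
explicit input); θ standard errors are the asymptotic (covariance-based)
ones from the Levenberg–Marquardt fit.

## 7. Known limitations

* Nitrite accumulation at cold temperatures is *not* reproduced by the
  mechanistic model (the calibrated NOO keeps up at 8 °C); it is present
  only in the synthetic generator's empirical nitrite-fraction law.
  Capturing it mechanistically would require temperature-dependent NOB
  kinetics beyond a single Arrhenius base.
* The gas lumen is a fixed-composition mixed compartment; axial depletion
  along the fibre is ignored.
* Constant thickness by construction: growth/sloughing cycles and
  long-term thickness drift (a plausible cause of run-to-run differences
  in real campaigns) are out of scope.
* One steady state is computed per scenario; the washout-floor convention
  (0.1 % mean volume fraction) decides marginal NOO persistence.
* The 30 °C thin-film/thick-LBL matrix cell is systematically ~15 % low;
  see §4.
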