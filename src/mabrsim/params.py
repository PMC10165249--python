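"""Kinetics, stoichiometry and temperature-correction laws for two-step
nitrification.

The model describes two autotrophic guilds: ammonia oxidisers (AOO),
converting NH4+ to NO2-, and nitrite oxidisers (NOO), converting NO2- to
NO3-.  Growth follows double-Monod kinetics on the nitrogen substrate and
dissolved oxygen; decay is first-order endogenous respiration with an inert
residue.  Units are fixed package-wide: lengths in m, time in d, solutes in
g/m3 (= mg/L), biomass in g COD/m3; temperatures are accepted in degrees
Celsius and converted to Kelvin only inside exponential laws.

Temperature enters through:

* an Arrhenius-type power law ``v(T) = v_ref * theta**(T - T_ref)`` for
  growth and decay rates,
* a van't Hoff law for the Henry (oxygen solubility) constant,
* Stokes-Einstein scaling ``D ~ T/eta(T)`` with a Vogel water-viscosity
  correlation for aqueous diffusivities,
* an Arrhenius law in 1/T for the membrane oxygen permeance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .exceptions import (
    InvalidParameterError,
    InvalidStateError,
    TemperatureRangeError,
)

#: Solute ordering used by every array in the package.
SOLUTES = ("O2", "NH4", "NO2", "NO3")
I_O2, I_NH4, I_NO2, I_NO3 = range(4)

#: Particulate guild ordering (volume fractions).
GUILDS = ("AOO", "NOO", "INERT")
I_AOO, I_NOO, I_INERT = range(3)

#: Process ordering of the stoichiometry matrix.
PROCESSES = ("growth_AOO", "growth_NOO", "decay_AOO", "decay_NOO")
#: Component ordering of the stoichiometry matrix columns.
COMPONENTS = ("S_O2", "S_NH4", "S_NO2", "S_NO3", "X_AOO", "X_NOO", "X_I")

# Theoretical oxygen demand of the two oxidation steps, g O2 per g N.
COD_NH4_TO_NO2 = 3.43
COD_NO2_TO_NO3 = 1.14

R_GAS = 8.314  # J/(mol K)
_T0K = 273.15


def _kelvin(T: float) -> float:
    return T + _T0K


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameterSet:
    """Stoichiometric and kinetic constants of both nitrifier guilds at the
    reference temperature ``T_ref``.

    Defaults are a standard activated-sludge-model style nitrification set,
    fine-tuned with :func:`mabrsim.experiments.calibrate_to_matrix` against
    the membrane-aerated biofilm simulation matrix this package reproduces.
    Every value can be overridden from a configuration file.
    """

    mu_max_AOO: float = 0.493  # 1/d, maximum specific growth rate of AOO
    mu_max_NOO: float = 0.699  # 1/d, maximum specific growth rate of NOO
    K_NH4: float = 1.0  # g N/m3, ammonium half-saturation (AOO)
    K_NO2: float = 0.5  # g N/m3, nitrite half-saturation (NOO)
    K_O2_AOO: float = 0.60  # g O2/m3
    K_O2_NOO: float = 0.43  # g O2/m3, Nitrospira-type high O2 affinity
    Y_AOO: float = 0.15  # g COD biomass per g N oxidised
    Y_NOO: float = 0.041  # g COD biomass per g N oxidised
    b_AOO: float = 0.05  # 1/d, decay coefficient at T_ref
    b_NOO: float = 0.05  # 1/d
    i_N: float = 0.07  # g N per g COD biomass
    f_I: float = 0.1  # inert fraction produced on decay
    rho_X: float = 141800.0  # g COD/m3, solid-phase biomass density
    T_ref: float = 20.0  # degC

    def __post_init__(self):
        positive = (
            "mu_max_AOO", "mu_max_NOO", "K_NH4", "K_NO2", "K_O2_AOO",
            "K_O2_NOO", "Y_AOO", "Y_NOO", "b_AOO", "b_NOO", "i_N", "rho_X",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0 <= self.f_I < 1:
            raise InvalidParameterError("f_I must lie in [0, 1)")
        # oxygen stoichiometry of growth must stay a consumption term
        if not self.Y_AOO < COD_NH4_TO_NO2:
            raise InvalidParameterError("Y_AOO must be < 3.43 g COD/g N")
        if not self.Y_NOO < COD_NO2_TO_NO3:
            raise InvalidParameterError("Y_NOO must be < 1.14 g COD/g N")


def _default_D_ref() -> dict:
    # aqueous diffusivities at 20 degC, m2/s -> m2/d
    day = 86400.0
    return {
        "O2": 1.98e-9 * day,
        "NH4": 1.80e-9 * day,
        "NO2": 1.70e-9 * day,
        "NO3": 1.70e-9 * day,
    }


@dataclass(frozen=True)
class TemperatureRuleSet:
    """Per-parameter temperature-correction laws.

    ``theta_*`` are Arrhenius bases per degC; ``henry_ref`` is the dissolved
    oxygen concentration in equilibrium with 1 bar O2 partial pressure at
    ``T_ref``; ``perm_ref`` is the membrane oxygen permeance (flux per unit
    dissolved-concentration driving force) at ``T_ref``.
    """

    theta_mu_AOO: float = 1.095
    theta_mu_NOO: float = 1.06
    theta_b: float = 1.04
    henry_ref: float = 43.0  # g O2/m3 per bar O2
    henry_vant_hoff_K: float = 1700.0  # K
    D_ref: Mapping[str, float] = field(default_factory=_default_D_ref)
    biofilm_diffusivity_ratio: float = 0.420
    perm_ref: float = 2.5  # m/d, effective module-scale membrane permeance
    perm_activation_energy: float = 8400.0  # J/mol
    T_ref: float = 20.0  # degC

    def __post_init__(self):
        for name in ("theta_mu_AOO", "theta_mu_NOO", "theta_b"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0 < self.biofilm_diffusivity_ratio <= 1:
            raise InvalidParameterError(
                "biofilm_diffusivity_ratio must lie in (0, 1]"
            )
        if not self.henry_ref > 0 or not self.perm_ref > 0:
            raise InvalidParameterError("henry_ref and perm_ref must be positive")
        for sol in SOLUTES:
            if sol not in self.D_ref or not self.D_ref[sol] > 0:
                raise InvalidParameterError(f"D_ref missing/non-positive for {sol}")

    @property
    def D_ref_array(self) -> np.ndarray:
        """Aqueous reference diffusivities ordered as :data:`SOLUTES`, m2/d."""
        return np.array([self.D_ref[s] for s in SOLUTES])

    def with_scaled_diffusivity(self, solute: str, factor: float) -> "TemperatureRuleSet":
        """Return a copy with ``D_ref[solute]`` multiplied by ``factor``."""
        if solute not in SOLUTES:
            raise KeyError(solute)
        d = dict(self.D_ref)
        d[solute] = d[solute] * factor
        return replace(self, D_ref=d)


# ---------------------------------------------------------------------------
# temperature-correction laws
# ---------------------------------------------------------------------------


def arrhenius_correct(value_ref: float, T: float, T_ref: float, theta: float) -> float:
    """Arrhenius-type power-law correction ``value_ref * theta**(T - T_ref)``.

    The identity holds exactly at ``T == T_ref`` and the map is its own
    inverse under exchange of ``T`` and ``T_ref``.
    """
    if not value_ref > 0:
        raise InvalidParameterError("value_ref must be strictly positive")
    if not theta > 0:
        raise InvalidParameterError("theta must be strictly positive")
    return value_ref * theta ** (T - T_ref)


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of water in mPa s from the Vogel equation.

    ``ln eta = A + B / (C + T_K)`` with A = -3.7188, B = 578.919 K,
    C = -137.546 K; accurate to about 1 % between 0 and 100 degC.
    """
    TK = _kelvin(T)
    return math.exp(-3.7188 + 578.919 / (TK - 137.546))


def water_diffusivity(D_ref: float, T: float, T_ref: float = 20.0) -> float:
    """Aqueous diffusivity at temperature ``T`` by Stokes-Einstein scaling.

    ``D(T) = D_ref * (T_K / T_ref_K) * (eta(T_ref) / eta(T))``; strictly
    increasing in T.  Over 8-30 degC the effective per-degC factor is about
    1.028.
    """
    if not D_ref > 0:
        raise InvalidParameterError("D_ref must be strictly positive")
    return (
        D_ref
        * (_kelvin(T) / _kelvin(T_ref))
        * (water_viscosity(T_ref) / water_viscosity(T))
    )


def oxygen_saturation(T: float, pO2: float, rules: TemperatureRuleSet) -> float:
    """Equilibrium dissolved O2 concentration (g/m3) at partial pressure
    ``pO2`` (bar) via a van't Hoff corrected Henry constant.

    Strictly decreasing in T for fixed ``pO2 > 0``; valid for -5..50 degC.
    """
    if pO2 < 0:
        raise InvalidParameterError("pO2 must be non-negative")
    if not -5.0 <= T <= 50.0:
        raise TemperatureRangeError(
            f"oxygen_saturation valid for -5..50 degC, got {T}"
        )
    TK, TrefK = _kelvin(T), _kelvin(rules.T_ref)
    henry = rules.henry_ref * math.exp(
        rules.henry_vant_hoff_K * (1.0 / TK - 1.0 / TrefK)
    )
    return pO2 * henry


def membrane_permeance(T: float, rules: TemperatureRuleSet) -> float:
    """Membrane oxygen permeance (m/d) at temperature ``T``.

    Arrhenius in 1/T: ``perm_ref * exp(-Ea/R * (1/T_K - 1/T_ref_K))``;
    increasing in T for positive activation energy.
    """
    TK, TrefK = _kelvin(T), _kelvin(rules.T_ref)
    Ea = rules.perm_activation_energy
    return rules.perm_ref * math.exp(-(Ea / R_GAS) * (1.0 / TK - 1.0 / TrefK))


@dataclass(frozen=True)
class TemperatureAdjusted:
    """All temperature-corrected constants needed by the biofilm solver at a
    single operating temperature (precomputed once per scenario)."""

    T: float
    mu_AOO: float
    mu_NOO: float
    b_AOO: float
    b_NOO: float
    D_water: np.ndarray  # (4,) m2/d, ordered as SOLUTES
    D_film: np.ndarray  # (4,) m2/d
    permeance: float  # m/d


def temperature_adjusted(
    kin: KineticParameterSet, rules: TemperatureRuleSet, T: float
) -> TemperatureAdjusted:
    """Apply every temperature-correction law at operating temperature ``T``."""
    Dw = np.array(
        [water_diffusivity(rules.D_ref[s], T, rules.T_ref) for s in SOLUTES]
    )
    return TemperatureAdjusted(
        T=T,
        mu_AOO=arrhenius_correct(kin.mu_max_AOO, T, kin.T_ref, rules.theta_mu_AOO),
        mu_NOO=arrhenius_correct(kin.mu_max_NOO, T, kin.T_ref, rules.theta_mu_NOO),
        b_AOO=arrhenius_correct(kin.b_AOO, T, kin.T_ref, rules.theta_b),
        b_NOO=arrhenius_correct(kin.b_NOO, T, kin.T_ref, rules.theta_b),
        D_water=Dw,
        D_film=rules.biofilm_diffusivity_ratio * Dw,
        permeance=membrane_permeance(T, rules),
    )


# ---------------------------------------------------------------------------
# stoichiometry and rates
# ---------------------------------------------------------------------------


def stoichiometry_matrix(kin: KineticParameterSet) -> np.ndarray:
    """Stoichiometric coefficients, shape (4 processes, 7 components), per
    g COD of process turnover.

    Rows are :data:`PROCESSES`, columns :data:`COMPONENTS`.  Nitrogen is
    conserved within each process when biomass N content is counted at
    ``i_N``; growth oxygen coefficients are ``-(3.43 - Y)/Y`` (AOO) and
    ``-(1.14 - Y)/Y`` (NOO).  Decay routes a fraction ``f_I`` of the biomass
    to inerts; the remainder is oxidised with its nitrogen released as NH4.
    """
    Y_A, Y_N = kin.Y_AOO, kin.Y_NOO
    iN, fI = kin.i_N, kin.f_I
    return np.array(
        [
            # S_O2,                 S_NH4,            S_NO2,  S_NO3, X_AOO, X_NOO, X_I
            [-(COD_NH4_TO_NO2 - Y_A) / Y_A, -(1 / Y_A + iN), 1 / Y_A, 0.0, 1.0, 0.0, 0.0],
            [-(COD_NO2_TO_NO3 - Y_N) / Y_N, -iN, -1 / Y_N, 1 / Y_N, 0.0, 1.0, 0.0],
            [-(1 - fI), iN * (1 - fI), 0.0, 0.0, -1.0, 0.0, fI],
            [-(1 - fI), iN * (1 - fI), 0.0, 0.0, 0.0, -1.0, fI],
        ]
    )


def stoichiometry_table(kin: KineticParameterSet):
    """The stoichiometry matrix as a labelled :class:`pandas.DataFrame`."""
    import pandas as pd

    return pd.DataFrame(stoichiometry_matrix(kin), index=PROCESSES, columns=COMPONENTS)


def _monod(S, K):
    return S / (K + S)


def process_rates(
    S,
    X,
    kin: KineticParameterSet,
    rules: TemperatureRuleSet | None = None,
    T: float | None = None,
    o2_limited_decay: bool = True,
):
    """Per-process turnover rates, g COD/(m3 d).

    Parameters
    ----------
    S : array_like, shape (4,) or (4, n)
        Solute concentrations ordered as :data:`SOLUTES`, g/m3.
    X : array_like, shape (2,) or (2, n)
        Active biomass concentrations (AOO, NOO), g COD/m3.
    rules, T : optional
        When both are given, growth and decay rates are temperature
        corrected; otherwise reference-temperature values apply.
    o2_limited_decay : bool
        Apply a Monod oxygen switching function (the guild's own K_O2) to
        endogenous decay, so respiration shuts down in anoxic zones.

    Returns
    -------
    ndarray, shape (4,) or (4, n), ordered as :data:`PROCESSES`.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(S < 0):
        raise InvalidStateError("negative solute concentration")
    if np.any(X < 0):
        raise InvalidStateError("negative biomass concentration")
    if rules is not None and T is not None:
        adj = temperature_adjusted(kin, rules, T)
        mu_A, mu_N, b_A, b_N = adj.mu_AOO, adj.mu_NOO, adj.b_AOO, adj.b_NOO
    else:
        mu_A, mu_N, b_A, b_N = kin.mu_max_AOO, kin.mu_max_NOO, kin.b_AOO, kin.b_NOO

    o2, nh4, no2 = S[I_O2], S[I_NH4], S[I_NO2]
    x_a, x_n = X[0], X[1]
    sw_a = _monod(o2, kin.K_O2_AOO) if o2_limited_decay else np.ones_like(o2)
    sw_n = _monod(o2, kin.K_O2_NOO) if o2_limited_decay else np.ones_like(o2)
    return np.array(
        [
            mu_A * _monod(nh4, kin.K_NH4) * _monod(o2, kin.K_O2_AOO) * x_a,
            mu_N * _monod(no2, kin.K_NO2) * _monod(o2, kin.K_O2_NOO) * x_n,
            b_A * sw_a * x_a,
            b_N * sw_n * x_n,
        ]
    )


def net_conversion_rates(
    S,
    X,
    kin: KineticParameterSet,
    rules: TemperatureRuleSet | None = None,
    T: float | None = None,
    o2_limited_decay: bool = True,
):
    """Per-component volumetric conversion rates, g/(m3 d).

    Matrix product of :func:`process_rates` with the stoichiometry matrix;
    nitrogen closes to machine precision by construction (biomass counted at
    ``i_N`` g N per g COD).  Returns shape (7,) or (7, n) ordered as
    :data:`COMPONENTS`.
    """
    r = process_rates(S, X, kin, rules, T, o2_limited_decay)
    nu = stoichiometry_matrix(kin)
    return np.tensordot(nu.T, r, axes=1)
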