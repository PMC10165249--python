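"""Synthetic batch-campaign generator.

Emulates reactor drawdown experiments: a feed tank is filled to about
50 mg N/L ammonium, the membrane biofilm removes nitrogen at an areal rate
R(T) = R_T0 * theta**(T - T0) moderated by a Monod factor in the bulk
concentration (near zero-order above a few mg/L), and the tank is sampled
every 15 min.  Removed nitrogen reappears as nitrite and nitrate in a
temperature-dependent split (more nitrite at colder temperatures), and
independent Gaussian measurement noise, truncated at zero, is added to
every measured concentration.  Campaigns visit a descending temperature
ladder and then repeat it in reverse, giving duplicate runs at every
temperature.  All randomness is seeded and bit-reproducible; sub-seeds are
derived per series so any single series can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .batch import (
    DEFAULT_LIQUID_VOLUME,
    DEFAULT_MEMBRANE_AREA,
    MINUTES_PER_DAY,
    BatchSeries,
)
from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class CampaignSpec:
    """Design of a synthetic batch campaign.

    ``temperatures`` is the first-run ladder (the second run is the same
    ladder reversed); ``R_T0`` and ``theta`` define the true areal rate
    law; ``K_app`` is the apparent bulk half-saturation making the
    drawdown near zero-order above ~2.5 mg/L; ``noise_sd`` is the additive
    measurement noise standard deviation in g N/m3.  The nitrite fraction
    of the removed nitrogen falls linearly with temperature between the
    anchors ``(8 degC, nitrite_frac_8)`` and ``(30 degC, nitrite_frac_30)``.
    """

    temperatures: Sequence[float] = (30.0, 24.0, 18.0, 12.0, 8.0)
    R_T0: float = 3.0  # g N m-2 d-1 at T0
    theta: float = 1.026
    T0: float = 20.0
    initial_NH4: float = 50.0  # g N/m3
    sample_interval_min: float = 15.0
    volume: float = DEFAULT_LIQUID_VOLUME
    area: float = DEFAULT_MEMBRANE_AREA
    noise_sd: float = 0.2  # g N/m3
    K_app: float = 1.0  # g N/m3
    nitrite_frac_30: float = 0.074
    nitrite_frac_8: float = 0.535
    stop_NH4: float = 1.0  # g N/m3, sampling stops once NH4 falls below
    max_samples: int = 400
    seed: int = 0

    def __post_init__(self):
        if any(not 0 <= T <= 40 for T in self.temperatures):
            raise InvalidParameterError("temperatures must lie in [0, 40] degC")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        for f in (self.nitrite_frac_30, self.nitrite_frac_8):
            if not 0 <= f <= 1:
                raise InvalidParameterError("nitrite fractions must lie in [0, 1]")
        if not (self.R_T0 > 0 and self.theta > 0 and self.K_app > 0):
            raise InvalidParameterError("R_T0, theta, K_app must be positive")

    def areal_rate(self, T: float) -> float:
        """True maximum areal removal rate at temperature T, g N m-2 d-1."""
        return self.R_T0 * self.theta ** (T - self.T0)

    def nitrite_fraction(self, T: float) -> float:
        """Fraction of removed N appearing as nitrite at temperature T."""
        slope = (self.nitrite_frac_30 - self.nitrite_frac_8) / (30.0 - 8.0)
        return float(np.clip(self.nitrite_frac_8 + slope * (T - 8.0), 0.0, 1.0))


def _series_seed(spec: CampaignSpec, index: int) -> np.random.SeedSequence:
    """Deterministic sub-seed for series ``index`` of a campaign."""
    return np.random.SeedSequence([int(spec.seed), int(index)])


def generate_batch_series(
    spec: CampaignSpec,
    T: float,
    run: str = "first",
    seed=None,
    rate_model: Callable[[float, float], float] | None = None,
) -> BatchSeries:
    """Generate one batch drawdown series at temperature ``T``.

    Integrates the bulk mass balance ``dC/dt = -R(T) (A/V) C/(K_app + C)``
    (or, when ``rate_model(T, C)`` is supplied, that areal flux instead),
    samples every ``sample_interval_min`` minutes until the true NH4 drops
    below ``stop_NH4``, splits the removed nitrogen into NO2/NO3 by the
    nitrite-fraction law and then adds the measurement noise.  Nitrogen is
    conserved exactly before noise.
    """
    if seed is None:
        index = 0 if run == "first" else 1
        seed = _series_seed(spec, hash((round(float(T), 6), index)) % 2**31)
    rng = np.random.default_rng(seed)

    AV = spec.area / spec.volume  # 1/m
    if rate_model is None:
        def flux(T_, C):
            return spec.areal_rate(T_) * C / (spec.K_app + C)
    else:
        flux = rate_model

    def rhs(t, y):
        return [-AV * flux(T, max(y[0], 0.0))]

    dt_d = spec.sample_interval_min / MINUTES_PER_DAY
    t_grid = [0.0]
    # generous horizon: zero-order time to stop level plus first-order tail
    R = max(flux(T, spec.initial_NH4), 1e-9)
    horizon = (spec.initial_NH4 / (AV * R)) * 3.0 + 10 * dt_d
    n_max = min(spec.max_samples, int(horizon / dt_d) + 2)
    t_eval = np.arange(n_max) * dt_d
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), [spec.initial_NH4], t_eval=t_eval,
        rtol=1e-9, atol=1e-10, method="RK45",
    )
    C = np.maximum(sol.y[0], 0.0)
    keep = C >= spec.stop_NH4
    if keep.any():
        last = int(np.nonzero(keep)[0][-1]) + 1
    else:
        last = len(C)
    t_samp, C_samp = t_eval[:last], C[:last]

    removed = spec.initial_NH4 - C_samp
    f_no2 = spec.nitrite_fraction(T)
    no2 = f_no2 * removed
    no3 = (1.0 - f_no2) * removed

    def noisy(x):
        return np.maximum(x + rng.normal(0.0, spec.noise_sd, size=x.shape), 0.0)

    if spec.noise_sd > 0:
        nh4_m, no2_m, no3_m = noisy(C_samp), noisy(no2), noisy(no3)
    else:
        nh4_m, no2_m, no3_m = C_samp, no2, no3
    return BatchSeries(
        time_d=t_samp,
        nh4=nh4_m,
        no2=no2_m,
        no3=no3_m,
        temperature=T,
        volume=spec.volume,
        area=spec.area,
        run=run,
    )


def generate_campaign(spec: CampaignSpec) -> tuple[list[BatchSeries], dict]:
    """Generate the full two-run campaign.

    Run one visits ``spec.temperatures`` in order; run two repeats the
    ladder reversed, so every temperature is measured twice.  Returns the
    series list plus a manifest recording the true generating parameters
    (for parameter-recovery tests only, never consumed by the analysis).
    """
    series = []
    manifest = {
        "true_R_T0": spec.R_T0,
        "true_theta": spec.theta,
        "T0": spec.T0,
        "seed": spec.seed,
        "series": [],
    }
    schedule = [("first", list(spec.temperatures)),
                ("second", list(spec.temperatures)[::-1])]
    index = 0
    for run, temps in schedule:
        for T in temps:
            s = generate_batch_series(spec, T, run=run, seed=_series_seed(spec, index))
            series.append(s)
            manifest["series"].append(
                {"index": index, "temperature": T, "run": run,
                 "n_samples": len(s.time_d)}
            )
            index += 1
    return series, manifest
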