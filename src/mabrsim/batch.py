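"""Batch-test rate analysis.

Implements the rate calculations applied to reactor drawdown experiments:
ordinary least-squares removal rates inside fixed ammonium concentration
windows, conversion from volumetric (g N m-3 d-1) to membrane-area specific
rates (g N m-2 d-1), run averaging, the two-point percent-per-degC
temperature statistic, Arrhenius-type theta fitting across temperatures,
and the nitrite fraction of oxidised nitrogen at the end of a test.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import (
    FitError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFractionError,
)

#: Package default membrane area, m2 (two hollow-fibre bundles of 1.87 m2).
DEFAULT_MEMBRANE_AREA = 3.74
#: Default batch liquid volume, m3 (reactor 28 L + columns 10.3 L); the
#: exact feed-tank volume of any given rig is metadata the caller supplies.
DEFAULT_LIQUID_VOLUME = 0.0383

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class BatchSeries:
    """One batch drawdown experiment.

    ``time_d`` in days (strictly increasing), concentrations in g N/m3,
    temperature in degC, liquid volume ``volume`` in m3 and membrane area
    ``area`` in m2.  ``run`` labels the first or second campaign pass.
    """

    time_d: np.ndarray
    nh4: np.ndarray
    no2: np.ndarray
    no3: np.ndarray
    temperature: float
    volume: float = DEFAULT_LIQUID_VOLUME
    area: float = DEFAULT_MEMBRANE_AREA
    run: str = "first"

    def __post_init__(self):
        for name in ("time_d", "nh4", "no2", "no3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_d)
        if any(len(getattr(self, f)) != n for f in ("nh4", "no2", "no3")):
            raise InvalidParameterError("all series columns must share one length")
        if np.any(np.diff(self.time_d) <= 0):
            raise InvalidParameterError("sample times must be strictly increasing")
        if min(self.nh4.min(initial=0), self.no2.min(initial=0), self.no3.min(initial=0)) < 0:
            raise InvalidParameterError("concentrations must be non-negative")
        if not (self.volume > 0 and self.area > 0):
            raise InvalidParameterError("volume and area must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Windowed linear removal-rate estimate.

    ``volumetric`` is the (positive) NH4 drawdown slope in g N m-3 d-1;
    ``areal = volumetric * V / A`` in g N m-2 d-1.
    """

    window: tuple
    volumetric: float
    areal: float
    n_points: int
    residual_se: float
    temperature: float
    run: str = "first"


@dataclass(frozen=True)
class ArrheniusFit:
    """Fitted Arrhenius-type correlation R(T) = R_T0 * theta**(T - T0)."""

    R_T0: float
    theta: float
    se_R_T0: float
    se_theta: float
    T0: float


def windowed_rate(series: BatchSeries, c_lo: float, c_hi: float) -> RateEstimate:
    """OLS removal rate over the samples with ``c_lo <= NH4 <= c_hi``.

    Window membership is inclusive and judged on the measured NH4 values;
    the time axis is shifted to the first in-window sample.  The fitted
    slope is sign-flipped to a positive removal rate and converted to a
    membrane-area specific rate with the series' volume and area metadata.
    """
    if not c_lo < c_hi:
        raise InvalidParameterError("require c_lo < c_hi")
    mask = (series.nh4 >= c_lo) & (series.nh4 <= c_hi)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"window ({c_lo}, {c_hi}) g N/m3 holds {n} samples; need >= 3"
        )
    t = series.time_d[mask]
    c = series.nh4[mask]
    t = t - t[0]
    slope, intercept = np.polyfit(t, c, 1)
    resid = c - (slope * t + intercept)
    dof = max(n - 2, 1)
    rse = float(np.sqrt(np.sum(resid**2) / dof))
    volumetric = -float(slope)
    return RateEstimate(
        window=(c_lo, c_hi),
        volumetric=volumetric,
        areal=volumetric * series.volume / series.area,
        n_points=n,
        residual_se=rse,
        temperature=series.temperature,
        run=series.run,
    )


def percent_per_degree(R1: float, R0: float, T1: float, T0: float) -> float:
    """Percent change of a rate per degC: ``100 (R1 - R0)/R0 / (T1 - T0)``."""
    if not R0 > 0:
        raise InvalidParameterError("reference rate R0 must be strictly positive")
    if T1 == T0:
        raise UndefinedFractionError("T1 == T0: percent per degC undefined")
    return 100.0 * (R1 - R0) / R0 / (T1 - T0)


def fit_arrhenius(
    rates: Sequence[tuple], T0: float, p0: tuple | None = None
) -> ArrheniusFit:
    """Nonlinear least-squares fit of ``R(T) = R_T0 * theta**(T - T0)``.

    ``rates`` is a sequence of (temperature degC, areal rate) pairs with at
    least three distinct temperatures and strictly positive rates.  The fit
    uses Levenberg-Marquardt; standard errors come from the asymptotic
    covariance of the estimates.
    """
    T = np.array([r[0] for r in rates], dtype=float)
    R = np.array([r[1] for r in rates], dtype=float)
    if np.any(R <= 0):
        raise InvalidParameterError("all rates must be strictly positive")
    if len(np.unique(T)) < 3:
        raise InsufficientDataError("need rates at >= 3 distinct temperatures")

    def model(T, R0, theta):
        return R0 * theta ** (T - T0)

    if p0 is None:
        # log-linear seed: ln R = ln R0 + (T - T0) ln theta
        b, a = np.polyfit(T - T0, np.log(R), 1)
        p0 = (math.exp(a), math.exp(b))
    try:
        popt, pcov = curve_fit(model, T, R, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - LM rarely fails here
        raise FitError(f"Arrhenius fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan] * 2)
    if popt[1] <= 0:
        raise FitError(f"Arrhenius fit returned non-positive theta {popt[1]}")
    return ArrheniusFit(
        R_T0=float(popt[0]),
        theta=float(popt[1]),
        se_R_T0=float(se[0]),
        se_theta=float(se[1]),
        T0=T0,
    )


def average_runs(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    """Mean areal rate per (temperature, window) across duplicate runs.

    Groups the estimates by temperature and concentration window, averages
    the areal rates arithmetically and flags groups backed by a single run.
    """
    records = list(estimates)
    if not records:
        raise InsufficientDataError("no rate estimates to average")
    df = pd.DataFrame(
        {
            "temperature": [e.temperature for e in records],
            "window_lo": [e.window[0] for e in records],
            "window_hi": [e.window[1] for e in records],
            "areal": [e.areal for e in records],
        }
    )
    out = (
        df.groupby(["temperature", "window_lo", "window_hi"], as_index=False)
        .agg(areal_rate=("areal", "mean"), n_runs=("areal", "size"))
        .assign(single_run=lambda d: d.n_runs == 1)
    )
    return out


def nitrite_accumulation(series: BatchSeries) -> float:
    """Nitrite fraction of the oxidised nitrogen at the final sample, in %.

    ``100 * NO2 / (NO2 + NO3)`` at the last sample time; higher values at
    lower temperatures indicate nitrite-oxidiser activity lagging behind
    ammonia oxidation.
    """
    no2, no3 = series.no2[-1], series.no3[-1]
    if no2 + no3 <= 0:
        raise UndefinedFractionError("no oxidised nitrogen at the final sample")
    return 100.0 * no2 / (no2 + no3)


# ---------------------------------------------------------------------------
# campaign-level pipeline and text I/O
# ---------------------------------------------------------------------------


def arrhenius_from_campaign(
    series: Iterable[BatchSeries],
    window: tuple = (10.0, 20.0),
    T0: float = 20.0,
) -> tuple[ArrheniusFit, pd.DataFrame]:
    """Full pipeline: windowed rates per series, run averaging, theta fit.

    Returns the fit together with the per-temperature averaged rate table.
    """
    estimates = [windowed_rate(s, *window) for s in series]
    table = average_runs(estimates)
    fit = fit_arrhenius(
        list(zip(table.temperature, table.areal_rate)), T0=T0
    )
    return fit, table


def write_batch_series(series: BatchSeries, path) -> None:
    """Write a series in the package text format: ``# key: value`` metadata
    header followed by tab-separated columns time_min, nh4_mgL, no2_mgL,
    no3_mgL."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# temperature_C: {series.temperature}\n")
        fh.write(f"# volume_m3: {series.volume}\n")
        fh.write(f"# area_m2: {series.area}\n")
        fh.write(f"# run: {series.run}\n")
        fh.write("time_min\tnh4_mgL\tno2_mgL\tno3_mgL\n")
        for t, a, b, c in zip(series.time_d, series.nh4, series.no2, series.no3):
            fh.write(f"{t * MINUTES_PER_DAY:.6g}\t{a:.6g}\t{b:.6g}\t{c:.6g}\n")


def read_batch_series(path) -> BatchSeries:
    """Read a series written by :func:`write_batch_series`."""
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                rows.append(line)
    df = pd.read_csv(io.StringIO("\n".join(rows)), sep="\t")
    required = {"time_min", "nh4_mgL", "no2_mgL", "no3_mgL"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"batch series file missing columns {sorted(required - set(df.columns))}"
        )
    return BatchSeries(
        time_d=df["time_min"].to_numpy() / MINUTES_PER_DAY,
        nh4=df["nh4_mgL"].to_numpy(),
        no2=df["no2_mgL"].to_numpy(),
        no3=df["no3_mgL"].to_numpy(),
        temperature=float(meta.get("temperature_C", "nan")),
        volume=float(meta.get("volume_m3", DEFAULT_LIQUID_VOLUME)),
        area=float(meta.get("area_m2", DEFAULT_MEMBRANE_AREA)),
        run=meta.get("run", "first"),
    )
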