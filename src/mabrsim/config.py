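"""Configuration schema, file loading and tabular result writing.

One human-readable YAML configuration drives every workflow; the schema is
strict (unknown keys are rejected with their location) and versioned so a
results directory can always be tied back to the exact configuration that
produced it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .batch import DEFAULT_LIQUID_VOLUME, DEFAULT_MEMBRANE_AREA
from .biofilm import DEFAULT_GAS_PO2, BiofilmGeometry, SolverOptions
from .exceptions import ConfigError
from .params import KineticParameterSet, TemperatureRuleSet, _default_D_ref
from .synth import CampaignSpec

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsBlock(_Strict):
    mu_max_AOO: float = 0.493
    mu_max_NOO: float = 0.699
    K_NH4: float = 1.0
    K_NO2: float = 0.5
    K_O2_AOO: float = 0.60
    K_O2_NOO: float = 0.43
    Y_AOO: float = 0.15
    Y_NOO: float = 0.041
    b_AOO: float = 0.05
    b_NOO: float = 0.05
    i_N: float = 0.07
    f_I: float = 0.1
    rho_X: float = 141800.0
    T_ref: float = 20.0


class TemperatureRulesBlock(_Strict):
    theta_mu_AOO: float = 1.095
    theta_mu_NOO: float = 1.06
    theta_b: float = 1.04
    henry_ref: float = 43.0
    henry_vant_hoff_K: float = 1700.0
    D_ref: Dict[str, float] = Field(default_factory=_default_D_ref)
    biofilm_diffusivity_ratio: float = 0.420
    perm_ref: float = 2.5
    perm_activation_energy: float = 8400.0
    T_ref: float = 20.0


class GeometryBlock(_Strict):
    mode: Literal["planar", "cylindrical"] = "cylindrical"
    Lf: float = Field(default=150e-6, gt=0)
    L_LBL: float = Field(default=50e-6, gt=0)
    membrane_outer_radius: float = Field(default=275e-6, gt=0)
    membrane_wall: float = Field(default=135e-6, gt=0)
    gas_pO2: float = Field(default=DEFAULT_GAS_PO2, ge=0)


class SolverBlock(_Strict):
    n_nodes: int = Field(default=100, ge=4)
    newton_tol: float = Field(default=1e-10, gt=0)
    steady_tol: float = Field(default=1e-4, gt=0)
    probe_interval: float = Field(default=5.0, gt=0)
    dt_max: float = Field(default=2.0, gt=0)
    max_time: float = Field(default=6000.0, gt=0)


class MatrixBlock(_Strict):
    temperatures: List[float] = Field(default_factory=lambda: [8.0, 30.0])
    thicknesses: List[float] = Field(default_factory=lambda: [50e-6, 150e-6])
    lbl_thicknesses: List[float] = Field(default_factory=lambda: [50e-6, 250e-6])
    bulk_NH4: float = Field(default=35.0, ge=0)


class BatchBlock(_Strict):
    windows: List[List[float]] = Field(
        default_factory=lambda: [[10.0, 20.0], [2.5, 10.0]]
    )
    T0: float = 20.0


class SynthBlock(_Strict):
    temperatures: List[float] = Field(
        default_factory=lambda: [30.0, 24.0, 18.0, 12.0, 8.0]
    )
    R_T0: float = 3.0
    theta: float = 1.026
    T0: float = 20.0
    initial_NH4: float = 50.0
    sample_interval_min: float = 15.0
    volume: float = DEFAULT_LIQUID_VOLUME
    area: float = DEFAULT_MEMBRANE_AREA
    noise_sd: float = 0.2
    K_app: float = 1.0
    nitrite_frac_30: float = 0.074
    nitrite_frac_8: float = 0.535
    stop_NH4: float = 1.0
    seed: int = 0


class RunConfig(_Strict):
    """Validated top-level configuration with defaults filled in."""

    schema_version: int = SCHEMA_VERSION
    output_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    temperature_rules: TemperatureRulesBlock = Field(
        default_factory=TemperatureRulesBlock
    )
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    matrix: MatrixBlock = Field(default_factory=MatrixBlock)
    batch: BatchBlock = Field(default_factory=BatchBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)

    # -- conversions to the runtime dataclasses ----------------------------

    def kinetic_parameters(self) -> KineticParameterSet:
        return KineticParameterSet(**self.kinetics.model_dump())

    def temperature_rule_set(self) -> TemperatureRuleSet:
        return TemperatureRuleSet(**self.temperature_rules.model_dump())

    def biofilm_geometry(self) -> BiofilmGeometry:
        d = self.geometry.model_dump()
        d.pop("gas_pO2")
        return BiofilmGeometry(**d)

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver.model_dump())

    def campaign_spec(self, seed: int | None = None) -> CampaignSpec:
        d = self.synth.model_dump()
        if seed is not None:
            d["seed"] = seed
        return CampaignSpec(**d)


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration; defaults fill missing keys.

    Raises :class:`ConfigError` with key paths on schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(
            f"invalid configuration {path}:\n{_format_errors(exc)}"
        ) from exc
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.schema_version}; "
            f"this release reads version {SCHEMA_VERSION}"
        )
    # trigger the dataclass invariant checks early for a clear message
    cfg.kinetic_parameters()
    cfg.temperature_rule_set()
    cfg.biofilm_geometry()
    return cfg


def default_config() -> RunConfig:
    """The packaged default configuration (all defaults filled)."""
    return RunConfig()


def write_config(cfg: RunConfig, path) -> None:
    """Serialise a configuration back to YAML (round-trips losslessly)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> List[Path]:
    """Write each table as tab-separated text with a documented header.

    File names are the (sanitised) table names; float columns get a
    display-rounded twin column (2 decimals, suffix ``_2dp``) next to the
    full-precision value.  A ``manifest.txt`` listing every file written is
    produced last.  Returns the list of written paths (manifest included).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name in sorted(tables):
        df = tables[name].copy()
        for col in list(df.columns):
            if pd.api.types.is_float_dtype(df[col]):
                df[f"{col}_2dp"] = np.round(df[col].astype(float), 2)
        path = out_dir / f"{name}.tsv"
        with path.open("w") as fh:
            fh.write(f"# table: {name}\n# delimiter: tab\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
        written.append(path)
    manifest = out_dir / "manifest.txt"
    with manifest.open("w") as fh:
        for p in written:
            fh.write(p.name + "\n")
        fh.write(manifest.name + "\n")
    written.append(manifest)
    return written
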