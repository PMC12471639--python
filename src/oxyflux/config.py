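"""Run configuration: schema, validation, JSON/YAML I/O.

A single flat document with one section per module.  All defaults
reproduce the reference study conditions (venous inlet, pure-O2 gas side,
Table-style blood constants), so an empty file is a valid, runnable
configuration.  Unknown keys are rejected with the offending name; field
provenance (default vs user-supplied) is recorded for reproducibility, and
every artifact written by the CLI embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .channel import ChannelGeometry
from .membrane import MembraneSpec, RheologyParams
from .parameters import BloodParameters, GasTransportConstants
from .solver import BoundaryConditions, SolverSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file rejected; message names the offending key."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BloodSection(_Section):
    Hb: float = Field(0.118, gt=0.0, lt=0.25, description="gHb/mL blood")
    T: float = Field(37.0, ge=20.0, le=45.0, description="deg C")
    pKa: float = Field(6.082, gt=5.5, lt=6.5)
    BE: float = 0.0
    pco2_floor: float = Field(0.5, gt=0.0)
    pco2_ceil: float = 250.0
    po2_floor: float = Field(0.01, gt=0.0)

    def build(self) -> BloodParameters:
        return BloodParameters(Hb=self.Hb, T=self.T, pKa=self.pKa, BE=self.BE,
                               pco2_floor=self.pco2_floor,
                               pco2_ceil=self.pco2_ceil,
                               po2_floor=self.po2_floor)


class GasConstantsSection(_Section):
    D_O2: float = Field(1.9e-9, gt=0)
    D_HbO2: float = Field(1.44e-11, gt=0)
    D_CO2: float = Field(7.39e-10, gt=0)
    D_HbCO2: float = Field(1.44e-11, gt=0)
    D_HCO3: float = Field(4.62e-10, gt=0)
    alpha_O2: float = Field(3.0e-5, gt=0)
    alpha_CO2: float = Field(0.0307, gt=0)
    k_O2: float = Field(1.34, gt=0)
    k_CO2: float = Field(1.384, gt=0)
    P50_CO2: float = Field(265.0, gt=0)
    n_CO2: float = Field(0.9942, gt=0)

    def build(self) -> GasTransportConstants:
        return GasTransportConstants(**self.model_dump())


class MembraneSection(_Section):
    d_outer: float = Field(380.0, gt=0, description="um")
    d_inner: float = Field(200.0, gt=0, description="um")
    Km_O2: float = Field(1.08e-3, gt=0)
    Km_CO2: float = Field(1.40e-3, gt=0)
    tau: float = Field(4.0, ge=1.0)
    eps: float = Field(0.5, gt=0, lt=1)
    d_pore: float = Field(249.0, gt=0, description="nm")
    T0: float = Field(298.0, gt=0)
    P0: float = Field(760.0, gt=0)

    def build(self) -> MembraneSpec:
        return MembraneSpec(**self.model_dump())


class RheologySection(_Section):
    rho: float = Field(1050.0, gt=0)
    mu0: float = Field(0.056, gt=0)
    mu_inf: float = Field(0.00345, gt=0)
    lam: float = Field(3.313, gt=0)
    a: float = Field(2.0, gt=0)
    n: float = Field(0.3568, gt=0)

    def build(self) -> RheologyParams:
        return RheologyParams(**self.model_dump())


class GeometrySection(_Section):
    length: float = Field(0.016, ge=0, description="m")
    half_gap: float = Field(90e-6, gt=0, description="m")
    symmetry: bool = True
    width: float = Field(0.01, gt=0, description="m, depth for flow bookkeeping")

    def build(self) -> ChannelGeometry:
        return ChannelGeometry(length=self.length, half_gap=self.half_gap,
                               symmetry=self.symmetry)


class GridSection(_Section):
    Nx: int = Field(120, ge=1)
    Ny: int = Field(40, ge=1)
    grading: float = Field(1.06, gt=0)


class VelocitySection(_Section):
    profile: str = Field("poiseuille", pattern="^(plug|poiseuille|file)$")
    mean_velocity: float = Field(0.0034, ge=0, description="m/s")
    csv_path: str | None = None

    @model_validator(mode="after")
    def _file_needs_path(self):
        if self.profile == "file" and not self.csv_path:
            raise ValueError("velocity.profile='file' requires velocity.csv_path")
        return self


class BoundarySection(_Section):
    po2_inlet: float = Field(35.9, ge=0)
    pco2_inlet: float = Field(44.0, ge=0)
    wall_mode: str = Field("dirichlet", pattern="^(dirichlet|robin_membrane)$")
    po2_wall: float = Field(707.7, ge=0)
    pco2_wall: float = Field(0.0, ge=0)
    wall_T: float = Field(310.0, gt=0)

    def build(self, membrane: MembraneSpec | None = None) -> BoundaryConditions:
        return BoundaryConditions(
            po2_inlet=self.po2_inlet, pco2_inlet=self.pco2_inlet,
            wall_mode=self.wall_mode, po2_wall=self.po2_wall,
            pco2_wall=self.pco2_wall,
            membrane=membrane if self.wall_mode == "robin_membrane" else None,
            wall_T=self.wall_T)


class SolverSection(_Section):
    tol: float = Field(1e-6, gt=0)
    max_outer: int = Field(200, ge=1)
    relax: float = Field(0.7, gt=0, le=1)
    axial_diffusion: bool = True
    linear_tol: float = Field(1e-12, gt=0)

    def build(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())


class OutputSection(_Section):
    directory: str = "results"
    fields_csv: str = "fields.csv"
    report_json: str = "report.json"
    vtk: bool = False


class RunConfig(_Section):
    """Validated, fully defaulted run configuration."""

    blood: BloodSection = Field(default_factory=BloodSection)
    gas_constants: GasConstantsSection = Field(default_factory=GasConstantsSection)
    membrane: MembraneSection = Field(default_factory=MembraneSection)
    rheology: RheologySection = Field(default_factory=RheologySection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    grid: GridSection = Field(default_factory=GridSection)
    velocity: VelocitySection = Field(default_factory=VelocitySection)
    boundary: BoundarySection = Field(default_factory=BoundarySection)
    solver: SolverSection = Field(default_factory=SolverSection)
    closure: str = Field("coupled",
                         pattern="^(coupled|frozen_o2_curve|constant_co2_slope|linear_tracer)$")
    output: OutputSection = Field(default_factory=OutputSection)

    def provenance(self) -> dict[str, list[str]]:
        """Per-section list of user-supplied (non-default) field names."""
        out: dict[str, list[str]] = {}
        for name in self.model_fields_set:
            section = getattr(self, name)
            if isinstance(section, BaseModel):
                out[name] = sorted(section.model_fields_set)
            else:
                out[name] = []
        return out

    def config_hash(self) -> str:
        """Stable short hash of the fully resolved configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_dict(self) -> dict:
        return self.model_dump()


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a JSON or YAML configuration.

    ``None`` or an empty file yields the all-defaults configuration.
    Raises :class:`ConfigError` naming the offending key on any schema
    violation (including unknown keys).
    """
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    if not text.strip():
        return RunConfig()
    try:
        if p.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON or YAML (by extension); lossless
    round-trip with :func:`load_config`."""
    p = Path(path)
    data = config.model_dump()
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(data, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False))
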