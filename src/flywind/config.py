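"""Run-configuration schema and validation.

One YAML document with per-module blocks; every physical quantity carries
explicit units in its key name.  Unknown keys are hard errors.  The empty
configuration reproduces the nominal forward-flight case (U_inf = 0.94 m/s,
f = 213 Hz, Re = 173, k = 0.65) at desk scale.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = ["ConfigError", "RunConfiguration", "validate_config"]


class ConfigError(ValueError):
    """Schema violation with an itemized message list."""

    def __init__(self, items: list[str]):
        self.items = items
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {i}" for i in items))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FlowBlock(_Block):
    u_inf_m_per_s: float = Field(0.94, gt=0)
    nu_m2_per_s: float = Field(1.56e-5, gt=0)
    rho_kg_per_m3: float = Field(1.225, gt=0)


class KinematicsBlock(_Block):
    amplitude_deg: float = Field(140.0, gt=0, le=180)
    frequency_hz: float = Field(213.0, gt=0)
    deviation_deg: float = 0.0
    alpha_up_deg: float = 60.0
    alpha_down_deg: float = -30.0
    reversal_fraction: float = Field(0.22, gt=0, lt=0.5)
    stroke_plane_deg: float = 20.0
    body_incline_deg: float = 45.0
    hinge_R: tuple[float, float, float] = (0.0, 0.16, 0.12)


class GeometryBlock(_Block):
    wing_area_mm2: float = Field(2.59, gt=0)
    wing_span_mm: float = Field(2.87, gt=0)
    clipped_area_mm2: float = Field(2.09, gt=0)
    body_axes_mm: tuple[float, float, float] = (1.25, 0.45, 0.45)
    resolution: int = Field(16, ge=8)


class GridBlock(_Block):
    delta_R: float = Field(0.03, gt=0)
    stretch_ratio: float = Field(1.15, gt=1, le=1.2)
    domain_R: list[tuple[float, float]] = [(-4.0, 8.0), (-4.5, 4.5)]
    box_R: list[tuple[float, float]] = [(-1.35, 1.35), (-1.6, 1.25)]


class SolverBlock(_Block):
    cfl: float = Field(0.4, gt=0, le=0.5)
    dt_nondim: float | None = Field(None, gt=0)
    poisson_tol: float = Field(1e-8, gt=0)
    poisson_solver: str = "direct"
    diffusion: str = "cn"

    @field_validator("poisson_solver")
    @classmethod
    def _ps(cls, v):
        if v not in ("direct", "cg"):
            raise ValueError("poisson_solver must be 'direct' or 'cg'")
        return v

    @field_validator("diffusion")
    @classmethod
    def _df(cls, v):
        if v not in ("cn", "explicit"):
            raise ValueError("diffusion must be 'cn' or 'explicit'")
        return v


class OdorBlock(_Block):
    c_inlet: float = Field(1.0, ge=0)
    rho_odor_kg_per_m3: float = Field(1.225, gt=0)
    diffusion: bool = False
    diffusivity_cm2_per_s: float = Field(0.1, gt=0)
    tracer_dt_s: float = Field(0.001, gt=0)


class ProbesBlock(_Block):
    offset_R: float = Field(0.03, gt=0)
    capture_radius_R: float = Field(0.05, gt=0)


class ExperimentBlock(_Block):
    k_values: list[float] = [0.33, 0.65, 1.30]
    cycles: int = Field(4, ge=1)
    scale: str = "desk"

    @field_validator("scale")
    @classmethod
    def _sc(cls, v):
        if v not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")
        return v

    @field_validator("k_values")
    @classmethod
    def _kv(cls, v):
        if any(k <= 0 for k in v):
            raise ValueError("k_values must be positive")
        return v


class RunConfiguration(_Block):
    flow: FlowBlock = Field(default_factory=FlowBlock)
    kinematics: KinematicsBlock = Field(default_factory=KinematicsBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    grid: GridBlock = Field(default_factory=GridBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    odor: OdorBlock = Field(default_factory=OdorBlock)
    probes: ProbesBlock = Field(default_factory=ProbesBlock)
    experiment: ExperimentBlock = Field(default_factory=ExperimentBlock)
    output_dir: str = "runs"
    verbosity: int = Field(1, ge=0, le=3)

    @property
    def reynolds(self) -> float:
        return (
            self.flow.u_inf_m_per_s
            * self.geometry.wing_span_mm * 1e-3
            / self.flow.nu_m2_per_s
        )

    @property
    def reduced_frequency(self) -> float:
        return (
            self.kinematics.frequency_hz
            * self.geometry.wing_span_mm * 1e-3
            / self.flow.u_inf_m_per_s
        )


def validate_config(text: str) -> RunConfiguration:
    """Parse + validate YAML text; empty text yields the nominal defaults."""
    try:
        raw = yaml.safe_load(text) if text.strip() else {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"not parseable YAML: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    try:
        return RunConfiguration(**raw)
    except ValidationError as exc:
        items = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            items.append(f"{loc}: {err['msg']}")
        raise ConfigError(items) from exc
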