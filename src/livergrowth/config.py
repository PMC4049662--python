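"""YAML run configuration: schema, validation, loading.

A run configuration bundles a shape section (torus or prism), the growth
constants, and optional partial-growth / fit / synthetic-observation /
output sections.  Unknown keys are rejected and numeric constraints are
enforced at load time with field-path error messages.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Tuple, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import SchemaError
from .geometry import LiverShape, PrismLiverShape, TorusLiverShape
from .growth import GrowthConfig
from .partial import PartialGrowthParams

__all__ = ["RunConfig", "load_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TorusShapeSection(_Section):
    type: Literal["torus"]
    r_b: float = Field(gt=0)
    r_e: float = Field(gt=0)
    d_b: float = Field(gt=0)
    P: float = Field(gt=0, le=1,
                     description="fraction of the full torus ring retained")
    initial_volume_cm3: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _geometry(self) -> "TorusShapeSection":
        if self.r_e < self.r_b:
            raise ValueError("r_e must be >= r_b")
        if self.d_b <= self.r_b:
            raise ValueError("d_b must exceed r_b (self-intersecting torus)")
        return self

    def build(self) -> TorusLiverShape:
        if self.initial_volume_cm3 is not None:
            return TorusLiverShape.with_initial_volume(
                self.r_b, self.r_e, self.d_b, self.P, self.initial_volume_cm3)
        return TorusLiverShape(self.r_b, self.r_e, self.d_b, self.P)


class PrismShapeSection(_Section):
    type: Literal["prism"]
    width: float = Field(gt=0)
    small_base: float = Field(gt=0, description="in units of width")
    large_base: float = Field(gt=0, description="in units of width")
    length: float = Field(gt=0, description="in units of width")
    lobe: Literal["left", "right"] = "left"
    F: float = Field(gt=0, le=1,
                     description="initial graft volume fraction of the liver")
    whole_volume_cm3: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _geometry(self) -> "PrismShapeSection":
        if self.large_base <= self.small_base:
            raise ValueError("large_base must exceed small_base")
        return self

    def build(self) -> PrismLiverShape:
        return PrismLiverShape.from_width_units(
            self.width, self.small_base, self.large_base, self.length,
            lobe=self.lobe, F=self.F, whole_volume_cm3=self.whole_volume_cm3)


class GrowthSection(_Section):
    K: float = Field(default=1.0, gt=0)
    k: float = Field(default=1.0, gt=0)
    rho: float = Field(default=1.0, gt=0)
    n_steps: int = Field(default=1000, ge=10)

    def build(self) -> GrowthConfig:
        return GrowthConfig(K=self.K, k=self.k, rho=self.rho,
                            n_steps=self.n_steps)


class PartialSection(_Section):
    A: float = Field(gt=0, le=1)
    p: float = Field(gt=0)
    V_j: Optional[float] = Field(default=None, gt=0,
                                 description="absolute joining volume (model units)")
    V_j_fraction: Optional[float] = Field(default=None, gt=0, le=1,
                                          description="joining volume as a "
                                          "fraction of the final volume")

    @model_validator(mode="after")
    def _one_of(self) -> "PartialSection":
        if (self.V_j is None) == (self.V_j_fraction is None):
            raise ValueError("exactly one of V_j and V_j_fraction is required")
        return self

    def build(self, shape: LiverShape) -> PartialGrowthParams:
        if self.V_j is not None:
            return PartialGrowthParams(A=self.A, p=self.p, V_j=self.V_j)
        return PartialGrowthParams.from_fraction(self.A, self.p,
                                                 self.V_j_fraction, shape)


class FitSection(_Section):
    A_bounds: Tuple[float, float] = (0.05, 1.0)
    p_bounds: Tuple[float, float] = (0.1, 3.0)
    A_tol: float = Field(default=1e-4, gt=0)
    p_tol: float = Field(default=1e-3, gt=0)
    tol_joining: Optional[float] = Field(default=None, gt=0)
    max_rounds: int = Field(default=50, ge=1)


class SynthSection(_Section):
    observation_times: Optional[List[float]] = None
    every: Optional[float] = Field(default=None, gt=0)
    until: Optional[float] = Field(default=None, gt=0)
    noise_cv: float = Field(default=0.05, ge=0)
    time_scale: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _times(self) -> "SynthSection":
        if self.observation_times is None and (self.every is None
                                               or self.until is None):
            raise ValueError("give observation_times or both every and until")
        return self

    def times(self) -> np.ndarray:
        if self.observation_times is not None:
            return np.asarray(self.observation_times, dtype=float)
        return np.arange(self.every, self.until + 1e-9, self.every)


class OutputSection(_Section):
    curve: Optional[str] = None
    observations: Optional[str] = None
    fit: Optional[str] = None
    joining: Optional[str] = None
    lobes: Optional[str] = None


class RunConfig(_Section):
    """Validated run configuration; see the YAML examples under examples/."""

    shape: Union[TorusShapeSection, PrismShapeSection] = Field(
        discriminator="type")
    growth: GrowthSection = GrowthSection()
    partial: Optional[PartialSection] = None
    fit: FitSection = FitSection()
    synth: Optional[SynthSection] = None
    output: OutputSection = OutputSection()

    def build_shape(self) -> LiverShape:
        return self.shape.build()

    def build_growth(self) -> GrowthConfig:
        return self.growth.build()

    def build_partial(self, shape: LiverShape) -> Optional[PartialGrowthParams]:
        return None if self.partial is None else self.partial.build(shape)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Schema violations raise :class:`SchemaError` naming the offending
    field path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise SchemaError(f"{path}: invalid configuration: "
                          + "; ".join(lines)) from exc
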