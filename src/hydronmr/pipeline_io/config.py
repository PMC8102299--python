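"""Validated configuration for the batch pipeline (YAML-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CourseSpec(_Strict):
    path: str
    humidity: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    direction: Literal["hydration", "dehydration"] = "hydration"
    order: Union[Literal["auto"], Literal[1], Literal[2]] = "auto"


class IsothermSpec(_Strict):
    path: str
    model: Literal["GAB", "BET"] = "GAB"
    method: Literal["direct", "parabolic"] = "direct"
    humidity_unit: Literal["fraction", "percent"] = "fraction"


class FidSpec(_Strict):
    path: str
    liquid_order: Union[Literal["auto"], Literal[1], Literal[2]] = "auto"
    skip_points: int = Field(default=0, ge=0)


class SpectrumSpec(_Strict):
    path: str
    lorentzian_order: Union[Literal["auto"], Literal[1], Literal[2]] = "auto"


class SoluteSpec(_Strict):
    path: str
    gamma_mode: Literal["free", "fixed"] = "free"
    gamma_value: Optional[float] = Field(default=None, gt=0)
    detect_threshold: bool = True


class AnalysisConfig(_Strict):
    """Input paths and model options for one end-to-end analysis run."""

    courses: List[CourseSpec] = Field(default_factory=list)
    isotherm: Optional[IsothermSpec] = None
    fid: Optional[FidSpec] = None
    spectrum: Optional[SpectrumSpec] = None
    solute: Optional[SoluteSpec] = None
    isotherm_model: Literal["GAB", "BET"] = "GAB"
    isotherm_method: Literal["direct", "parabolic"] = "direct"
    seed: int = 0
    output_dir: Optional[str] = None

    def datasets(self) -> list:
        out = [c.path for c in self.courses]
        for spec in (self.isotherm, self.fid, self.spectrum, self.solute):
            if spec is not None:
                out.append(spec.path)
        return out

    def validate_paths(self, base: Optional[Path] = None) -> None:
        if not self.datasets():
            raise ConfigError("configuration references no datasets")
        for p in self.datasets():
            full = (base / p) if base is not None else Path(p)
            if not full.exists():
                raise ConfigError(f"input path does not exist: {full}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(exclude_none=True), sort_keys=False)
        )
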