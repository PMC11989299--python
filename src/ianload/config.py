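"""Run configuration: YAML in, validated domain objects out.

Schema validation uses pydantic with ``extra='forbid'`` so a misspelled
key fails loudly with its field path.  Omitted fields fall back to the
reference defaults (geometry, Table-style materials, 200 N load).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .fem import LoadCase, Material, default_materials
from .geometry import ModelParams, Region
from .sweep import SweepConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Unreadable or invalid configuration file."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    block_diameter: float = 8.0
    block_length: float = 8.0
    cortical_thickness: float = 1.0
    lateral_cortical: bool = False
    implant_length: float = 4.0
    implant_diameter: float = 4.0
    crown_height: float = 6.0
    composite_height: float = 1.0
    bolus_height: float = 2.0
    canal_diameter: float = 2.5
    nerve_diameter: float = 2.0
    apex_to_canal_distance: float = Field(1.5, gt=0)
    thread_depth: float = Field(0.0, ge=0)
    thread_pitch: float = Field(0.8, gt=0)
    global_element_size: float = Field(0.5, gt=0)
    refined_element_size: float = Field(0.1, gt=0)
    refine_margin: float = Field(0.5, gt=0)
    axial_window: Optional[float] = Field(None, gt=0)
    symmetry: str = "none"

    def to_params(self) -> ModelParams:
        return ModelParams(**self.model_dump())


class MaterialSection(_Strict):
    E_MPa: float = Field(gt=0)
    nu: float = Field(ge=0, lt=0.5)


class LoadSection(_Strict):
    total_load_N: float = Field(200.0, ge=0)
    fixed_tags: dict[str, str] = Field(default_factory=lambda: {
        "BLOCK_BOTTOM": "xyz", "BLOCK_LATERAL": "xyz", "NERVE_ENDS": "xyz"})

    def to_load(self) -> LoadCase:
        return LoadCase(total_load=self.total_load_N, fixed=dict(self.fixed_tags))


class AdaptiveSection(_Strict):
    rel_tol: float = Field(0.10, gt=0)
    max_meshes: int = Field(4, ge=1)
    refine_factor: float = Field(0.7, gt=0, lt=1)
    refine_floor: Optional[float] = Field(None, gt=0)
    axial_window: Optional[float] = Field(None, gt=0)


class SweepSection(_Strict):
    distances_mm: list[float] = [1.5, 0.5, 0.1]
    hu_grades: Optional[list[float]] = None       # HU list -> E via calibration
    e_grades_mpa: Optional[list[float]] = None    # explicit moduli
    threshold_mpa: float = Field(0.026, gt=0)
    sweep_cortical: bool = False


class RunConfigModel(_Strict):
    model: ModelSection = Field(default_factory=ModelSection)
    materials: dict[str, MaterialSection] = Field(default_factory=dict)
    load: LoadSection = Field(default_factory=LoadSection)
    adaptive: AdaptiveSection = Field(default_factory=AdaptiveSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    seed: int = 0
    verbose: bool = False


class RunConfig:
    """Validated configuration resolved into domain objects."""

    def __init__(self, raw: RunConfigModel):
        from . import calibration

        self.raw = raw
        self.params = raw.model.to_params()
        self.load = raw.load.to_load()
        self.seed = raw.seed
        self.verbose = raw.verbose

        mats = default_materials()
        for name, sec in raw.materials.items():
            try:
                region = Region[name.upper()]
            except KeyError as exc:
                raise ConfigError(
                    f"materials.{name}: unknown region "
                    f"(expected one of {[r.name for r in Region]})") from exc
            mats[region] = Material(sec.E_MPa, sec.nu)
        self.materials = mats

        if raw.sweep.hu_grades is not None and raw.sweep.e_grades_mpa is not None:
            raise ConfigError("sweep: give hu_grades or e_grades_mpa, not both")
        if raw.sweep.hu_grades is not None:
            pts = calibration.build_calibration_table(raw.sweep.hu_grades)
            grades = tuple((p.hu, p.e_modulus) for p in pts)
        elif raw.sweep.e_grades_mpa is not None:
            grades = tuple((float("nan"), float(e)) for e in raw.sweep.e_grades_mpa)
        else:
            pts = calibration.build_calibration_table(calibration.DEFAULT_HU_GRADES)
            grades = tuple((p.hu, p.e_modulus) for p in pts)

        self.sweep = SweepConfig(
            distances_mm=tuple(raw.sweep.distances_mm),
            grades=grades,
            threshold_mpa=raw.sweep.threshold_mpa,
            load_n=self.load.total_load,
            model=self.params,
            sweep_cortical=raw.sweep.sweep_cortical,
            rel_tol=raw.adaptive.rel_tol,
            max_meshes=raw.adaptive.max_meshes,
            refine_factor=raw.adaptive.refine_factor,
            refine_floor=raw.adaptive.refine_floor,
            axial_window=raw.adaptive.axial_window,
        )

    def dump(self) -> dict:
        return self.raw.model_dump()


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; defaults fill omitted fields."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    try:
        raw = RunConfigModel.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + f": {e['msg']}"
            for e in exc.errors())
        raise ConfigError(f"{path}: {locs}") from exc
    try:
        return RunConfig(raw)
    except (ValueError, ConfigError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
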