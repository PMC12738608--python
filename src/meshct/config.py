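"""Run configuration schema and validation.

A run config (YAML or JSON) drives the full pipeline: scene assembly,
grid geometry, artefact parameters, patient demographics and output.
Unknown keys are rejected so typos fail loudly; validation errors carry
the dotted path of the offending key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MeshEntry(_Strict):
    path: str
    density_hu: float
    priority: int
    name: str | None = None


class SceneConfig(_Strict):
    meshes: list[MeshEntry] = Field(min_length=1)


class GridConfig(_Strict):
    spacing_mm: float | tuple[float, float, float] = 2.5
    padding_mm: float = Field(default=0.0, ge=0)
    background_hu: float = -1000.0
    supersample_k: int = Field(default=3, ge=1)
    chunk_slices: int = Field(default=8, ge=1)

    def spacing_tuple(self):
        s = self.spacing_mm
        out = (s, s, s) if isinstance(s, (int, float)) else tuple(s)
        if any(v <= 0 for v in out):
            raise ConfigError("grid.spacing_mm: spacing must be positive")
        return out


class ArtefactConfig(_Strict):
    noise_std_dev: float = Field(default=0.0, ge=0)
    metal_threshold: float = 3000.0
    num_angles: int = Field(default=36, ge=1)
    streak_intensity: float = Field(default=0.0, ge=0)
    streak_attenuation: float = Field(default=0.05, ge=0)
    streak_max_radius: float = Field(default=100.0, gt=0)
    pve_sigma: float = Field(default=0.0, ge=0)
    ring_frequency: float = Field(default=8.0, gt=0)
    ring_intensity: float = Field(default=0.0, ge=0)


class PatientConfig(_Strict):
    name: str = "SYNTHETIC^PHANTOM"
    id: str = "SYN000"
    sex: str = "O"
    birthdate: str = "19700101"


class PhasesConfig(_Strict):
    count: int = Field(ge=1)
    si_amplitude: float = Field(default=0.10, ge=0, le=0.5)
    ap_amplitude: float = Field(default=0.03, ge=0, le=0.5)
    structures: list[str] | None = None


class RunConfig(_Strict):
    scene: SceneConfig
    grid: GridConfig = GridConfig()
    artefacts: ArtefactConfig = ArtefactConfig()
    patient: PatientConfig = PatientConfig()
    output_dir: str
    seed: int = 0
    phases: PhasesConfig | None = None
    uid_root: str | None = None
    study_date: str | None = None
    study_time: str | None = None


def _format_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_error(exc)) from exc


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON form (reproducibility manifest key)."""
    canonical = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def validate_config(path, check_files: bool = True) -> list:
    """Schema + referential checks without running; returns issue strings."""
    issues = []
    try:
        cfg = load_config(path)
    except ConfigError as exc:
        return [str(exc)]
    if check_files:
        base = Path(path).parent
        for i, entry in enumerate(cfg.scene.meshes):
            mesh_path = Path(entry.path)
            if not mesh_path.is_absolute():
                mesh_path = base / mesh_path
            if not mesh_path.exists():
                issues.append(f"scene.meshes.{i}.path: file not found: {entry.path}")
    try:
        cfg.grid.spacing_tuple()
    except ConfigError as exc:
        issues.append(str(exc))
    if cfg.phases is not None and cfg.phases.count > 1:
        if cfg.phases.si_amplitude == 0 and cfg.phases.ap_amplitude == 0:
            issues.append(
                "phases: count > 1 but both motion amplitudes are zero; "
                "all phases would be identical"
            )
    return issues
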