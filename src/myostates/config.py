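"""Run configuration (schema-validated YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .types import BeamGeometry, ConditionEffects, DecayTruth, StudyDesign

__all__ = ["RunConfig", "load_config", "config_hash", "write_manifest", "file_sha256"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    conditions: list[str] = ["SA", "IBA", "torpor"]
    animals_per_condition: int = 5
    fibers_per_animal: tuple[int, int] = (8, 12)
    fiber_type_proportion: float = 0.5
    temperatures_C: list[float] = [20.0]
    frame_interval_s: float = 5.0
    duration_s: float = 300.0

    def build(self, seed: int) -> StudyDesign:
        return StudyDesign(
            conditions=tuple(self.conditions),
            animals_per_condition=self.animals_per_condition,
            fibers_per_animal=tuple(self.fibers_per_animal),
            fiber_type_proportion=self.fiber_type_proportion,
            temperatures_C=tuple(self.temperatures_C),
            frame_interval_s=self.frame_interval_s,
            duration_s=self.duration_s,
            seed=seed,
        ).validate()


class BaselineTruthConfig(_Strict):
    p1_frac: float = 0.25
    t1_s: float = 15.0
    p2_frac: float = 0.50
    t2_s: float = 200.0


class EffectsConfig(_Strict):
    baseline: BaselineTruthConfig = Field(default_factory=BaselineTruthConfig)
    # keys "condition:fiber_type", e.g. "torpor:II": 0.65
    t1_multipliers: dict[str, float] = {}
    t2_multipliers: dict[str, float] = {}
    p1_shifts: dict[str, float] = {}
    # keys are temperatures as strings, values (m_t1, m_t2)
    temperature_multipliers: dict[str, tuple[float, float]] = {}
    animal_cv: float = 0.08
    fiber_cv: float = 0.12
    animal_amp_sd: float = 0.02
    fiber_amp_sd: float = 0.03
    noise_sd: float = 0.01
    baseline_intensity: tuple[float, float] = (400.0, 600.0)
    background_level: tuple[float, float] = (40.0, 60.0)
    background_drift_per_s: float = 0.0

    @staticmethod
    def _split(d: dict) -> dict:
        out = {}
        for key, v in d.items():
            cond, _, ftype = key.partition(":")
            out[(cond, ftype)] = v
        return out

    def build(self) -> ConditionEffects:
        b = self.baseline
        return ConditionEffects(
            baseline=DecayTruth(b.p1_frac, b.t1_s, b.p2_frac, b.t2_s),
            t1_multipliers=self._split(self.t1_multipliers),
            t2_multipliers=self._split(self.t2_multipliers),
            p1_shifts=self._split(self.p1_shifts),
            temperature_multipliers={
                float(t): tuple(v) for t, v in self.temperature_multipliers.items()
            },
            animal_cv=self.animal_cv,
            fiber_cv=self.fiber_cv,
            animal_amp_sd=self.animal_amp_sd,
            fiber_amp_sd=self.fiber_amp_sd,
            noise_sd=self.noise_sd,
            baseline_intensity=tuple(self.baseline_intensity),
            background_level=tuple(self.background_level),
            background_drift_per_s=self.background_drift_per_s,
        ).validate()


class FitConfig(_Strict):
    unconstrained: bool = False
    rel_tol: float = 1e-10
    max_nfev: int = 10_000


class QCConfig(_Strict):
    require_converged: bool = True
    max_rel_se_t1: float = 1.0
    max_rel_se_t2: float = 1.0
    reject_amplitude_sum_gt_100: bool = False
    reject_lifetimes_close: bool = False


class GeometryConfig(_Strict):
    wavelength_nm: float = 0.10
    camera_length_m: float = 2.14
    pixel_size_mm: float | None = None

    def build(self) -> BeamGeometry:
        return BeamGeometry(
            wavelength_nm=self.wavelength_nm,
            camera_length_m=self.camera_length_m,
            pixel_size_mm=self.pixel_size_mm,
        ).validate()


class OmicsConfig(_Strict):
    min_valid_per_group: int = 2
    already_log2: bool = True
    equal_var: bool = False
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05


class EnergeticsConfig(_Strict):
    head_concentration_uM: float = 220.0
    baseline_condition: str = "SA"
    warm_C: float = 20.0
    cold_C: float = 8.0


class RunConfig(_Strict):
    """Top-level run configuration; unknown keys are rejected."""

    seed: int = 0
    design: DesignConfig = Field(default_factory=DesignConfig)
    effects: EffectsConfig = Field(default_factory=EffectsConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    omics: OmicsConfig = Field(default_factory=OmicsConfig)
    energetics: EnergeticsConfig = Field(default_factory=EnergeticsConfig)


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, config: RunConfig, inputs=(), outputs=()):
    """Write a per-stage manifest of config hash, seed and file hashes.

    Timestamps are recorded but live in a separate key so deterministic
    comparisons can ignore them.
    """
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("myostates")
    except PackageNotFoundError:
        pkg_version = "unknown"

    manifest = {
        "stage": stage,
        "package_version": pkg_version,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": {str(p): file_sha256(p) for p in outputs},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
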