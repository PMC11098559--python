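"""Shared domain types for the single-fiber myosin state pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "DecayTruth",
    "StudyDesign",
    "ConditionEffects",
    "FluorescenceTrace",
    "NormalizedDecay",
    "DecayFit",
    "BeamGeometry",
    "DiffractionProfile",
    "ReflectionMeasurement",
]


@dataclass(frozen=True)
class DecayTruth:
    """Ground-truth parameters of one fiber's double-exponential decay.

    ``p1_frac``/``t1_s`` are the DRX amplitude fraction and lifetime,
    ``p2_frac``/``t2_s`` the SRX pair; the remainder ``1 - p1 - p2`` is a
    non-exchanging plateau and must be non-negative.
    """

    p1_frac: float
    t1_s: float
    p2_frac: float
    t2_s: float

    @property
    def plateau_frac(self) -> float:
        return 1.0 - self.p1_frac - self.p2_frac

    def validate(self) -> "DecayTruth":
        if not 0.0 <= self.p1_frac <= 1.0:
            raise ValueError(f"p1_frac={self.p1_frac} outside [0, 1]")
        if not 0.0 <= self.p2_frac <= 1.0:
            raise ValueError(f"p2_frac={self.p2_frac} outside [0, 1]")
        if self.p1_frac + self.p2_frac > 1.0 + 1e-12:
            raise ValueError(
                f"p1_frac + p2_frac = {self.p1_frac + self.p2_frac:g} exceeds 1"
            )
        if not self.t1_s > 0:
            raise ValueError(f"t1_s={self.t1_s} must be positive")
        if not self.t2_s > 0:
            raise ValueError(f"t2_s={self.t2_s} must be positive")
        if not self.t1_s < self.t2_s:
            raise ValueError(
                f"t1_s={self.t1_s} must be smaller than t2_s={self.t2_s} "
                "(DRX is the fast component)"
            )
        return self


@dataclass
class StudyDesign:
    """Layout of a simulated hibernation study.

    Defaults mirror the study design the analysis assumes: conditions
    compared with 5 animals per condition, 8-12 fibers per animal, a mix of
    type I/II fibers, and frames every 5 s for 300 s.
    """

    conditions: tuple = ("SA", "IBA", "torpor")
    animals_per_condition: int = 5
    fibers_per_animal: tuple = (8, 12)
    fiber_type_proportion: float = 0.5  # fraction of type II fibers
    temperatures_C: tuple = (20.0,)
    frame_interval_s: float = 5.0
    duration_s: float = 300.0
    seed: int = 0

    def validate(self) -> "StudyDesign":
        if len(self.conditions) < 1:
            raise ValueError("at least one condition is required")
        if self.animals_per_condition < 1:
            raise ValueError("animals_per_condition must be >= 1")
        low, high = self.fibers_per_animal
        if low < 1 or low > high:
            raise ValueError(f"invalid fibers_per_animal range ({low}, {high})")
        if not 0.0 <= self.fiber_type_proportion <= 1.0:
            raise ValueError("fiber_type_proportion must be in [0, 1]")
        if self.frame_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("frame_interval_s and duration_s must be positive")
        n = self.duration_s / self.frame_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "duration_s must be an integer multiple of frame_interval_s"
            )
        return self

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s / self.frame_interval_s))
        return np.arange(n + 1) * self.frame_interval_s


@dataclass
class ConditionEffects:
    """Condition/fiber-type effects and variance components for a simulation.

    ``t1_multipliers`` etc. map ``(condition, fiber_type)`` to a multiplier
    on the baseline lifetime (missing keys default to 1); ``p1_shifts`` are
    additive shifts on the DRX amplitude fraction.
    ``temperature_multipliers`` maps a temperature (deg C) to ``(m_t1, m_t2)``
    lifetime multipliers applied on top of condition effects.  Between-animal
    and within-animal variation act multiplicatively (log-normal) on the
    lifetimes with the given coefficients of variation, and additively
    (normal) on the amplitude fractions.  ``noise_sd`` is the additive
    Gaussian noise on the normalized fluorescence.
    """

    baseline: DecayTruth = field(
        default_factory=lambda: DecayTruth(0.25, 15.0, 0.50, 200.0)
    )
    t1_multipliers: dict = field(default_factory=dict)
    t2_multipliers: dict = field(default_factory=dict)
    p1_shifts: dict = field(default_factory=dict)
    temperature_multipliers: dict = field(default_factory=dict)
    animal_cv: float = 0.08
    fiber_cv: float = 0.12
    animal_amp_sd: float = 0.02
    fiber_amp_sd: float = 0.03
    noise_sd: float = 0.01
    baseline_intensity: tuple = (400.0, 600.0)  # a.u., uniform draw per fiber
    background_level: tuple = (40.0, 60.0)  # a.u., uniform draw per fiber
    background_drift_per_s: float = 0.0  # optional linear background drift

    def validate(self) -> "ConditionEffects":
        self.baseline.validate()
        for name, d in (
            ("t1_multipliers", self.t1_multipliers),
            ("t2_multipliers", self.t2_multipliers),
        ):
            for key, m in d.items():
                if not m > 0:
                    raise ValueError(f"{name}[{key}]={m} must be positive")
        for temp, (m1, m2) in self.temperature_multipliers.items():
            if not (m1 > 0 and m2 > 0):
                raise ValueError(f"temperature_multipliers[{temp}] must be positive")
        for name, v in (
            ("animal_cv", self.animal_cv),
            ("fiber_cv", self.fiber_cv),
            ("animal_amp_sd", self.animal_amp_sd),
            ("fiber_amp_sd", self.fiber_amp_sd),
            ("noise_sd", self.noise_sd),
        ):
            if v < 0:
                raise ValueError(f"{name}={v} must be >= 0")
        return self


@dataclass
class FluorescenceTrace:
    """One fiber's raw frame-by-frame fluorescence with its background trace."""

    fiber_id: str
    time_s: np.ndarray
    raw_fluor: np.ndarray
    background_fluor: np.ndarray
    animal_id: str = ""
    condition: str = ""
    fiber_type: str = ""  # "I" or "II"
    temperature_C: float = 20.0

    def validate(self) -> "FluorescenceTrace":
        t = np.asarray(self.time_s, float)
        if t.size == 0:
            raise ValueError("empty time vector")
        if t[0] != 0:
            raise ValueError(f"time_s must start at 0 (washout); got {t[0]}")
        if not (np.diff(t) > 0).all():
            raise ValueError("time_s must be strictly increasing")
        if not (len(self.raw_fluor) == t.size == len(self.background_fluor)):
            raise ValueError("time and intensity vectors must have equal length")
        return self


@dataclass
class NormalizedDecay:
    """Background-corrected decay, dimensionless, exactly 1 at t = 0."""

    time_s: np.ndarray
    norm_fluor: np.ndarray


@dataclass(frozen=True)
class DecayFit:
    """Fitted DRX/SRX parameters for one fiber.

    Amplitudes are in percent; lifetimes in seconds.  The faster lifetime is
    always labelled (P1, T1) = DRX.  When ``converged`` is false the
    parameters are NaN and must not be used.
    """

    p1_pct: float
    t1_s: float
    p2_pct: float
    t2_s: float
    p1_pct_se: float
    t1_s_se: float
    p2_pct_se: float
    t2_s_se: float
    rss: float
    n_points: int
    converged: bool
    qc_flags: frozenset = frozenset()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["qc_flags"] = "|".join(sorted(self.qc_flags))
        return d


@dataclass(frozen=True)
class BeamGeometry:
    """Small-angle scattering geometry: wavelength, camera length, pixel size."""

    wavelength_nm: float = 0.10
    camera_length_m: float = 2.14
    pixel_size_mm: float | None = None

    def validate(self) -> "BeamGeometry":
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")
        if not self.camera_length_m > 0:
            raise ValueError("camera_length_m must be positive")
        if self.pixel_size_mm is not None and not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        return self


@dataclass
class DiffractionProfile:
    """1-D diffraction intensity profile along one axis of the pattern."""

    radius_mm: np.ndarray
    intensity: np.ndarray
    axis: str = "meridional"  # or "equatorial"
    condition: str = ""
    bundle_id: str = ""

    def validate(self) -> "DiffractionProfile":
        r = np.asarray(self.radius_mm, float)
        if not (np.diff(r) > 0).all():
            raise ValueError("radial coordinate must be strictly increasing")
        if not np.isfinite(np.asarray(self.intensity, float)).all():
            raise ValueError("intensities must be finite")
        return self


@dataclass(frozen=True)
class ReflectionMeasurement:
    """Fitted reflection: center, integrated intensity, lattice spacing."""

    name: str  # "1,0" | "1,1" | "M3" | "M6" | user-defined
    center_mm: float
    width_mm: float
    intensity: float  # integrated peak area, a.u.
    height: float
    spacing_nm: float
    rss: float
    baseline: tuple = ()
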