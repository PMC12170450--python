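"""Synthetic cohort generator.

Produces binary lesion masks on a 2 mm grid, a behavioral table mixing two
assessment instruments, and the ground truth needed for parameter-recovery
testing. The behavioral model plants a deficit in the self-generated-speech
metric driven by fractional coverage of a critical region:

    self  = 10 - effect_beta * coverage - overall_beta * (volume / ref) + noise
    overall = 10 - overall_beta * (volume / ref) + noise

both clamped to [0, 10]. Raw instrument subscores are back-generated so that
harmonization reproduces the latent metrics exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mask import LesionMask

__all__ = [
    "Ellipsoid",
    "SimConfig",
    "GroundTruth",
    "generate_lesion",
    "generate_cohort",
    "generate_paired_assessments",
    "simulation_affine",
]

log = logging.getLogger(__name__)

ETIOLOGIES = (
    "low_grade_glioma",
    "high_grade_glioma",
    "epilepsy",
    "vascular_malformation",
    "metastasis",
    "necrosis",
)
# cohort proportions: 103/145/34/14/9/2 of 307
ETIOLOGY_P = np.array([103, 145, 34, 14, 9, 2], dtype=float) / 307.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world mm: center and per-axis radii."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or len(self.radii_mm) != 3:
            raise ValueError("center_mm and radii_mm must be length-3")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"radii must be positive, got {self.radii_mm}")

    def to_dict(self) -> dict:
        return {"center_mm": list(self.center_mm), "radii_mm": list(self.radii_mm)}

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(tuple(d["center_mm"]), tuple(d["radii_mm"]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated cohort.

    ``effect_beta`` is the score-point drop per unit coverage of the critical
    region; ``overall_beta`` scales a global-severity effect of lesion volume
    relative to ``reference_volume_cm3``.
    """

    grid_shape: tuple[int, int, int] = (32, 36, 32)
    voxel_size_mm: float = 2.0
    n_subjects: int = 60
    critical_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((32.0, 36.0, 32.0), (10.0, 8.0, 8.0))
    )
    effect_beta: float = 4.0
    overall_beta: float = 1.0
    aos_region: Ellipsoid | None = field(
        default_factory=lambda: Ellipsoid((14.0, 56.0, 32.0), (7.0, 7.0, 7.0))
    )
    noise_sd: float = 1.0
    qab_fraction: float = 0.5
    seed: int = 0
    # --- sampling knobs (not part of the behavioral model) ---
    reference_volume_cm3: float = 20.0
    focal_fraction: float = 0.5  # P(lesion centered near the critical region)
    jitter_mm: float = 4.0
    radii_range_mm: tuple[float, float] = (6.0, 14.0)  # non-focal lesions
    focal_radii_scale: tuple[float, float] = (0.7, 1.3)  # x critical radii
    days_beta: float = 0.0  # optional recovery nuisance: score drop per day early

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 dims all >= 8, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.effect_beta < 0 or self.overall_beta < 0:
            raise ValueError("effect betas must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.qab_fraction <= 1.0:
            raise ValueError("qab_fraction must be in [0, 1]")

    @property
    def affine(self) -> np.ndarray:
        return simulation_affine(self.voxel_size_mm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["radii_range_mm"] = list(self.radii_range_mm)
        d["focal_radii_scale"] = list(self.focal_radii_scale)
        d["critical_region"] = self.critical_region.to_dict()
        d["aos_region"] = None if self.aos_region is None else self.aos_region.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["radii_range_mm"] = tuple(d.get("radii_range_mm", (6.0, 14.0)))
        d["focal_radii_scale"] = tuple(d.get("focal_radii_scale", (0.7, 1.3)))
        d["critical_region"] = Ellipsoid.from_dict(d["critical_region"])
        if d.get("aos_region") is not None:
            d["aos_region"] = Ellipsoid.from_dict(d["aos_region"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the analysis tries to recover."""

    critical_mask: LesionMask
    aos_mask: LesionMask | None
    coverage_fraction: np.ndarray  # per subject, |lesion ∩ critical| / |critical|
    latent: pd.DataFrame  # noiseless self/overall/repetition/naming


def simulation_affine(voxel_size_mm: float) -> np.ndarray:
    """Diagonal RAS affine; voxel center i maps to i * voxel_size mm."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def _voxel_center_grids(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vs = config.voxel_size_mm
    return tuple(np.arange(n) * vs for n in config.grid_shape)  # type: ignore[return-value]


def ellipsoid_mask(ellipsoid: Ellipsoid, config: SimConfig) -> np.ndarray:
    """Boolean volume: voxel centers strictly inside the ellipsoid."""
    xs, ys, zs = _voxel_center_grids(config)
    cx, cy, cz = ellipsoid.center_mm
    rx, ry, rz = ellipsoid.radii_mm
    q = (
        ((xs - cx) / rx)[:, None, None] ** 2
        + ((ys - cy) / ry)[None, :, None] ** 2
        + ((zs - cz) / rz)[None, None, :] ** 2
    )
    return q < 1.0


def generate_lesion(
    center_mm: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
    config: SimConfig,
) -> LesionMask:
    """Rasterize an axis-aligned ellipsoid onto the simulation grid.

    A voxel is lesioned iff its center lies strictly inside the ellipsoid.
    Raises ``ValueError`` if no voxel center falls inside.
    """
    data = ellipsoid_mask(Ellipsoid(tuple(center_mm), tuple(radii_mm)), config)
    if not data.any():
        raise ValueError(
            f"ellipsoid centered at {tuple(center_mm)} mm contains no voxel center"
        )
    return LesionMask(data, config.affine)


def _sample_lesion(rng: np.random.Generator, config: SimConfig) -> LesionMask:
    """One random ellipsoidal lesion; focal lesions cluster near the critical region."""
    vs = config.voxel_size_mm
    hi = tuple((n - 1) * vs for n in config.grid_shape)
    lo_r, hi_r = config.radii_range_mm
    for _ in range(100):
        focal = rng.random() < config.focal_fraction
        if focal:
            center = np.asarray(config.critical_region.center_mm) + rng.normal(
                0.0, config.jitter_mm, size=3
            )
            lo_s, hi_s = config.focal_radii_scale
            radii = np.asarray(config.critical_region.radii_mm) * rng.uniform(
                lo_s, hi_s, size=3
            )
        else:
            center = rng.uniform(0.0, hi, size=3)
            radii = rng.uniform(lo_r, hi_r, size=3)
        center = np.clip(center, 0.0, hi)
        data = ellipsoid_mask(Ellipsoid(tuple(center), tuple(radii)), config)
        if data.any():
            return LesionMask(data, config.affine)
    raise RuntimeError("failed to sample a nonempty lesion in 100 attempts")


def coverage_fraction(lesion: LesionMask, region: LesionMask) -> float:
    """|lesion ∩ region| / |region|."""
    denom = region.n_voxels
    if denom == 0:
        raise ValueError("region mask is empty")
    return float(np.logical_and(lesion.data, region.data).sum()) / denom


def _clamp01_10(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 10.0)


def generate_cohort(
    config: SimConfig,
) -> tuple[list[LesionMask], pd.DataFrame, GroundTruth]:
    """Simulate lesions, behavior, and ground truth for one cohort.

    Returns masks (one per subject), a raw behavior table in the documented
    CSV schema, and a :class:`GroundTruth` carrying the planted critical
    region, exact coverage fractions, and noiseless latent scores.
    """
    if config.n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {config.n_subjects}")
    rng = np.random.default_rng(config.seed)

    critical = LesionMask(ellipsoid_mask(config.critical_region, config), config.affine)
    if critical.n_voxels == 0:
        raise ValueError("critical region contains no voxel center on this grid")
    aos_mask = None
    if config.aos_region is not None:
        aos_mask = LesionMask(ellipsoid_mask(config.aos_region, config), config.affine)

    masks = [_sample_lesion(rng, config) for _ in range(config.n_subjects)]
    cov = np.array([coverage_fraction(m, critical) for m in masks])
    vol_cm3 = np.array([m.volume_cm3 for m in masks])
    vol_term = config.overall_beta * (vol_cm3 / config.reference_volume_cm3)

    days = rng.integers(1, 6, size=config.n_subjects)
    days_term = config.days_beta * (5 - days)  # earlier evaluation, lower score
    age = np.clip(rng.normal(46.2, 16.2, size=config.n_subjects), 18, 87)
    etiology = rng.choice(ETIOLOGIES, size=config.n_subjects, p=ETIOLOGY_P)
    is_qab = rng.random(config.n_subjects) < config.qab_fraction
    if aos_mask is not None:
        aos = np.array(
            [bool(np.logical_and(m.data, aos_mask.data).any()) for m in masks]
        )
    else:
        aos = np.zeros(config.n_subjects, dtype=bool)

    latent_self = 10.0 - config.effect_beta * cov - vol_term - days_term
    latent_overall = 10.0 - vol_term - days_term
    latent_rep = 10.0 - 0.5 * vol_term
    latent_naming = 10.0 - 0.5 * vol_term

    noise = rng.normal(0.0, config.noise_sd, size=(config.n_subjects, 4))
    self_s = _clamp01_10(latent_self + noise[:, 0])
    overall = _clamp01_10(latent_overall + noise[:, 1])
    rep = _clamp01_10(latent_rep + noise[:, 2])
    naming = _clamp01_10(latent_naming + noise[:, 3])

    rows = []
    for i in range(config.n_subjects):
        row: dict = {
            "subject_id": f"S{i + 1:04d}",
            "instrument": "QAB" if is_qab[i] else "WAB",
            "wab_fluency": np.nan,
            "wab_aq": np.nan,
            "wab_repetition": np.nan,
            "wab_naming": np.nan,
            "qab_length_complexity": np.nan,
            "qab_speech_rate": np.nan,
            "qab_comm_impairment": np.nan,
            "qab_overall": np.nan,
            "qab_repetition": np.nan,
            "qab_naming": np.nan,
            "aos": int(aos[i]),
            "days_post_surgery": int(days[i]),
            "etiology": etiology[i],
            "age": float(age[i]),
            "lesion_cm3": float(vol_cm3[i]),
        }
        if is_qab[i]:
            # mean(three ratings) * 2.5 == self_s exactly
            row["qab_length_complexity"] = self_s[i] * 0.4
            row["qab_speech_rate"] = self_s[i] * 0.4
            row["qab_comm_impairment"] = self_s[i] * 0.4
            row["qab_overall"] = overall[i]
            row["qab_repetition"] = rep[i]
            row["qab_naming"] = naming[i]
        else:
            row["wab_fluency"] = self_s[i]
            row["wab_aq"] = overall[i] * 10.0
            row["wab_repetition"] = rep[i]
            row["wab_naming"] = naming[i]
        rows.append(row)
    behavior = pd.DataFrame(rows)

    truth = GroundTruth(
        critical_mask=critical,
        aos_mask=aos_mask,
        coverage_fraction=cov,
        latent=pd.DataFrame(
            {
                "self_generated": latent_self,
                "overall": latent_overall,
                "repetition": latent_rep,
                "naming": latent_naming,
            }
        ),
    )
    return masks, behavior, truth


def generate_paired_assessments(
    n: int,
    latent_sd: float,
    seed: int,
    instrument_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Paired WAB+QAB raw subscores drawn from one latent profile per subject.

    Both instruments observe the same latent self/overall/repetition/naming
    profile plus independent instrument noise, so the harmonized metrics
    correlate — perfectly when ``instrument_noise_sd`` is 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 paired subjects, got {n}")
    if latent_sd <= 0:
        raise ValueError("latent_sd must be positive")
    rng = np.random.default_rng(seed)
    latent = _clamp01_10(rng.normal(7.0, latent_sd, size=(n, 4)))
    eps_w = rng.normal(0.0, instrument_noise_sd, size=(n, 4))
    eps_q = rng.normal(0.0, instrument_noise_sd, size=(n, 4))
    wab = _clamp01_10(latent + eps_w)
    qab = _clamp01_10(latent + eps_q)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i + 1:03d}" for i in range(n)],
            "wab_fluency": wab[:, 0],
            "wab_aq": wab[:, 1] * 10.0,
            "wab_repetition": wab[:, 2],
            "wab_naming": wab[:, 3],
            "qab_length_complexity": qab[:, 0] * 0.4,
            "qab_speech_rate": qab[:, 0] * 0.4,
            "qab_comm_impairment": qab[:, 0] * 0.4,
            "qab_overall": qab[:, 1],
            "qab_repetition": qab[:, 2],
            "qab_naming": qab[:, 3],
        }
    )
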