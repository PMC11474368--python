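"""Seedable synthetic cohorts with ground-truth mismatch labels.

The generator is a forward model of the mechanisms that make circumpapillary
RNFL and BMO-MRW disagree in glaucomatous eyes:

* clean angular profiles are the normative mean curves pulled toward a
  parameter-specific measurement floor by arcuate wedge defects plus a
  diffuse loss component (the rim collapses toward its floor faster than
  the RNFL, so deep defects leave MRW proportionally lower);
* large vessels (the arcade branches near the vertical poles) add a large
  bump to the RNFL profile at the vessel's retinal trajectory and a smaller
  bump to the MRW at its optic-nerve-head insertion, offset by a
  configurable angular deviation;
* small circumlinear vessels, focal retinoschisis and inclusion of outer
  retinal layers thicken the MRW only.

Ground-truth mismatch labels are computed by running the two-stage screen
analytically on the *noiseless* sector values, so tests can separate screen
errors from noise effects.  Generation is bit-deterministic for a fixed
seed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEG_PER_ASCAN,
    N_ASCANS,
    N_SECTORS,
    SectorGrid,
    circular_distance,
    sectorize_rnfl,
)
from .normative import (
    DEFAULT_MRW_CONFIG,
    DEFAULT_RNFL_CONFIG,
    BandConfig,
    NormativeBands,
    build_default_bands,
    classify,
)
from .screening import (
    DEFAULT_CUTOFFS,
    Cutoffs,
    MismatchType,
    ScreenGroup,
    ScreenResult,
    stage1_group,
    stage2_confirm,
)

__all__ = [
    "EyeRecord",
    "ArtifactKind",
    "Artifact",
    "SyntheticTruth",
    "CohortConfig",
    "generate_cohort",
    "floor_model",
    "annotations_from_truth",
    "evaluate_recovery",
]

logger = logging.getLogger(__name__)


@dataclass
class EyeRecord:
    """One eye's exported measurements and session metadata."""

    eye_id: str
    patient_id: str
    laterality: str
    age: float
    rnfl_profile: np.ndarray  # 768 values, µm (NaN = missing A-scan)
    mrw_sectors: np.ndarray  # 48 values, µm
    bmo_area: float  # mm²
    quality_factor: float
    missing_fraction: float

    def __post_init__(self) -> None:
        self.rnfl_profile = np.asarray(self.rnfl_profile, dtype=float)
        self.mrw_sectors = np.asarray(self.mrw_sectors, dtype=float)
        if self.rnfl_profile.shape != (N_ASCANS,):
            raise ValueError(f"rnfl_profile must have {N_ASCANS} values")
        if self.mrw_sectors.shape != (N_SECTORS,):
            raise ValueError(f"mrw_sectors must have {N_SECTORS} values")
        for arr in (self.rnfl_profile, self.mrw_sectors):
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError("thicknesses must be non-negative")


class ArtifactKind(enum.Enum):
    LARGE_VESSEL = "large_vessel"
    SMALL_VESSEL = "small_vessel"
    RETINOSCHISIS = "retinoschisis"
    OUTER_RETINA_INCLUSION = "outer_retina_inclusion"
    GLAUCOMA_WEDGE = "glaucoma_wedge"


@dataclass(frozen=True)
class Artifact:
    """One injected feature: location, kind, magnitude and vessel offset.

    For vessels ``angle_deg`` is the retinal-trajectory angle and
    ``offset_deg`` the signed angular deviation of the optic-nerve-head
    insertion relative to it; for other kinds the offset is 0.
    """

    kind: ArtifactKind
    angle_deg: float
    magnitude_um: float
    offset_deg: float = 0.0
    sigma_deg: float = 4.0

    @property
    def insertion_angle_deg(self) -> float:
        return (self.angle_deg + self.offset_deg) % 360.0


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort.

    ``expected[eye_id][angle]`` is the mismatch type the two-stage screen
    assigns to the noiseless sector values (absent key = no mismatch);
    derivable deterministically from the clean profiles, artifacts and bands.
    """

    artifacts: dict[str, list[Artifact]]
    expected: dict[str, dict[float, MismatchType]] = field(default_factory=dict)
    clean_rnfl_sectors: dict[str, np.ndarray] = field(default_factory=dict)
    clean_mrw_sectors: dict[str, np.ndarray] = field(default_factory=dict)

    def n_expected(self) -> int:
        return sum(len(v) for v in self.expected.values())


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a glaucoma cohort with the published stage mix
    (56% early / 23% moderate / 21% advanced), arcade large vessels near the
    vertical poles (trajectories concentrated around 82.5° / 277.5°), small
    circumlinear vessels concentrated around 45° / 322.5°, and sporadic
    retinoschisis / outer-retina inclusion.  All magnitudes in µm, angles in
    degrees, TSNIT right-eye convention.
    """

    n_eyes: int = 100
    second_eye_prob: float = 0.58  # 186 eyes / 118 patients

    # demography / metadata
    age_mean: float = 68.1
    age_sd: float = 9.1
    age_range: tuple[float, float] = (40.0, 80.0)
    bmo_area_mean: float = 1.92
    bmo_area_sd: float = 0.48
    quality_mean: float = 25.0
    quality_sd: float = 5.0
    missing_prob: float = 0.15  # eyes with a missing-data run
    missing_max_fraction: float = 0.14

    # disease model
    severity_mix: tuple[float, float, float] = (0.56, 0.23, 0.21)
    severity_ranges: tuple[tuple[float, float], ...] = ((0.15, 0.5), (0.5, 0.75), (0.75, 0.98))
    diffuse_loss_frac: float = 0.3
    extra_wedge_prob: float = 0.6  # second wedge in the opposite hemifield
    wedge_center_means: tuple[float, float] = (67.5, 292.5)
    wedge_center_kappa: float = 4.0
    wedge_core_half_width_range: tuple[float, float] = (15.0, 45.0)
    wedge_taper_deg: float = 10.0
    wedge_depth_jitter: float = 0.35

    # normative shape and floors
    rnfl_shape: BandConfig = DEFAULT_RNFL_CONFIG
    mrw_shape: BandConfig = DEFAULT_MRW_CONFIG
    rnfl_floor_um: float = 42.0
    mrw_floor_um: float = 65.0
    rnfl_severity_gamma: float = 1.0
    mrw_severity_gamma: float = 1.6

    # artifacts
    large_vessels_per_pole: int = 1
    extra_large_vessel_rate: float = 0.5
    large_vessel_centers: tuple[float, float] = (82.5, 277.5)
    large_vessel_kappa: float = 75.0
    large_vessel_rnfl_peak_range: tuple[float, float] = (100.0, 150.0)
    large_vessel_mrw_bump_range: tuple[float, float] = (15.0, 30.0)
    large_vessel_sigma_range: tuple[float, float] = (2.0, 3.0)
    large_vessel_offset_mean: float = 12.0
    large_vessel_offset_sd: float = 4.0

    small_vessels_per_center: int = 1
    extra_small_vessel_rate: float = 0.5
    small_vessel_centers: tuple[float, float] = (45.0, 322.5)
    small_vessel_kappa: float = 40.0
    small_vessel_mrw_peak_range: tuple[float, float] = (150.0, 210.0)
    small_vessel_sigma_deg: float = 6.0

    retinoschisis_rate: float = 0.06
    retinoschisis_peak_range: tuple[float, float] = (120.0, 200.0)
    retinoschisis_sigma_deg: float = 6.0
    outer_retina_rate: float = 0.12
    outer_retina_peak_range: tuple[float, float] = (90.0, 150.0)
    outer_retina_sigma_deg: float = 5.0

    # measurement noise
    rnfl_noise_sd: float = 2.0  # per A-scan
    mrw_noise_sd: float = 3.0  # per radial cut

    cutoffs: Cutoffs = DEFAULT_CUTOFFS


def floor_model(severity, parameter: str, config: CohortConfig | None = None):
    """Residual thickness (µm) at the global mean level for a given severity.

    Monotone decreasing from the normative mean at severity 0 to the
    configured floor at severity 1:
    ``floor + (mean − floor) · (1 − severity)^γ`` with a per-parameter
    exponent γ (>1 for BMO-MRW, which approaches its floor faster).
    """
    if config is None:
        config = CohortConfig()
    severity = np.asarray(severity, dtype=float)
    if np.any(severity < 0) or np.any(severity > 1):
        raise ValueError("severity must lie in [0, 1]")
    if parameter == "RNFL":
        mean, floor, gamma = (
            config.rnfl_shape.mean_level_um,
            config.rnfl_floor_um,
            config.rnfl_severity_gamma,
        )
    elif parameter == "BMO_MRW":
        mean, floor, gamma = (
            config.mrw_shape.mean_level_um,
            config.mrw_floor_um,
            config.mrw_severity_gamma,
        )
    else:
        raise ValueError(f"unknown parameter {parameter!r}")
    out = floor + (mean - floor) * (1.0 - severity) ** gamma
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class _Wedge:
    center_deg: float
    core_half_width_deg: float
    taper_deg: float
    depth: float


def _wedge_profile(angles: np.ndarray, wedge: _Wedge) -> np.ndarray:
    """Plateau defect with raised-cosine shoulders (1 in the core, 0 outside)."""
    d = circular_distance(angles, wedge.center_deg)
    out = np.zeros_like(d, dtype=float)
    out[d <= wedge.core_half_width_deg] = 1.0
    shoulder = (d > wedge.core_half_width_deg) & (d < wedge.core_half_width_deg + wedge.taper_deg)
    frac = (d[shoulder] - wedge.core_half_width_deg) / wedge.taper_deg
    out[shoulder] = 0.5 * (1.0 + np.cos(np.pi * frac))
    return out


def _gaussian_bump(angles: np.ndarray, center_deg: float, peak_um: float, sigma_deg: float) -> np.ndarray:
    d = circular_distance(angles, center_deg)
    return peak_um * np.exp(-0.5 * (d / sigma_deg) ** 2)


def _von_mises_deg(rng: np.random.Generator, mu_deg: float, kappa: float) -> float:
    return float(np.degrees(rng.vonmises(np.radians(mu_deg), kappa)) % 360.0)


def _severity_field(angles: np.ndarray, wedges: list[_Wedge], diffuse: float) -> np.ndarray:
    sev = np.full_like(angles, diffuse, dtype=float)
    for w in wedges:
        sev = sev + w.depth * _wedge_profile(angles, w)
    return np.clip(sev, 0.0, 1.0)


def _clean_profiles(
    config: CohortConfig, wedges: list[_Wedge], artifacts: list[Artifact]
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless RNFL A-scan profile (768) and MRW cut values (48)."""
    ascan_angles = np.arange(N_ASCANS) * DEG_PER_ASCAN
    cut_angles = SectorGrid().sector_angles
    diffuse_base = config.diffuse_loss_frac

    rnfl = _residual(config, "RNFL", ascan_angles, wedges, diffuse_base)
    mrw = _residual(config, "BMO_MRW", cut_angles, wedges, diffuse_base)

    for art in artifacts:
        if art.kind is ArtifactKind.LARGE_VESSEL:
            rnfl = rnfl + _gaussian_bump(ascan_angles, art.angle_deg, art.magnitude_um, art.sigma_deg)
            mrw_bump = art.magnitude_um * 0.2  # smaller insertion bump
            mrw = mrw + _gaussian_bump(cut_angles, art.insertion_angle_deg, mrw_bump, art.sigma_deg)
        else:
            mrw = mrw + _gaussian_bump(cut_angles, art.angle_deg, art.magnitude_um, art.sigma_deg)

    if np.any(rnfl < config.rnfl_floor_um - 1e-9) or np.any(mrw < config.mrw_floor_um - 1e-9):
        logger.warning("profile fell below the configured floor; clipping")
        rnfl = np.maximum(rnfl, config.rnfl_floor_um)
        mrw = np.maximum(mrw, config.mrw_floor_um)
    return rnfl, mrw


def _residual(
    config: CohortConfig,
    parameter: str,
    angles: np.ndarray,
    wedges: list[_Wedge],
    diffuse_frac: float,
) -> np.ndarray:
    shape = config.rnfl_shape if parameter == "RNFL" else config.mrw_shape
    floor = config.rnfl_floor_um if parameter == "RNFL" else config.mrw_floor_um
    gamma = config.rnfl_severity_gamma if parameter == "RNFL" else config.mrw_severity_gamma
    mean = shape.mean_curve(angles)
    # severity scales the per-eye diffuse component
    sev = _severity_field(angles, wedges, diffuse_frac * (wedges[0].depth if wedges else 0.0))
    return floor + (mean - floor) * (1.0 - sev) ** gamma


def _expected_labels(
    clean_rnfl_sectors: np.ndarray,
    clean_mrw: np.ndarray,
    age: float,
    bands_rnfl: NormativeBands,
    bands_mrw: NormativeBands,
    cutoffs: Cutoffs,
    grid: SectorGrid,
) -> dict[float, MismatchType]:
    """Run the screen definition analytically on the noiseless sector values."""
    expected: dict[float, MismatchType] = {}
    sector_angles = grid.sector_angles
    for angle in grid.analysis_angles:
        k = int(np.argmin(np.abs(sector_angles - angle)))
        group = stage1_group(clean_rnfl_sectors[k], clean_mrw[k], cutoffs)
        if group in (ScreenGroup.G2_highMRW_lowRNFL, ScreenGroup.G4_highRNFL_lowMRW):
            mtype = stage2_confirm(
                group,
                classify(clean_rnfl_sectors[k], angle, bands_rnfl, age),
                classify(clean_mrw[k], angle, bands_mrw, age),
            )
            if mtype is not None:
                expected[float(angle)] = mtype
    return expected


def _draw_wedges(rng: np.random.Generator, config: CohortConfig, severity: float) -> list[_Wedge]:
    hemis = [0, 1] if rng.random() < config.extra_wedge_prob else [int(rng.integers(2))]
    wedges = []
    for h in hemis:
        depth = float(np.clip(severity + rng.uniform(0.0, config.wedge_depth_jitter), 0.0, 1.0))
        wedges.append(
            _Wedge(
                center_deg=_von_mises_deg(rng, config.wedge_center_means[h], config.wedge_center_kappa),
                core_half_width_deg=float(rng.uniform(*config.wedge_core_half_width_range)),
                taper_deg=config.wedge_taper_deg,
                depth=depth,
            )
        )
    # anchor the diffuse component to the deepest wedge
    wedges.sort(key=lambda w: -w.depth)
    return wedges


def _draw_artifacts(rng: np.random.Generator, config: CohortConfig) -> list[Artifact]:
    artifacts: list[Artifact] = []
    # large arcade vessels: one per vertical pole plus occasional extras
    n_extra = int(rng.poisson(config.extra_large_vessel_rate))
    poles = list(config.large_vessel_centers) * config.large_vessels_per_pole
    poles += [config.large_vessel_centers[int(rng.integers(2))] for _ in range(n_extra)]
    for mu in poles:
        offset = float(rng.normal(config.large_vessel_offset_mean, config.large_vessel_offset_sd))
        offset *= -1 if rng.random() < 0.5 else 1
        artifacts.append(
            Artifact(
                kind=ArtifactKind.LARGE_VESSEL,
                angle_deg=_von_mises_deg(rng, mu, config.large_vessel_kappa),
                magnitude_um=float(rng.uniform(*config.large_vessel_rnfl_peak_range)),
                offset_deg=offset,
                sigma_deg=float(rng.uniform(*config.large_vessel_sigma_range)),
            )
        )
    # small circumlinear vessels near the superotemporal/inferotemporal centres
    n_extra = int(rng.poisson(config.extra_small_vessel_rate))
    centres = list(config.small_vessel_centers) * config.small_vessels_per_center
    centres += [config.small_vessel_centers[int(rng.integers(2))] for _ in range(n_extra)]
    for mu in centres:
        artifacts.append(
            Artifact(
                kind=ArtifactKind.SMALL_VESSEL,
                angle_deg=_von_mises_deg(rng, mu, config.small_vessel_kappa),
                magnitude_um=float(rng.uniform(*config.small_vessel_mrw_peak_range)),
                sigma_deg=config.small_vessel_sigma_deg,
            )
        )
    analysis = SectorGrid().analysis_angles
    for kind, rate, peaks, sigma in (
        (ArtifactKind.RETINOSCHISIS, config.retinoschisis_rate, config.retinoschisis_peak_range, config.retinoschisis_sigma_deg),
        (ArtifactKind.OUTER_RETINA_INCLUSION, config.outer_retina_rate, config.outer_retina_peak_range, config.outer_retina_sigma_deg),
    ):
        for _ in range(int(rng.poisson(rate))):
            artifacts.append(
                Artifact(
                    kind=kind,
                    angle_deg=float(rng.choice(analysis)) + float(rng.uniform(-3.75, 3.75)),
                    magnitude_um=float(rng.uniform(*peaks)),
                    sigma_deg=sigma,
                )
            )
    return artifacts


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[EyeRecord], SyntheticTruth]:
    """Generate a synthetic glaucoma cohort with full ground truth.

    Deterministic for a fixed seed.  Returns the eye records (noisy, with
    missing-data runs and QC metadata) and the :class:`SyntheticTruth`
    holding injected artifacts and the expected mismatch label per analysed
    sector, computed on the noiseless profiles.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    grid = SectorGrid()
    bands_rnfl = build_default_bands("RNFL")
    bands_mrw = build_default_bands("BMO_MRW")

    eyes: list[EyeRecord] = []
    truth = SyntheticTruth(artifacts={})
    stages = np.arange(3)
    patient = 0
    eyes_left = config.n_eyes
    while eyes_left > 0:
        patient += 1
        n_for_patient = 2 if (rng.random() < config.second_eye_prob and eyes_left >= 2) else 1
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
        lateralities = ["right", "left"] if n_for_patient == 2 else [("right", "left")[int(rng.integers(2))]]
        for lat in lateralities[:n_for_patient]:
            eye_id = f"E{config.n_eyes - eyes_left + 1:04d}"
            eyes_left -= 1
            stage = int(rng.choice(stages, p=np.asarray(config.severity_mix)))
            severity = float(rng.uniform(*config.severity_ranges[stage]))
            wedges = _draw_wedges(rng, config, severity)
            artifacts = _draw_artifacts(rng, config)
            clean_rnfl, clean_mrw = _clean_profiles(config, wedges, artifacts)

            clean_sectors = sectorize_rnfl(clean_rnfl).values
            truth.clean_rnfl_sectors[eye_id] = clean_sectors
            truth.clean_mrw_sectors[eye_id] = clean_mrw.copy()
            truth.artifacts[eye_id] = artifacts + [
                Artifact(
                    kind=ArtifactKind.GLAUCOMA_WEDGE,
                    angle_deg=w.center_deg,
                    magnitude_um=w.depth * (config.rnfl_shape.mean_level_um - config.rnfl_floor_um),
                    sigma_deg=w.core_half_width_deg,
                )
                for w in wedges
            ]
            truth.expected[eye_id] = _expected_labels(
                clean_sectors, clean_mrw, age, bands_rnfl, bands_mrw, config.cutoffs, grid
            )

            rnfl = np.maximum(clean_rnfl + rng.normal(0.0, config.rnfl_noise_sd, N_ASCANS), 0.0)
            mrw = np.maximum(clean_mrw + rng.normal(0.0, config.mrw_noise_sd, N_SECTORS), 0.0)
            missing_fraction = 0.0
            if rng.random() < config.missing_prob:
                missing_fraction = float(rng.uniform(0.0, config.missing_max_fraction))
                n_miss = int(round(missing_fraction * N_ASCANS))
                if n_miss:
                    start = int(rng.integers(N_ASCANS))
                    rnfl[(start + np.arange(n_miss)) % N_ASCANS] = np.nan
            eyes.append(
                EyeRecord(
                    eye_id=eye_id,
                    patient_id=f"P{patient:04d}",
                    laterality=lat,
                    age=age,
                    rnfl_profile=rnfl,
                    mrw_sectors=mrw,
                    bmo_area=float(np.clip(rng.normal(config.bmo_area_mean, config.bmo_area_sd), 1.0, 3.5)),
                    quality_factor=float(np.clip(rng.normal(config.quality_mean, config.quality_sd), 5.0, 40.0)),
                    missing_fraction=missing_fraction,
                )
            )
    return eyes, truth


#: Artifact kinds that thicken the MRW at a record's angle.
_MRW_THICKENERS = (
    ArtifactKind.SMALL_VESSEL,
    ArtifactKind.RETINOSCHISIS,
    ArtifactKind.OUTER_RETINA_INCLUSION,
)

_KIND_TO_CAUSE = {
    ArtifactKind.LARGE_VESSEL: "large_vessel",
    ArtifactKind.SMALL_VESSEL: "small_vessel",
    ArtifactKind.RETINOSCHISIS: "retinoschisis",
    ArtifactKind.OUTER_RETINA_INCLUSION: "outer_retina_inclusion",
}


def annotations_from_truth(truth: SyntheticTruth, records, window_deg: float = 15.0):
    """Derive cause annotations for mismatch records from injected artifacts.

    Stands in for the qualitative image review: each record is attributed to
    the nearest injected artifact (within ``window_deg``) that can explain
    its direction — MRW thickeners (small vessels, retinoschisis,
    outer-retina inclusion, large-vessel insertions) for high-MRW/low-RNFL
    records, large-vessel trajectories for high-RNFL/low-MRW records.
    """
    from .attribution import Cause, CauseAnnotation

    annotations = []
    for rec in records:
        arts = truth.artifacts.get(rec.eye_id, [])
        best: tuple[float, ArtifactKind] | None = None
        for art in arts:
            if rec.type is MismatchType.HIGH_MRW_LOW_RNFL:
                if art.kind in _MRW_THICKENERS:
                    d = float(circular_distance(art.angle_deg, rec.angle_deg))
                elif art.kind is ArtifactKind.LARGE_VESSEL:
                    d = float(circular_distance(art.insertion_angle_deg, rec.angle_deg))
                else:
                    continue
            elif rec.type is MismatchType.HIGH_RNFL_LOW_MRW:
                if art.kind is not ArtifactKind.LARGE_VESSEL:
                    continue
                d = float(circular_distance(art.angle_deg, rec.angle_deg))
            else:  # pragma: no cover - closed enum
                continue
            if d <= window_deg and (best is None or d < best[0]):
                best = (d, art.kind)
        cause = Cause(_KIND_TO_CAUSE[best[1]]) if best else Cause.OTHER
        annotations.append(CauseAnnotation(eye_id=rec.eye_id, angle_deg=rec.angle_deg, cause=cause))
    return annotations


def evaluate_recovery(results: list[ScreenResult], truth: SyntheticTruth) -> dict:
    """Compare screened mismatches with the ground-truth labels.

    Restricted to sectors that were actually screened (eyes passing QC,
    sectors without missing data).  Sensitivity = recovered truth-positive
    sectors / truth positives; the false-positive rate is over truth-negative
    screened sectors.
    """
    tp = fn = fp = tn = 0
    for res in results:
        expected = truth.expected.get(res.eye_id, {})
        detected = {rec.angle_deg: rec.type for rec in res.records}
        for angle in res.screened_angles:
            exp = expected.get(angle)
            det = detected.get(angle)
            if exp is not None:
                if det == exp:
                    tp += 1
                else:
                    fn += 1
            else:
                if det is not None:
                    fp += 1
                else:
                    tn += 1
    n_pos, n_neg = tp + fn, fp + tn
    return {
        "n_truth_positive": n_pos,
        "n_truth_negative": n_neg,
        "true_positives": tp,
        "false_negatives": fn,
        "false_positives": fp,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "false_positive_rate": fp / n_neg if n_neg else float("nan"),
    }
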