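"""Angle-dependent normative percentile bands and TSNIT colour classification.

A sector value is classified against per-angle 1st and 5th percentile
thresholds the way the device renders the TSNIT curve: below the 1st
percentile is red, between the 1st and 5th yellow, above the 5th green.
Device normative databases are proprietary and unpublished, so this module
ships a parametric stand-in — a harmonic mean curve (the double-hump TSNIT
shape for RNFL), Gaussian dispersion and a linear age slope — and also
accepts user-supplied per-angle threshold tables.  The thresholds therefore
vary with the location around the optic nerve head and with patient age:
the same 70 µm RNFL value can fall below the 1st percentile at a
superotemporal cut yet within the normal range at a temporal cut.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import N_SECTORS, SECTOR_SPACING_DEG, SectorGrid

__all__ = [
    "PercentileClass",
    "Harmonic",
    "BandConfig",
    "NormativeBands",
    "DEFAULT_RNFL_CONFIG",
    "DEFAULT_MRW_CONFIG",
    "build_default_bands",
    "classify",
    "classify_values",
    "load_bands",
    "save_bands",
]

Z_P1 = float(stats.norm.ppf(0.01))  # -2.3263
Z_P5 = float(stats.norm.ppf(0.05))  # -1.6449


class PercentileClass(enum.Enum):
    """TSNIT colour class: RED < p1 ≤ YELLOW < p5 ≤ GREEN."""

    RED = "red"  # below the 1st percentile
    YELLOW = "yellow"  # 1st to 5th percentile
    GREEN = "green"  # above the 5th percentile


class ConfigError(ValueError):
    """Invalid band configuration (e.g. non-monotone quantiles)."""


@dataclass(frozen=True)
class Harmonic:
    """One cosine term of the mean curve: amplitude·cos(order·(θ − phase))."""

    order: int
    amplitude_um: float
    phase_deg: float


@dataclass(frozen=True)
class BandConfig:
    """Parametric generator for normative percentile bands.

    The mean curve is ``level + Σ harmonics`` over the 48 sector angles;
    percentile thresholds are ``mean + z·dispersion`` with z at the 1st/5th
    standard-normal quantiles, clamped at a positive floor.  Age adjustment
    is linear: thresholds shift by ``age_slope · (age − reference_age)``.
    """

    mean_level_um: float
    harmonics: tuple[Harmonic, ...] = ()
    dispersion_sd_um: float = 15.0
    age_slope_um_per_year: float = -0.2
    reference_age_years: float = 55.0
    floor_um: float = 2.0

    def mean_curve(self, angles_deg: np.ndarray) -> np.ndarray:
        angles = np.asarray(angles_deg, dtype=float)
        out = np.full_like(angles, self.mean_level_um, dtype=float)
        for h in self.harmonics:
            out = out + h.amplitude_um * np.cos(h.order * np.radians(angles - h.phase_deg))
        return out


#: Double-hump TSNIT shape: ~63 µm temporal/nasal troughs, ~133 µm
#: superior/inferior peaks, between-subject SD 16 µm, mild ageing loss.
DEFAULT_RNFL_CONFIG = BandConfig(
    mean_level_um=98.0,
    harmonics=(Harmonic(order=2, amplitude_um=35.0, phase_deg=90.0),),
    dispersion_sd_um=16.0,
    age_slope_um_per_year=-0.2,
    reference_age_years=55.0,
    floor_um=2.0,
)

#: Neuroretinal rim width: higher level, wide between-subject spread and a
#: steeper age slope than RNFL.
DEFAULT_MRW_CONFIG = BandConfig(
    mean_level_um=300.0,
    harmonics=(Harmonic(order=2, amplitude_um=30.0, phase_deg=90.0),),
    dispersion_sd_um=50.0,
    age_slope_um_per_year=-1.0,
    reference_age_years=55.0,
    floor_um=5.0,
)

DEFAULT_CONFIGS = {"RNFL": DEFAULT_RNFL_CONFIG, "BMO_MRW": DEFAULT_MRW_CONFIG}


@dataclass(frozen=True)
class NormativeBands:
    """Per-angle 1st/5th percentile thresholds for one parameter (µm)."""

    parameter: str
    angles_deg: np.ndarray
    p1_um: np.ndarray
    p5_um: np.ndarray
    reference_age_years: float = 55.0
    age_slope_um_per_year: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", np.asarray(self.angles_deg, dtype=float))
        object.__setattr__(self, "p1_um", np.asarray(self.p1_um, dtype=float))
        object.__setattr__(self, "p5_um", np.asarray(self.p5_um, dtype=float))
        if self.angles_deg.shape != (N_SECTORS,):
            raise ConfigError(f"bands must cover all {N_SECTORS} sector angles")
        if self.age_slope_um_per_year > 0:
            raise ConfigError("age slope must be ≤ 0 (thickness does not grow with age)")
        if np.any(self.p1_um <= 0) or np.any(self.p1_um >= self.p5_um):
            raise ConfigError("bands require 0 < p1 < p5 at every angle")

    def _angle_index(self, angle_deg: float) -> int:
        idx = int(round((angle_deg % 360.0) / SECTOR_SPACING_DEG)) % N_SECTORS
        if not np.isclose(self.angles_deg[idx], angle_deg % 360.0):
            raise ValueError(f"angle {angle_deg}° is not on the {SECTOR_SPACING_DEG}° sector grid")
        return idx

    def thresholds_at(self, angle_deg: float, age_years: float | None = None) -> tuple[float, float]:
        """Age-adjusted (p1, p5) at one sector angle."""
        idx = self._angle_index(angle_deg)
        shift = 0.0
        if age_years is not None:
            shift = self.age_slope_um_per_year * (age_years - self.reference_age_years)
        return float(self.p1_um[idx] + shift), float(self.p5_um[idx] + shift)


def build_default_bands(parameter: str, config: BandConfig | None = None) -> NormativeBands:
    """Deterministic parametric bands for ``parameter`` ("RNFL" or "BMO_MRW")."""
    if parameter not in DEFAULT_CONFIGS:
        raise ConfigError(f"unknown parameter {parameter!r}; expected one of {list(DEFAULT_CONFIGS)}")
    if config is None:
        config = DEFAULT_CONFIGS[parameter]
    if config.dispersion_sd_um <= 0:
        raise ConfigError("dispersion must be positive: zero dispersion collapses p1 onto p5")
    angles = SectorGrid().sector_angles
    mean = config.mean_curve(angles)
    p1 = np.maximum(mean + Z_P1 * config.dispersion_sd_um, config.floor_um)
    p5 = np.maximum(mean + Z_P5 * config.dispersion_sd_um, config.floor_um)
    if np.any(p1 >= p5):
        raise ConfigError("floor clamp collapsed p1 onto p5; lower the floor or raise the mean")
    return NormativeBands(
        parameter=parameter,
        angles_deg=angles,
        p1_um=p1,
        p5_um=p5,
        reference_age_years=config.reference_age_years,
        age_slope_um_per_year=config.age_slope_um_per_year,
        provenance=f"parametric stand-in: {config}",
    )


def classify(
    value_um: float,
    angle_deg: float,
    bands: NormativeBands,
    age_years: float | None = None,
) -> PercentileClass:
    """Classify one sector value into the TSNIT colour class.

    RED if strictly below the (age-adjusted) 1st percentile; YELLOW from the
    1st up to (excluding) the 5th; GREEN at or above the 5th.  A value exactly
    at p1 is "greater than first percentile", hence YELLOW.
    """
    if not np.isfinite(value_um) or value_um < 0:
        raise ValueError(f"value must be finite and non-negative, got {value_um}")
    p1, p5 = bands.thresholds_at(angle_deg, age_years)
    if value_um < p1:
        return PercentileClass.RED
    if value_um < p5:
        return PercentileClass.YELLOW
    return PercentileClass.GREEN


def classify_values(
    values_um: np.ndarray,
    angles_deg: np.ndarray,
    bands: NormativeBands,
    age_years: float | None = None,
) -> list[PercentileClass]:
    """Vectorised :func:`classify` over paired (value, angle) arrays."""
    values = np.asarray(values_um, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    return [classify(v, a, bands, age_years) for v, a in zip(values, angles, strict=True)]


def save_bands(bands: NormativeBands, path: str | Path) -> None:
    """Write a band table as delimited text: angle_deg, p1_um, p5_um."""
    pd.DataFrame(
        {"angle_deg": bands.angles_deg, "p1_um": bands.p1_um, "p5_um": bands.p5_um}
    ).to_csv(path, index=False)


def load_bands(
    path: str | Path,
    parameter: str = "RNFL",
    reference_age_years: float = 55.0,
    age_slope_um_per_year: float = 0.0,
) -> NormativeBands:
    """Load a per-angle threshold table (columns angle_deg, p1_um, p5_um)."""
    df = pd.read_csv(path)
    required = {"angle_deg", "p1_um", "p5_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"band table {path} must have columns {sorted(required)}")
    df = df.sort_values("angle_deg").reset_index(drop=True)
    return NormativeBands(
        parameter=parameter,
        angles_deg=df["angle_deg"].to_numpy(),
        p1_um=df["p1_um"].to_numpy(),
        p5_um=df["p5_um"].to_numpy(),
        reference_age_years=reference_age_years,
        age_slope_um_per_year=age_slope_um_per_year,
        provenance=f"loaded from {path}",
    )
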