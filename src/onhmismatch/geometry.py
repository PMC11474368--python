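"""Angular geometry of the circumpapillary measurement circle.

The optic-nerve-head volume scan acquires 768 A-scans on a 12° measurement
circle centred on the BMO centroid, plus 24 radial B-scans whose two ends
yield 48 BMO-MRW measurements at 7.5° increments.  This module defines the
shared angular coordinate system (0° = temporal, TSNIT rotational order,
right-eye format), maps the 768-point RNFL profile onto the 48 radial
sectors, and selects the 37-sector analysis wedge that excludes the noisy
nasal 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "N_ASCANS",
    "N_SECTORS",
    "N_RADIAL_CUTS",
    "ASCANS_PER_SECTOR",
    "SECTOR_SPACING_DEG",
    "DEG_PER_ASCAN",
    "WEDGE_START_DEG",
    "WEDGE_END_DEG",
    "N_ANALYSIS_SECTORS",
    "SectorGrid",
    "AngularConvention",
    "SectorizedProfile",
    "SectorAverager",
    "ascan_angle",
    "sector_ascan_indices",
    "sectorize_rnfl",
    "analysis_angles",
    "normalize_laterality",
    "circular_distance",
]

N_ASCANS = 768
N_RADIAL_CUTS = 24
N_SECTORS = 48
ASCANS_PER_SECTOR = N_ASCANS // N_SECTORS  # 16
SECTOR_SPACING_DEG = 360.0 / N_SECTORS  # 7.5
DEG_PER_ASCAN = 360.0 / N_ASCANS  # 0.46875
#: Analysis wedge runs from 225° through temporal 0° to 135° (both ends
#: inclusive), i.e. the temporal 180° plus the superonasal and inferonasal 45°.
WEDGE_START_DEG = 225.0
WEDGE_END_DEG = 135.0
N_ANALYSIS_SECTORS = 37


@dataclass(frozen=True)
class AngularConvention:
    """Angular convention: 0° temporal, TSNIT order, right-eye format.

    Under this convention 90° is superior, 180° nasal and 270° inferior;
    all angles are reduced modulo 360.  Left-eye data presented in absolute
    screen orientation are mirrored about the vertical axis so that the
    temporal position maps to 0° for every eye.
    """

    zero_reference: str = "temporal"
    direction: str = "tsnit"
    format: str = "right eye format"


@dataclass(frozen=True)
class SectorGrid:
    """The 48-sector grid derived from 24 radial B-scans.

    Parameters
    ----------
    phase_offset_deg:
        Angular offset of A-scan 0 relative to the temporal radial cut.
        The device documentation does not state the phase; the default
        anchors A-scan 0 at 0° with sectors centred on the cut angles.
    """

    n_radial_cuts: int = N_RADIAL_CUTS
    n_sectors: int = N_SECTORS
    sector_spacing_deg: float = SECTOR_SPACING_DEG
    phase_offset_deg: float = 0.0
    convention: AngularConvention = field(default_factory=AngularConvention)

    def __post_init__(self) -> None:
        if self.n_sectors != 2 * self.n_radial_cuts:
            raise ValueError("n_sectors must equal 2 x n_radial_cuts")
        if not np.isclose(self.sector_spacing_deg * self.n_sectors, 360.0):
            raise ValueError("sector_spacing_deg x n_sectors must equal 360")

    @property
    def sector_angles(self) -> np.ndarray:
        """Centre angles of the 48 sectors in ascending order (degrees)."""
        return np.arange(self.n_sectors) * self.sector_spacing_deg

    @property
    def analysis_mask(self) -> np.ndarray:
        """Boolean mask over sector indices: True for the 37 analysed sectors.

        The 11 masked-out sectors lie in the nasal wedge 142.5°–217.5°
        inclusive (nasal 90° centred at 180°, both half-open flanks).
        """
        ang = self.sector_angles
        return ~((ang > WEDGE_END_DEG) & (ang < WEDGE_START_DEG))

    @property
    def analysis_angles(self) -> np.ndarray:
        return analysis_angles(self)


def ascan_angle(index: int, grid: SectorGrid | None = None) -> float:
    """Angle of an A-scan on the measurement circle, degrees in [0, 360).

    A-scan ``index`` sits at ``index * 360/768 = index * 0.46875°`` (plus the
    grid's phase offset, zero by default).
    """
    index = int(index)
    if not 0 <= index < N_ASCANS:
        raise ValueError(f"A-scan index must be in [0, {N_ASCANS - 1}], got {index}")
    offset = 0.0 if grid is None else grid.phase_offset_deg
    return float((index * DEG_PER_ASCAN + offset) % 360.0)


def sector_ascan_indices(sector_k: int) -> np.ndarray:
    """The 16 A-scan indices averaged into sector ``sector_k``.

    Each sector thickness is the average of 16 A-scans centred around the
    radial BMO-MRW cut angle ``7.5 * k``: the contiguous (modulo 768) indices
    whose angles fall in the half-open window [7.5k − 3.75, 7.5k + 3.75),
    i.e. indices ``16k − 8 … 16k + 7`` mod 768.  The 48 windows partition the
    768 A-scans exactly.
    """
    sector_k = int(sector_k)
    if not 0 <= sector_k < N_SECTORS:
        raise ValueError(f"sector index must be in [0, {N_SECTORS - 1}], got {sector_k}")
    start = ASCANS_PER_SECTOR * sector_k - ASCANS_PER_SECTOR // 2
    return np.arange(start, start + ASCANS_PER_SECTOR) % N_ASCANS


@dataclass(frozen=True)
class SectorizedProfile:
    """48 sector means plus per-sector missing-A-scan bookkeeping.

    ``values[k]`` is NaN when any of the sector's 16 A-scans is missing;
    ``missing_counts[k]`` says how many were.  Missing data propagate to a
    flag rather than being silently imputed — imputation would bias the
    downstream mismatch screen.
    """

    values: np.ndarray
    missing_counts: np.ndarray

    @property
    def is_missing(self) -> np.ndarray:
        return self.missing_counts > 0


def sectorize_rnfl(profile: np.ndarray) -> SectorizedProfile:
    """Average the 768-point RNFL profile into the 48 radial sectors.

    Missing A-scans are encoded as NaN in the input; any sector containing
    one is flagged missing (NaN value) with a count of missing A-scans.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (N_ASCANS,):
        raise ValueError(
            f"RNFL profile must have exactly {N_ASCANS} values, got shape {profile.shape}"
        )
    finite = np.isfinite(profile)
    if np.any(profile[finite] < 0):
        raise ValueError("RNFL thicknesses must be non-negative")
    # reshape trick: roll by half a sector so each sector's 16 scans are contiguous
    rolled = np.roll(profile, ASCANS_PER_SECTOR // 2).reshape(N_SECTORS, ASCANS_PER_SECTOR)
    missing = np.sum(~np.isfinite(rolled), axis=1)
    values = np.where(missing == 0, np.nansum(rolled, axis=1) / ASCANS_PER_SECTOR, np.nan)
    return SectorizedProfile(values=values, missing_counts=missing)


def analysis_angles(grid: SectorGrid | None = None) -> np.ndarray:
    """The 37 analysed sector angles in TSNIT wedge order.

    Runs from 225° through the temporal 0° up to 135°, both endpoints
    inclusive; the excluded 11 angles span the nasal wedge 142.5°–217.5°.
    """
    if grid is None:
        grid = SectorGrid()
    return (WEDGE_START_DEG + np.arange(N_ANALYSIS_SECTORS) * grid.sector_spacing_deg) % 360.0


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Shortest arc between two angles on the circle, degrees in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def _mirror_angles(angles: np.ndarray) -> np.ndarray:
    """Mirror angles about the vertical axis: θ → (180 − θ) mod 360.

    Maps screen-temporal (180° for a left eye in absolute orientation) to 0°
    while fixing superior (90°) and inferior (270°)."""
    return (180.0 - np.asarray(angles, dtype=float)) % 360.0


def normalize_laterality(
    data: np.ndarray,
    laterality: str,
    input_convention: str = "tsnit",
    data_kind: str = "angles",
) -> np.ndarray:
    """Bring angles or profiles into TSNIT / right-eye format.

    Device-native exports are already TSNIT-ordered for both eyes, so
    ``input_convention="tsnit"`` is the identity.  For data recorded in
    absolute screen orientation (``"absolute-clockwise"``) a left eye is
    mirrored about the vertical axis so temporal maps to 0°.

    Parameters
    ----------
    data_kind:
        ``"angles"`` (array of degrees), ``"profile"`` (768-point RNFL
        profile) or ``"sectors"`` (48 sector values).
    """
    laterality = laterality.lower()
    if laterality not in ("right", "left", "od", "os"):
        raise ValueError(f"unknown laterality {laterality!r}")
    if input_convention not in ("tsnit", "absolute-clockwise"):
        raise ValueError(f"unknown input convention {input_convention!r}")
    if data_kind not in ("angles", "profile", "sectors"):
        raise ValueError(f"unknown data kind {data_kind!r}")
    data = np.asarray(data, dtype=float)
    if input_convention == "tsnit" or laterality in ("right", "od"):
        return data.copy()
    # absolute orientation, left eye: mirror about the vertical axis
    if data_kind == "angles":
        return _mirror_angles(data)
    if data_kind == "profile":
        idx = (N_ASCANS // 2 - np.arange(N_ASCANS)) % N_ASCANS
    else:
        idx = (N_SECTORS // 2 - np.arange(N_SECTORS)) % N_SECTORS
    return data[idx]


class SectorAverager(BaseEstimator, TransformerMixin):
    """Transformer mapping 768-point RNFL profiles to 48 sector means.

    Rows of ``X`` are per-eye circumpapillary profiles in µm; the transform
    averages each into the 48 radial sectors (NaN where a sector contains a
    missing A-scan).  Stateless apart from the grid; ``fit`` only validates.
    """

    def __init__(self, grid: SectorGrid | None = None):
        self.grid = grid

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        if X.shape[1] != N_ASCANS:
            raise ValueError(f"X must have {N_ASCANS} columns, got {X.shape[1]}")
        self.grid_ = self.grid if self.grid is not None else SectorGrid()
        self.n_features_in_ = N_ASCANS
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "grid_")
        X = check_array(X, ensure_all_finite="allow-nan")
        if X.shape[1] != N_ASCANS:
            raise ValueError(f"X must have {N_ASCANS} columns, got {X.shape[1]}")
        return np.vstack([sectorize_rnfl(row).values for row in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        grid = getattr(self, "grid_", None) or SectorGrid()
        return np.array([f"sector_{a:g}deg" for a in grid.sector_angles])
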