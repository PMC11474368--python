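"""Two-stage screen identifying true RNFL / BMO-MRW sector mismatches.

Stage 1 sorts each analysed sector's paired (RNFL, BMO-MRW) values into four
groups by fixed numeric cutoffs — group 1 (RNFL ≥65 µm, MRW ≥130 µm),
group 2 (RNFL ≤50, MRW ≥130), group 3 (RNFL ≤50, MRW ≤100), group 4
(RNFL ≥65, MRW ≤100); values inside the open gaps (50, 65) or (100, 130)
stay ungrouped.  Only the discordant groups 2 and 4 proceed to stage 2,
which confirms a *true mismatch* when the low member of the pair is below
the 1st normative percentile (red on the TSNIT curve) while its counterpart
is above it (yellow or green).  Sectors where both members sit below the
1st percentile — plausibly both at the measurement floor — are by design
never called mismatches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import geometry
from .geometry import SectorGrid, sectorize_rnfl
from .normative import NormativeBands, PercentileClass, build_default_bands, classify

__all__ = [
    "ScreenGroup",
    "MismatchType",
    "Cutoffs",
    "DEFAULT_CUTOFFS",
    "MismatchRecord",
    "ScreenResult",
    "stage1_group",
    "stage2_confirm",
    "screen_eye",
    "TwoStageMismatchScreen",
]


class ScreenGroup(enum.Enum):
    G1_bothHigh = "G1"
    G2_highMRW_lowRNFL = "G2"
    G3_bothLow = "G3"
    G4_highRNFL_lowMRW = "G4"
    UNGROUPED = "ungrouped"


class MismatchType(enum.Enum):
    HIGH_MRW_LOW_RNFL = "high_mrw_low_rnfl"
    HIGH_RNFL_LOW_MRW = "high_rnfl_low_mrw"


@dataclass(frozen=True)
class Cutoffs:
    """Stage-1 numeric cutoffs in µm."""

    rnfl_high: float = 65.0
    rnfl_low: float = 50.0
    mrw_high: float = 130.0
    mrw_low: float = 100.0

    def __post_init__(self) -> None:
        if not (self.rnfl_low < self.rnfl_high and self.mrw_low < self.mrw_high):
            raise ValueError("low cutoffs must be below high cutoffs")


DEFAULT_CUTOFFS = Cutoffs()


def stage1_group(rnfl_um: float, mrw_um: float, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> ScreenGroup:
    """Sort one sector's paired values into the four stage-1 groups.

    Values inside the indeterminate bands — RNFL in (50, 65) or MRW in
    (100, 130) µm — belong to no group and are never mismatch candidates.
    """
    if not (np.isfinite(rnfl_um) and np.isfinite(mrw_um)):
        raise ValueError("stage-1 grouping requires finite sector values")
    if rnfl_um < 0 or mrw_um < 0:
        raise ValueError("thicknesses must be non-negative")
    rnfl_high = rnfl_um >= cutoffs.rnfl_high
    rnfl_low = rnfl_um <= cutoffs.rnfl_low
    mrw_high = mrw_um >= cutoffs.mrw_high
    mrw_low = mrw_um <= cutoffs.mrw_low
    if rnfl_high and mrw_high:
        return ScreenGroup.G1_bothHigh
    if rnfl_low and mrw_high:
        return ScreenGroup.G2_highMRW_lowRNFL
    if rnfl_low and mrw_low:
        return ScreenGroup.G3_bothLow
    if rnfl_high and mrw_low:
        return ScreenGroup.G4_highRNFL_lowMRW
    return ScreenGroup.UNGROUPED


def stage2_confirm(
    group: ScreenGroup,
    rnfl_class: PercentileClass,
    mrw_class: PercentileClass,
) -> MismatchType | None:
    """Confirm a stage-1 candidate against the normative percentile classes.

    Group 2 confirms as HIGH_MRW_LOW_RNFL iff the RNFL is red (< 1st
    percentile) while the MRW is not; group 4 confirms as HIGH_RNFL_LOW_MRW
    iff the MRW is red while the RNFL is not.  Anything else — including
    both red — is not a mismatch.  Only groups 2 and 4 ever reach stage 2.
    """
    if group is ScreenGroup.G2_highMRW_lowRNFL:
        if rnfl_class is PercentileClass.RED and mrw_class is not PercentileClass.RED:
            return MismatchType.HIGH_MRW_LOW_RNFL
        return None
    if group is ScreenGroup.G4_highRNFL_lowMRW:
        if mrw_class is PercentileClass.RED and rnfl_class is not PercentileClass.RED:
            return MismatchType.HIGH_RNFL_LOW_MRW
        return None
    raise ValueError(f"stage 2 applies only to groups 2 and 4, got {group}")


@dataclass(frozen=True)
class MismatchRecord:
    """One sector flagged as a true mismatch by the two-stage screen."""

    eye_id: str
    angle_deg: float
    type: MismatchType
    rnfl_um: float
    mrw_um: float
    stage1_group: ScreenGroup
    rnfl_class: PercentileClass
    mrw_class: PercentileClass


@dataclass
class ScreenResult:
    """Per-eye screen output: mismatch records plus stage-1 bookkeeping."""

    eye_id: str
    records: list[MismatchRecord]
    group_counts: dict[ScreenGroup, int]
    n_missing: int
    screened_angles: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def screen_eye(
    eye,
    bands_rnfl: NormativeBands,
    bands_mrw: NormativeBands,
    grid: SectorGrid | None = None,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> ScreenResult:
    """Run the full two-stage screen on one eye.

    Sectorises the 768-point RNFL profile, restricts to the 37 analysed
    sectors, applies stage 1 then stage 2 per sector.  Sectors with a missing
    RNFL A-scan or MRW cut are excluded and counted, not imputed.  Records
    come back sorted by ascending angle.
    """
    if grid is None:
        grid = SectorGrid()
    rnfl_sectors = sectorize_rnfl(np.asarray(eye.rnfl_profile, dtype=float))
    mrw = np.asarray(eye.mrw_sectors, dtype=float)
    if mrw.shape != (geometry.N_SECTORS,):
        raise ValueError(f"mrw_sectors must have {geometry.N_SECTORS} values, got {mrw.shape}")
    age = getattr(eye, "age", None)

    records: list[MismatchRecord] = []
    group_counts: dict[ScreenGroup, int] = {g: 0 for g in ScreenGroup}
    n_missing = 0
    screened: list[float] = []
    sector_angles = grid.sector_angles
    for angle in grid.analysis_angles:
        k = int(np.argmin(np.abs(sector_angles - angle)))
        r, m = rnfl_sectors.values[k], mrw[k]
        if not (np.isfinite(r) and np.isfinite(m)):
            n_missing += 1
            continue
        screened.append(float(angle))
        group = stage1_group(r, m, cutoffs)
        group_counts[group] += 1
        if group in (ScreenGroup.G2_highMRW_lowRNFL, ScreenGroup.G4_highRNFL_lowMRW):
            r_class = classify(r, angle, bands_rnfl, age)
            m_class = classify(m, angle, bands_mrw, age)
            mtype = stage2_confirm(group, r_class, m_class)
            if mtype is not None:
                records.append(
                    MismatchRecord(
                        eye_id=str(eye.eye_id),
                        angle_deg=float(angle),
                        type=mtype,
                        rnfl_um=float(r),
                        mrw_um=float(m),
                        stage1_group=group,
                        rnfl_class=r_class,
                        mrw_class=m_class,
                    )
                )
    records.sort(key=lambda rec: rec.angle_deg)
    return ScreenResult(
        eye_id=str(eye.eye_id),
        records=records,
        group_counts=group_counts,
        n_missing=n_missing,
        screened_angles=screened,
    )


class TwoStageMismatchScreen(BaseEstimator):
    """Sklearn-style predictor wrapping the two-stage mismatch screen.

    ``X`` has one row per sector with columns ``(angle_deg, rnfl_um, mrw_um)``
    or ``(angle_deg, rnfl_um, mrw_um, age_years)``; ``predict`` returns the
    mismatch label per row: ``"none"``, ``"high_mrw_low_rnfl"`` or
    ``"high_rnfl_low_mrw"``.  Band objects default to the parametric
    normative stand-ins.
    """

    def __init__(
        self,
        bands_rnfl: NormativeBands | None = None,
        bands_mrw: NormativeBands | None = None,
        rnfl_high: float = 65.0,
        rnfl_low: float = 50.0,
        mrw_high: float = 130.0,
        mrw_low: float = 100.0,
    ):
        self.bands_rnfl = bands_rnfl
        self.bands_mrw = bands_mrw
        self.rnfl_high = rnfl_high
        self.rnfl_low = rnfl_low
        self.mrw_high = mrw_high
        self.mrw_low = mrw_low

    def fit(self, X=None, y=None):
        """Resolve bands and cutoffs; the screen itself has no free parameters."""
        self.cutoffs_ = Cutoffs(
            rnfl_high=self.rnfl_high,
            rnfl_low=self.rnfl_low,
            mrw_high=self.mrw_high,
            mrw_low=self.mrw_low,
        )
        self.bands_rnfl_ = self.bands_rnfl or build_default_bands("RNFL")
        self.bands_mrw_ = self.bands_mrw or build_default_bands("BMO_MRW")
        if X is not None:
            self._validate(X)
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = check_array(X, ensure_all_finite=True)
        if X.shape[1] not in (3, 4):
            raise ValueError(
                "X must have columns (angle_deg, rnfl_um, mrw_um[, age_years]), "
                f"got {X.shape[1]} columns"
            )
        return X

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoffs_")
        X = self._validate(X)
        labels = np.empty(len(X), dtype=object)
        for i, row in enumerate(X):
            angle, r, m = row[0], row[1], row[2]
            age = row[3] if len(row) == 4 else None
            group = stage1_group(r, m, self.cutoffs_)
            if group in (ScreenGroup.G2_highMRW_lowRNFL, ScreenGroup.G4_highRNFL_lowMRW):
                mtype = stage2_confirm(
                    group,
                    classify(r, angle, self.bands_rnfl_, age),
                    classify(m, angle, self.bands_mrw_, age),
                )
                labels[i] = mtype.value if mtype is not None else "none"
            else:
                labels[i] = "none"
        return labels
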