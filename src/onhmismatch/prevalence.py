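"""Cohort-level prevalence mapping of mismatch records.

Aggregates per-sector mismatch records into per-angle counts and
within-type fractions over the 37 analysed angles (the polar-chart view),
locates peak angles, and summarises same-eye co-occurrence of the two
mismatch types including the minimum circular separation between them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SectorGrid, circular_distance
from .screening import MismatchRecord, MismatchType

__all__ = [
    "PrevalenceMap",
    "CooccurrenceSummary",
    "build_prevalence",
    "peak_angles",
    "cooccurrence",
    "plot_polar",
]


@dataclass(frozen=True)
class PrevalenceMap:
    """Per-angle mismatch counts and within-type fractions over a cohort.

    ``angles_deg`` follows TSNIT wedge order (225° … 135° through temporal
    0°); ``total_sectors`` is eyes × 37, the denominator for rate-of-total
    percentages.
    """

    angles_deg: np.ndarray
    counts: dict[MismatchType, np.ndarray]
    cohort_size: int

    @property
    def totals(self) -> dict[MismatchType, int]:
        return {t: int(c.sum()) for t, c in self.counts.items()}

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    @property
    def total_sectors(self) -> int:
        return self.cohort_size * len(self.angles_deg)

    def fraction_of_type(self, mtype: MismatchType) -> np.ndarray:
        """Per-angle count ÷ that type's total (zeros if the type is absent)."""
        total = self.totals[mtype]
        if total == 0:
            return np.zeros_like(self.counts[mtype], dtype=float)
        return self.counts[mtype] / total

    def rate_of_total(self) -> float:
        """Overall mismatch rate: mismatched sectors / all analysed sectors."""
        if self.total_sectors == 0:
            return 0.0
        return self.grand_total / self.total_sectors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angles_deg,
                "count_high_mrw_low_rnfl": self.counts[MismatchType.HIGH_MRW_LOW_RNFL],
                "count_high_rnfl_low_mrw": self.counts[MismatchType.HIGH_RNFL_LOW_MRW],
                "frac_high_mrw_low_rnfl": self.fraction_of_type(MismatchType.HIGH_MRW_LOW_RNFL),
                "frac_high_rnfl_low_mrw": self.fraction_of_type(MismatchType.HIGH_RNFL_LOW_MRW),
            }
        )


def build_prevalence(
    records: list[MismatchRecord],
    cohort_size: int,
    grid: SectorGrid | None = None,
) -> PrevalenceMap:
    """Count mismatch records per analysed angle over a cohort of eyes."""
    if grid is None:
        grid = SectorGrid()
    angles = grid.analysis_angles
    index = {float(a): i for i, a in enumerate(angles)}
    counts = {t: np.zeros(len(angles), dtype=int) for t in MismatchType}
    for rec in records:
        key = float(rec.angle_deg % 360.0)
        if key not in index:
            raise ValueError(
                f"record angle {rec.angle_deg}° (eye {rec.eye_id}) is not an analysed sector angle"
            )
        counts[rec.type][index[key]] += 1
    return PrevalenceMap(angles_deg=angles, counts=counts, cohort_size=int(cohort_size))


def peak_angles(pmap: PrevalenceMap, mtype: MismatchType) -> list[tuple[float, float]]:
    """Angles achieving the maximal within-type fraction, ties in TSNIT order.

    Returns ``[(angle_deg, fraction_of_type), ...]``; empty if the type has
    no records.
    """
    if pmap.totals[mtype] == 0:
        return []
    frac = pmap.fraction_of_type(mtype)
    best = frac.max()
    return [
        (float(a), float(f))
        for a, f in zip(pmap.angles_deg, frac)
        if np.isclose(f, best)
    ]


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Same-eye co-occurrence of the two mismatch types."""

    n_dual_eyes: int
    n_sectors_in_dual_eyes: int
    share_of_all_mismatches: float
    min_separation_deg: float | None
    per_eye_min_separation_deg: dict[str, float]


def cooccurrence(records: list[MismatchRecord]) -> CooccurrenceSummary:
    """Pair opposite-type records within each eye and measure separations.

    Separation is the shortest circular arc between an eye's
    HIGH_MRW_LOW_RNFL and HIGH_RNFL_LOW_MRW sectors (wrapping through 0°).
    The sector count covers all mismatch sectors in dual-type eyes, reported
    also as a share of all mismatch sectors.
    """
    by_eye: dict[str, dict[MismatchType, list[float]]] = defaultdict(
        lambda: {t: [] for t in MismatchType}
    )
    for rec in records:
        by_eye[rec.eye_id][rec.type].append(rec.angle_deg)
    per_eye_min: dict[str, float] = {}
    n_dual_sectors = 0
    for eye_id, angles in by_eye.items():
        a = angles[MismatchType.HIGH_MRW_LOW_RNFL]
        b = angles[MismatchType.HIGH_RNFL_LOW_MRW]
        if a and b:
            seps = [float(circular_distance(x, y)) for x in a for y in b]
            per_eye_min[eye_id] = min(seps)
            n_dual_sectors += len(a) + len(b)
    total = len(records)
    return CooccurrenceSummary(
        n_dual_eyes=len(per_eye_min),
        n_sectors_in_dual_eyes=n_dual_sectors,
        share_of_all_mismatches=(n_dual_sectors / total) if total else 0.0,
        min_separation_deg=min(per_eye_min.values()) if per_eye_min else None,
        per_eye_min_separation_deg=per_eye_min,
    )


def plot_polar(pmap: PrevalenceMap, mtype: MismatchType, ax=None):
    """Optional polar-chart rendering of one mismatch type's distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(pmap.angles_deg)
    ax.bar(theta, pmap.counts[mtype], width=np.radians(7.5), alpha=0.7)
    ax.set_theta_zero_location("E")
    ax.set_title(mtype.value)
    return ax
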