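"""Cause attribution of mismatch records.

Joins mismatch records to per-sector cause annotations (large vessel, small
vessel, retinoschisis, outer-retinal-layer inclusion, other) and
cross-tabulates counts and row percentages by mismatch type.  Cause
determination itself is a qualitative image review and is *not* automated
here: the module's contract is bookkeeping over an annotation table, with
synthetic ground truth standing in for the reviewer in tests.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .screening import MismatchRecord, MismatchType

__all__ = [
    "Cause",
    "CauseAnnotation",
    "AttributionTable",
    "attribute",
    "attribution_from_counts",
    "format_report",
]

logger = logging.getLogger(__name__)


class Cause(enum.Enum):
    LARGE_VESSEL = "large_vessel"
    SMALL_VESSEL = "small_vessel"
    RETINOSCHISIS = "retinoschisis"
    OUTER_RETINA_INCLUSION = "outer_retina_inclusion"
    OTHER = "other"


#: Causes folded into the "Other" column of the 3-column table view.
_OTHER_FOLD = (Cause.RETINOSCHISIS, Cause.OUTER_RETINA_INCLUSION, Cause.OTHER)


@dataclass(frozen=True)
class CauseAnnotation:
    """Reviewer-assigned cause for one (eye, angle) mismatch sector."""

    eye_id: str
    angle_deg: float
    cause: Cause


@dataclass(frozen=True)
class AttributionTable:
    """Mismatch type × cause cross-tabulation.

    ``counts`` has one row per mismatch type and one column per detailed
    cause; :meth:`folded` collapses retinoschisis and outer-retina inclusion
    into "other", the 3-column published view.
    """

    counts: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def folded(self) -> pd.DataFrame:
        """3-column view: large vessels, small vessels, other."""
        out = pd.DataFrame(index=self.counts.index)
        out["large_vessel"] = self.counts[Cause.LARGE_VESSEL.value]
        out["small_vessel"] = self.counts[Cause.SMALL_VESSEL.value]
        out["other"] = self.counts[[c.value for c in _OTHER_FOLD]].sum(axis=1)
        return out

    def percentages(self, folded: bool = True, decimals: int = 1) -> pd.DataFrame:
        """Row percentages (of each mismatch type's total), one decimal."""
        table = self.folded() if folded else self.counts
        totals = table.sum(axis=1)
        pct = table.div(totals.where(totals > 0, other=1), axis=0) * 100.0
        return pct.round(decimals)

    def within_other_share(self, cause: Cause, mtype: MismatchType, decimals: int = 1) -> float:
        """A detailed cause's percentage share of the folded "other" column."""
        other_total = int(self.folded().loc[mtype.value, "other"])
        if other_total == 0:
            return 0.0
        part = int(self.counts.loc[mtype.value, cause.value])
        return round(100.0 * part / other_total, decimals)


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(
        0,
        index=[t.value for t in MismatchType],
        columns=[c.value for c in Cause],
        dtype=int,
    )


def attribute(
    records: list[MismatchRecord],
    annotations: list[CauseAnnotation],
) -> AttributionTable:
    """Cross-tabulate mismatch records by annotated cause.

    Records without an annotation fall into OTHER with a logged warning;
    annotations that reference no record are ignored with a warning.
    """
    lookup: dict[tuple[str, float], Cause] = {}
    for ann in annotations:
        lookup[(str(ann.eye_id), float(ann.angle_deg % 360.0))] = ann.cause
    counts = _empty_counts()
    matched: set[tuple[str, float]] = set()
    for rec in records:
        key = (str(rec.eye_id), float(rec.angle_deg % 360.0))
        cause = lookup.get(key)
        if cause is None:
            logger.warning("mismatch record %s@%g° has no cause annotation; counted as OTHER", *key)
            cause = Cause.OTHER
        else:
            matched.add(key)
        counts.loc[rec.type.value, cause.value] += 1
    for key in set(lookup) - matched:
        logger.warning("annotation %s@%g° matches no mismatch record; ignored", *key)
    return AttributionTable(counts=counts)


def attribution_from_counts(counts: dict[MismatchType, dict[Cause, int]]) -> AttributionTable:
    """Build a table directly from published or tallied counts."""
    table = _empty_counts()
    for mtype, row in counts.items():
        for cause, n in row.items():
            if n < 0:
                raise ValueError("counts must be non-negative")
            table.loc[mtype.value, cause.value] = int(n)
    return AttributionTable(counts=table)


def format_report(table: AttributionTable) -> str:
    """Aligned-text report of the folded counts with row percentages."""
    folded = table.folded()
    pct = table.percentages(folded=True)
    lines = [f"{'Mismatch type':<24}{'Large vessels':>16}{'Small vessels':>16}{'Other':>14}{'Total':>8}"]
    for row in folded.index:
        cells = [
            f"{folded.loc[row, c]} ({pct.loc[row, c]:.1f}%)"
            for c in ("large_vessel", "small_vessel", "other")
        ]
        lines.append(
            f"{row:<24}{cells[0]:>16}{cells[1]:>16}{cells[2]:>14}{int(folded.loc[row].sum()):>8}"
        )
    return "\n".join(lines)
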