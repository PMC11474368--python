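"""Delimited-text readers/writers, QC filtering and the pipeline driver.

The interchange format is plain CSV (UTF-8, header row, dot decimal): a
cohort is a directory with a ``manifest.csv`` plus per-eye profile files,
and every downstream product (mismatch records, prevalence table,
attribution table, truth tables) round-trips through CSV.  Schema
violations raise with the offending file and row rather than being
silently coerced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    AttributionTable,
    Cause,
    CauseAnnotation,
    attribute,
    format_report,
)
from .geometry import N_ASCANS, N_SECTORS, SectorGrid, normalize_laterality
from .normative import NormativeBands, build_default_bands, load_bands, save_bands
from .prevalence import build_prevalence, cooccurrence, peak_angles
from .normative import PercentileClass
from .screening import (
    MismatchRecord,
    MismatchType,
    ScreenGroup,
    screen_eye,
)
from .synthetic import (
    Artifact,
    ArtifactKind,
    CohortConfig,
    EyeRecord,
    SyntheticTruth,
    annotations_from_truth,
    evaluate_recovery,
    generate_cohort,
)

__all__ = [
    "QcRule",
    "FormatError",
    "apply_qc",
    "save_cohort",
    "load_cohort",
    "save_truth",
    "load_truth",
    "save_records",
    "load_records",
    "save_annotations",
    "load_annotations",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_MANIFEST_COLUMNS = [
    "eye_id",
    "patient_id",
    "laterality",
    "age",
    "bmo_area",
    "quality_factor",
    "missing_fraction",
]


class FormatError(ValueError):
    """A delimited-text file violates its documented schema."""


@dataclass(frozen=True)
class QcRule:
    """Session-level quality control: reject iff QF < 15 or missing > 10%.

    Rejection drops both the RNFL and the BMO-MRW data for the session —
    the two parameters come from the same volume scan.
    """

    min_quality_factor: float = 15.0
    max_missing_fraction: float = 0.10


def apply_qc(eyes: list[EyeRecord], rule: QcRule | None = None) -> tuple[list[EyeRecord], list[tuple[EyeRecord, str]]]:
    """Split a cohort into QC-passing eyes and rejects with reasons.

    An eye is rejected iff ``quality_factor < min`` (strictly) or
    ``missing_fraction > max`` (strictly); the printed boundaries
    (QF = 15.0, missing = 10%) are kept.
    """
    if rule is None:
        rule = QcRule()
    kept: list[EyeRecord] = []
    rejected: list[tuple[EyeRecord, str]] = []
    for eye in eyes:
        if eye.quality_factor is None or eye.missing_fraction is None or not (
            np.isfinite(eye.quality_factor) and np.isfinite(eye.missing_fraction)
        ):
            rejected.append((eye, "no QC metadata"))
        elif eye.quality_factor < rule.min_quality_factor:
            rejected.append((eye, f"quality factor {eye.quality_factor:.1f} < {rule.min_quality_factor:g}"))
        elif eye.missing_fraction > rule.max_missing_fraction:
            rejected.append((eye, f"missing fraction {eye.missing_fraction:.2f} > {rule.max_missing_fraction:g}"))
        else:
            kept.append(eye)
    return kept, rejected


def save_cohort(eyes: list[EyeRecord], path: str | Path) -> None:
    """Write a cohort directory: manifest.csv + per-eye RNFL/MRW files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "eye_id": e.eye_id,
                "patient_id": e.patient_id,
                "laterality": e.laterality,
                "age": e.age,
                "bmo_area": e.bmo_area,
                "quality_factor": e.quality_factor,
                "missing_fraction": e.missing_fraction,
            }
            for e in eyes
        ]
    ).to_csv(path / "manifest.csv", index=False)
    grid = SectorGrid()
    for e in eyes:
        pd.DataFrame(
            {"ascan_index": np.arange(N_ASCANS), "thickness_um": e.rnfl_profile}
        ).to_csv(path / f"{e.eye_id}_rnfl.csv", index=False)
        pd.DataFrame(
            {"angle_deg": grid.sector_angles, "thickness_um": e.mrw_sectors}
        ).to_csv(path / f"{e.eye_id}_mrw.csv", index=False)


def _read_profile(path: Path, column: str, expected_len: int) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if column not in df.columns or "thickness_um" not in df.columns:
        raise FormatError(f"{path}: expected columns [{column}, thickness_um], got {list(df.columns)}")
    if len(df) != expected_len:
        raise FormatError(f"{path}: expected {expected_len} rows, found {len(df)}")
    values = pd.to_numeric(df["thickness_um"], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values) & df["thickness_um"].notna().to_numpy())[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric thickness at data row {bad[0] + 1}")
    return values


def load_cohort(path: str | Path, input_convention: str = "tsnit") -> list[EyeRecord]:
    """Load a cohort directory written by :func:`save_cohort`.

    Left-eye data recorded in absolute screen orientation are mirrored into
    right-eye TSNIT format on load; device-native TSNIT exports pass
    through unchanged.
    """
    path = Path(path)
    manifest_path = path / "manifest.csv"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path} not found")
    manifest = pd.read_csv(manifest_path)
    missing_cols = set(_MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise FormatError(f"{manifest_path}: missing columns {sorted(missing_cols)}")
    eyes = []
    for i, row in manifest.iterrows():
        eye_id = str(row["eye_id"])
        rnfl = _read_profile(path / f"{eye_id}_rnfl.csv", "ascan_index", N_ASCANS)
        mrw = _read_profile(path / f"{eye_id}_mrw.csv", "angle_deg", N_SECTORS)
        laterality = str(row["laterality"]).lower()
        rnfl = normalize_laterality(rnfl, laterality, input_convention, data_kind="profile")
        mrw = normalize_laterality(mrw, laterality, input_convention, data_kind="sectors")
        try:
            eyes.append(
                EyeRecord(
                    eye_id=eye_id,
                    patient_id=str(row["patient_id"]),
                    laterality=laterality,
                    age=float(row["age"]),
                    rnfl_profile=rnfl,
                    mrw_sectors=mrw,
                    bmo_area=float(row["bmo_area"]),
                    quality_factor=float(row["quality_factor"]),
                    missing_fraction=float(row["missing_fraction"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{manifest_path} row {i + 2}: {exc}") from exc
    return eyes


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the ground-truth artifact and expected-mismatch tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "eye_id": eye_id,
                "angle_deg": a.angle_deg,
                "kind": a.kind.value,
                "magnitude_um": a.magnitude_um,
                "offset_deg": a.offset_deg,
                "sigma_deg": a.sigma_deg,
            }
            for eye_id, arts in truth.artifacts.items()
            for a in arts
        ]
    ).to_csv(path / "truth_artifacts.csv", index=False)
    pd.DataFrame(
        [
            {"eye_id": eye_id, "angle_deg": angle, "expected_type": mtype.value}
            for eye_id, labels in truth.expected.items()
            for angle, mtype in labels.items()
        ]
    ).to_csv(path / "truth_expected.csv", index=False)


def load_truth(path: str | Path) -> SyntheticTruth:
    path = Path(path)
    arts_df = pd.read_csv(path / "truth_artifacts.csv")
    exp_df = pd.read_csv(path / "truth_expected.csv")
    truth = SyntheticTruth(artifacts={})
    for _, row in arts_df.iterrows():
        truth.artifacts.setdefault(str(row["eye_id"]), []).append(
            Artifact(
                kind=ArtifactKind(row["kind"]),
                angle_deg=float(row["angle_deg"]),
                magnitude_um=float(row["magnitude_um"]),
                offset_deg=float(row["offset_deg"]),
                sigma_deg=float(row["sigma_deg"]),
            )
        )
    for eye_id in truth.artifacts:
        truth.expected.setdefault(eye_id, {})
    for _, row in exp_df.iterrows():
        truth.expected.setdefault(str(row["eye_id"]), {})[float(row["angle_deg"])] = MismatchType(
            row["expected_type"]
        )
    return truth


_RECORD_COLUMNS = [
    "eye_id",
    "angle_deg",
    "type",
    "rnfl_um",
    "mrw_um",
    "stage1_group",
    "rnfl_class",
    "mrw_class",
]


def save_records(records: list[MismatchRecord], path: str | Path) -> None:
    """Write mismatch records as delimited text."""
    pd.DataFrame(
        [
            {
                "eye_id": r.eye_id,
                "angle_deg": r.angle_deg,
                "type": r.type.value,
                "rnfl_um": r.rnfl_um,
                "mrw_um": r.mrw_um,
                "stage1_group": r.stage1_group.value,
                "rnfl_class": r.rnfl_class.value,
                "mrw_class": r.mrw_class.value,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    ).to_csv(path, index=False)


def load_records(path: str | Path) -> list[MismatchRecord]:
    df = pd.read_csv(path)
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    group_by_value = {g.value: g for g in ScreenGroup}
    return [
        MismatchRecord(
            eye_id=str(row["eye_id"]),
            angle_deg=float(row["angle_deg"]),
            type=MismatchType(row["type"]),
            rnfl_um=float(row["rnfl_um"]),
            mrw_um=float(row["mrw_um"]),
            stage1_group=group_by_value[row["stage1_group"]],
            rnfl_class=PercentileClass(row["rnfl_class"]),
            mrw_class=PercentileClass(row["mrw_class"]),
        )
        for _, row in df.iterrows()
    ]


def save_annotations(annotations: list[CauseAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"eye_id": a.eye_id, "angle_deg": a.angle_deg, "cause": a.cause.value} for a in annotations],
        columns=["eye_id", "angle_deg", "cause"],
    ).to_csv(path, index=False)


def load_annotations(path: str | Path) -> list[CauseAnnotation]:
    df = pd.read_csv(path)
    missing = {"eye_id", "angle_deg", "cause"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        CauseAnnotation(eye_id=str(row["eye_id"]), angle_deg=float(row["angle_deg"]), cause=Cause(row["cause"]))
        for _, row in df.iterrows()
    ]


def _resolve_bands(config: dict, parameter: str, key: str) -> NormativeBands:
    spec = config.get(key)
    if spec is None:
        bands = build_default_bands(parameter)
        logger.info("no %s configured; using default parametric bands (%s)", key, bands.provenance)
        return bands
    return load_bands(spec, parameter=parameter)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run simulate/load → QC → screen → prevalence → attribution end to end.

    ``config`` keys (all optional): ``seed``, ``cohort_dir`` (load instead of
    simulate), ``simulate`` (CohortConfig field overrides), ``bands_rnfl`` /
    ``bands_mrw`` (CSV paths), ``qc`` ({min_quality_factor,
    max_missing_fraction}), ``annotations`` (CSV path).  Writes all products
    plus a machine-readable ``report.json`` (with seed and version) under
    ``outdir`` and returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    grid = SectorGrid()

    truth = None
    if "cohort_dir" in config:
        eyes = load_cohort(config["cohort_dir"], config.get("input_convention", "tsnit"))
    else:
        sim_cfg = CohortConfig(**config.get("simulate", {}))
        eyes, truth = generate_cohort(sim_cfg, seed=seed)
        save_cohort(eyes, outdir / "cohort")
        save_truth(truth, outdir / "cohort")

    qc_cfg = config.get("qc", {})
    rule = QcRule(
        min_quality_factor=float(qc_cfg.get("min_quality_factor", 15.0)),
        max_missing_fraction=float(qc_cfg.get("max_missing_fraction", 0.10)),
    )
    kept, rejected = apply_qc(eyes, rule)
    for eye, reason in rejected:
        logger.warning("QC rejected eye %s: %s", eye.eye_id, reason)
    if not kept:
        logger.warning("no eyes passed QC; writing empty reports")

    bands_rnfl = _resolve_bands(config, "RNFL", "bands_rnfl")
    bands_mrw = _resolve_bands(config, "BMO_MRW", "bands_mrw")
    save_bands(bands_rnfl, outdir / "bands_rnfl.csv")
    save_bands(bands_mrw, outdir / "bands_mrw.csv")

    results = [screen_eye(eye, bands_rnfl, bands_mrw, grid) for eye in kept]
    records = [rec for res in results for rec in res.records]
    save_records(records, outdir / "mismatch_records.csv")

    pmap = build_prevalence(records, cohort_size=len(kept), grid=grid)
    pmap.to_frame().to_csv(outdir / "prevalence.csv", index=False)
    cooc = cooccurrence(records)

    if "annotations" in config:
        annotations = load_annotations(config["annotations"])
    elif truth is not None:
        annotations = annotations_from_truth(truth, records)
    else:
        annotations = []
    save_annotations(annotations, outdir / "annotations.csv")
    table = attribute(records, annotations)
    table.folded().to_csv(outdir / "attribution_counts.csv")
    table.percentages().to_csv(outdir / "attribution_percent.csv")
    (outdir / "attribution_report.txt").write_text(format_report(table) + "\n")

    report = {
        "version": __version__,
        "seed": seed,
        "n_eyes": len(eyes),
        "n_eyes_kept": len(kept),
        "n_eyes_rejected": len(rejected),
        "qc_reasons": [f"{eye.eye_id}: {reason}" for eye, reason in rejected],
        "total_sectors_analyzed": pmap.total_sectors,
        "n_mismatch_sectors": pmap.grand_total,
        "mismatch_rate_percent": round(100.0 * pmap.rate_of_total(), 2),
        "totals_by_type": {t.value: n for t, n in pmap.totals.items()},
        "peak_angles": {
            t.value: peak_angles(pmap, t) for t in MismatchType
        },
        "cooccurrence": {
            "n_dual_eyes": cooc.n_dual_eyes,
            "n_sectors_in_dual_eyes": cooc.n_sectors_in_dual_eyes,
            "share_of_all_mismatches": round(cooc.share_of_all_mismatches, 4),
            "min_separation_deg": cooc.min_separation_deg,
        },
    }
    if truth is not None:
        report["recovery"] = evaluate_recovery(results, truth)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
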