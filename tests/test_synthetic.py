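"""Synthetic cohort generator: determinism, floor model, ground truth."""

import numpy as np
import pytest

from onhmismatch.geometry import DEG_PER_ASCAN, N_ASCANS, SectorGrid, circular_distance, sectorize_rnfl
from onhmismatch.normative import build_default_bands
from onhmismatch.screening import DEFAULT_CUTOFFS, MismatchType, screen_eye
from onhmismatch.synthetic import (
    Artifact,
    ArtifactKind,
    CohortConfig,
    SyntheticTruth,
    _clean_profiles,
    _expected_labels,
    _Wedge,
    annotations_from_truth,
    evaluate_recovery,
    floor_model,
    generate_cohort,
)


def quiet_config(**overrides):
    """No disease, no artifacts, no noise, no missing data."""
    defaults = dict(
        n_eyes=2,
        severity_ranges=((0.0, 0.0),) * 3,
        diffuse_loss_frac=0.0,
        wedge_depth_jitter=0.0,
        large_vessels_per_pole=0,
        extra_large_vessel_rate=0.0,
        small_vessels_per_center=0,
        extra_small_vessel_rate=0.0,
        retinoschisis_rate=0.0,
        outer_retina_rate=0.0,
        rnfl_noise_sd=0.0,
        mrw_noise_sd=0.0,
        missing_prob=0.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_eyes=10)
        eyes1, truth1 = generate_cohort(cfg, seed=5)
        eyes2, truth2 = generate_cohort(cfg, seed=5)
        for a, b in zip(eyes1, eyes2):
            assert np.array_equal(a.rnfl_profile, b.rnfl_profile, equal_nan=True)
            assert np.array_equal(a.mrw_sectors, b.mrw_sectors)
            assert (a.eye_id, a.age, a.quality_factor) == (b.eye_id, b.age, b.quality_factor)
        assert truth1.expected == truth2.expected

    def test_different_seed_differs(self):
        eyes1, _ = generate_cohort(CohortConfig(n_eyes=3), seed=5)
        eyes2, _ = generate_cohort(CohortConfig(n_eyes=3), seed=6)
        assert not np.allclose(eyes1[0].rnfl_profile, eyes2[0].rnfl_profile, equal_nan=True)


class TestFloorModel:
    @pytest.mark.parametrize("parameter", ["RNFL", "BMO_MRW"])
    def test_endpoints(self, parameter):
        cfg = CohortConfig()
        mean = (cfg.rnfl_shape if parameter == "RNFL" else cfg.mrw_shape).mean_level_um
        floor = cfg.rnfl_floor_um if parameter == "RNFL" else cfg.mrw_floor_um
        assert floor_model(0.0, parameter, cfg) == pytest.approx(mean)
        assert floor_model(1.0, parameter, cfg) == pytest.approx(floor)

    @pytest.mark.parametrize("parameter", ["RNFL", "BMO_MRW"])
    def test_monotone_decreasing_on_grid(self, parameter):
        sev = np.linspace(0, 1, 101)
        values = floor_model(sev, parameter)
        assert np.all(np.diff(values) < 0)

    def test_severity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            floor_model(1.2, "RNFL")
        with pytest.raises(ValueError):
            floor_model(-0.1, "RNFL")

    def test_mrw_approaches_floor_faster_than_rnfl(self):
        """Relative residual above the floor at mid severity is smaller for
        the rim than for the RNFL (distinct effective floor dynamics)."""
        cfg = CohortConfig()
        rel = lambda p, mean, floor: (floor_model(0.5, p, cfg) - floor) / (mean - floor)
        assert rel("BMO_MRW", cfg.mrw_shape.mean_level_um, cfg.mrw_floor_um) < rel(
            "RNFL", cfg.rnfl_shape.mean_level_um, cfg.rnfl_floor_um
        )


class TestGroundTruth:
    def test_quiet_cohort_screens_clean(self, bands_rnfl, bands_mrw, grid):
        eyes, truth = generate_cohort(quiet_config(), seed=3)
        assert truth.n_expected() == 0
        for eye in eyes:
            assert screen_eye(eye, bands_rnfl, bands_mrw, grid).records == []

    def test_single_small_vessel_on_deep_wedge_gives_one_mismatch_at_45(self):
        """One small vessel at 45° atop a deep superotemporal wedge must
        produce exactly one high-MRW/low-RNFL truth label, at 45°."""
        cfg = CohortConfig()
        wedges = [_Wedge(center_deg=60.0, core_half_width_deg=30.0, taper_deg=10.0, depth=1.0)]
        artifacts = [
            Artifact(kind=ArtifactKind.SMALL_VESSEL, angle_deg=45.0, magnitude_um=180.0, sigma_deg=6.0)
        ]
        clean_rnfl, clean_mrw = _clean_profiles(cfg, wedges, artifacts)
        labels = _expected_labels(
            sectorize_rnfl(clean_rnfl).values,
            clean_mrw,
            65.0,
            build_default_bands("RNFL"),
            build_default_bands("BMO_MRW"),
            DEFAULT_CUTOFFS,
            SectorGrid(),
        )
        assert labels == {45.0: MismatchType.HIGH_MRW_LOW_RNFL}

    def test_truth_labels_rederivable_from_clean_sectors(self, small_cohort, bands_rnfl, bands_mrw, grid):
        """Expected labels are a deterministic function of the stored clean
        sector values, the eye's age and the bands."""
        eyes, truth = small_cohort
        ages = {e.eye_id: e.age for e in eyes}
        for eye_id, expected in truth.expected.items():
            labels = _expected_labels(
                truth.clean_rnfl_sectors[eye_id],
                truth.clean_mrw_sectors[eye_id],
                ages[eye_id],
                bands_rnfl,
                bands_mrw,
                DEFAULT_CUTOFFS,
                grid,
            )
            assert labels == expected


class TestRecovery:
    def test_pipeline_recovers_truth_at_default_noise(self, screened_small_cohort):
        kept, truth, results = screened_small_cohort
        m = evaluate_recovery(results, truth)
        assert m["n_truth_positive"] > 10
        assert m["sensitivity"] >= 0.95
        assert m["false_positive_rate"] < 0.01

    def test_error_rate_is_noise_monotone(self, bands_rnfl, bands_mrw, grid):
        def errors(rnfl_sd, mrw_sd):
            cfg = CohortConfig(n_eyes=40, rnfl_noise_sd=rnfl_sd, mrw_noise_sd=mrw_sd, missing_prob=0.0)
            eyes, truth = generate_cohort(cfg, seed=9)
            results = [screen_eye(e, bands_rnfl, bands_mrw, grid) for e in eyes]
            m = evaluate_recovery(results, truth)
            return m["false_negatives"] + m["false_positives"]

        assert errors(0.0, 0.0) == 0
        assert errors(2.0, 3.0) <= errors(10.0, 15.0)

    def test_summary_statistics_stable_across_seeds(self, bands_rnfl, bands_mrw, grid):
        totals = []
        for seed in (11, 12, 13, 14):
            eyes, _ = generate_cohort(CohortConfig(n_eyes=50), seed=seed)
            results = [screen_eye(e, bands_rnfl, bands_mrw, grid) for e in eyes]
            totals.append(sum(len(res.records) for res in results))
        cv = np.std(totals) / np.mean(totals)
        assert cv < 0.35

    def test_detected_peaks_near_injected_centres(self, bands_rnfl, bands_mrw, grid):
        from onhmismatch.prevalence import build_prevalence, peak_angles

        cfg = CohortConfig()
        eyes, _ = generate_cohort(cfg, seed=4)
        results = [screen_eye(e, bands_rnfl, bands_mrw, grid) for e in eyes]
        records = [r for res in results for r in res.records]
        pmap = build_prevalence(records, len(eyes), grid)
        for mtype, centres in (
            (MismatchType.HIGH_MRW_LOW_RNFL, cfg.small_vessel_centers),
            (MismatchType.HIGH_RNFL_LOW_MRW, cfg.large_vessel_centers),
        ):
            for angle, _ in peak_angles(pmap, mtype):
                assert min(float(circular_distance(angle, c)) for c in centres) <= 7.5


class TestAnnotationsFromTruth:
    def test_causes_follow_injected_artifacts(self, screened_small_cohort):
        from onhmismatch.attribution import Cause

        kept, truth, results = screened_small_cohort
        records = [r for res in results for r in res.records]
        annotations = annotations_from_truth(truth, records)
        assert len(annotations) == len(records)
        by_type = {}
        for rec_, ann in zip(records, annotations):
            by_type.setdefault(rec_.type, []).append(ann.cause)
        # high-RNFL/low-MRW mismatches are (almost) all large-vessel driven
        b_causes = by_type.get(MismatchType.HIGH_RNFL_LOW_MRW, [])
        if b_causes:
            assert b_causes.count(Cause.LARGE_VESSEL) / len(b_causes) > 0.8
        a_causes = by_type.get(MismatchType.HIGH_MRW_LOW_RNFL, [])
        if a_causes:
            assert Cause.SMALL_VESSEL in a_causes


def test_infeasible_profile_clipped_at_floor():
    cfg = CohortConfig()
    wedges = [_Wedge(center_deg=90.0, core_half_width_deg=180.0, taper_deg=10.0, depth=1.0)]
    clean_rnfl, clean_mrw = _clean_profiles(cfg, wedges, [])
    assert clean_rnfl.min() >= cfg.rnfl_floor_um - 1e-9
    assert clean_mrw.min() >= cfg.mrw_floor_um - 1e-9
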