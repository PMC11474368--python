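"""The two-stage mismatch screen, checked against an exhaustive oracle."""

import itertools

import numpy as np
import pytest

from onhmismatch.geometry import N_ASCANS, N_SECTORS, SectorGrid
from onhmismatch.normative import NormativeBands, PercentileClass, classify
from onhmismatch.screening import (
    Cutoffs,
    MismatchType,
    ScreenGroup,
    TwoStageMismatchScreen,
    screen_eye,
    stage1_group,
    stage2_confirm,
)

from conftest import make_eye

RED, YELLOW, GREEN = PercentileClass.RED, PercentileClass.YELLOW, PercentileClass.GREEN


class TestStage1:
    @pytest.mark.parametrize(
        "rnfl, mrw, expected",
        [
            (70, 90, ScreenGroup.G4_highRNFL_lowMRW),
            (45, 140, ScreenGroup.G2_highMRW_lowRNFL),
            (60, 115, ScreenGroup.UNGROUPED),
            (70, 140, ScreenGroup.G1_bothHigh),
            (45, 90, ScreenGroup.G3_bothLow),
            # boundary values are inclusive as printed (≥/≤)
            (65, 130, ScreenGroup.G1_bothHigh),
            (50, 130, ScreenGroup.G2_highMRW_lowRNFL),
            (50, 100, ScreenGroup.G3_bothLow),
            (65, 100, ScreenGroup.G4_highRNFL_lowMRW),
            # one value decisive, the other in the open gap -> no group
            (70, 115, ScreenGroup.UNGROUPED),
            (60, 90, ScreenGroup.UNGROUPED),
        ],
    )
    def test_grouping(self, rnfl, mrw, expected):
        assert stage1_group(rnfl, mrw) is expected

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError):
            stage1_group(float("nan"), 100.0)


class TestStage2:
    @pytest.mark.parametrize(
        "group, rc, mc, expected",
        [
            (ScreenGroup.G2_highMRW_lowRNFL, RED, GREEN, MismatchType.HIGH_MRW_LOW_RNFL),
            (ScreenGroup.G2_highMRW_lowRNFL, RED, YELLOW, MismatchType.HIGH_MRW_LOW_RNFL),
            (ScreenGroup.G2_highMRW_lowRNFL, YELLOW, GREEN, None),
            (ScreenGroup.G2_highMRW_lowRNFL, RED, RED, None),
            (ScreenGroup.G4_highRNFL_lowMRW, GREEN, RED, MismatchType.HIGH_RNFL_LOW_MRW),
            (ScreenGroup.G4_highRNFL_lowMRW, YELLOW, RED, MismatchType.HIGH_RNFL_LOW_MRW),
            (ScreenGroup.G4_highRNFL_lowMRW, RED, RED, None),
            (ScreenGroup.G4_highRNFL_lowMRW, GREEN, YELLOW, None),
        ],
    )
    def test_confirmation(self, group, rc, mc, expected):
        assert stage2_confirm(group, rc, mc) == expected

    @pytest.mark.parametrize(
        "group", [ScreenGroup.G1_bothHigh, ScreenGroup.G3_bothLow, ScreenGroup.UNGROUPED]
    )
    def test_only_discordant_groups_reach_stage2(self, group):
        with pytest.raises(ValueError):
            stage2_confirm(group, RED, GREEN)


def flat_bands(parameter, p1, p5):
    return NormativeBands(parameter, np.arange(48) * 7.5, np.full(48, float(p1)), np.full(48, float(p5)))


def oracle_decision(rnfl, mrw, rnfl_p1, rnfl_p5, mrw_p1, mrw_p5):
    """Literal restatement of the published screening rules, independent of
    the pipeline: numeric grouping cutoffs, then the percentile criterion."""
    if rnfl <= 50 and mrw >= 130:  # candidate: high MRW, low RNFL
        rnfl_red = rnfl < rnfl_p1
        mrw_red = mrw < mrw_p1
        if rnfl_red and not mrw_red:
            return "high_mrw_low_rnfl"
        return "none"
    if rnfl >= 65 and mrw <= 100:  # candidate: high RNFL, low MRW
        rnfl_red = rnfl < rnfl_p1
        mrw_red = mrw < mrw_p1
        if mrw_red and not rnfl_red:
            return "high_rnfl_low_mrw"
        return "none"
    return "none"


class TestOracleEquivalence:
    def test_pipeline_equals_exhaustive_truth_table(self):
        """Every combination of values crossing the 50/65 and 100/130 µm
        cutoffs and every RED/YELLOW/GREEN class combination must match the
        enumerated rules."""
        rnfl_p1, rnfl_p5 = 60.0, 80.0
        mrw_p1, mrw_p5 = 120.0, 160.0
        screen = TwoStageMismatchScreen(
            bands_rnfl=flat_bands("RNFL", rnfl_p1, rnfl_p5),
            bands_mrw=flat_bands("BMO_MRW", mrw_p1, mrw_p5),
        ).fit()
        rnfl_values = [0, 40, 49.9, 50, 50.1, 55, 59.9, 60, 64.9, 65, 70, 79.9, 80, 120]
        mrw_values = [0, 80, 99.9, 100, 100.1, 110, 119.9, 120, 129.9, 130, 140, 159.9, 160, 250]
        X = np.array([(45.0, r, m) for r, m in itertools.product(rnfl_values, mrw_values)])
        got = screen.predict(X)
        expected = [
            oracle_decision(r, m, rnfl_p1, rnfl_p5, mrw_p1, mrw_p5)
            for _, r, m in X
        ]
        assert list(got) == expected

    def test_oracle_equivalence_with_angle_dependent_bands(self, bands_rnfl, bands_mrw):
        screen = TwoStageMismatchScreen(bands_rnfl=bands_rnfl, bands_mrw=bands_mrw).fit()
        values_r = [40, 50, 60, 65, 70, 90, 130]
        values_m = [70, 100, 120, 130, 180, 250]
        angles = [0.0, 45.0, 90.0, 225.0, 322.5]
        X = np.array(list(itertools.product(angles, values_r, values_m)))
        got = screen.predict(X)
        for (angle, r, m), label in zip(X, got):
            p1r, p5r = bands_rnfl.thresholds_at(angle)
            p1m, p5m = bands_mrw.thresholds_at(angle)
            assert label == oracle_decision(r, m, p1r, p5r, p1m, p5m)


class TestScreenEye:
    def mean_profiles(self, bands_rnfl, bands_mrw):
        """An eye sitting exactly on the normative mean curves."""
        from onhmismatch.normative import DEFAULT_MRW_CONFIG, DEFAULT_RNFL_CONFIG

        ascan_angles = np.arange(N_ASCANS) * 360.0 / N_ASCANS
        cut_angles = np.arange(N_SECTORS) * 7.5
        return (
            DEFAULT_RNFL_CONFIG.mean_curve(ascan_angles),
            DEFAULT_MRW_CONFIG.mean_curve(cut_angles),
        )

    def test_normative_mean_eye_has_no_mismatches(self, bands_rnfl, bands_mrw, grid):
        rnfl, mrw = self.mean_profiles(bands_rnfl, bands_mrw)
        res = screen_eye(make_eye(rnfl, mrw, age=bands_rnfl.reference_age_years), bands_rnfl, bands_mrw, grid)
        assert res.records == []

    def test_single_constructed_mismatch_found_at_45_only(self, bands_rnfl, bands_mrw, grid):
        rnfl, mrw = self.mean_profiles(bands_rnfl, bands_mrw)
        # drop the 16 A-scans of the 45° sector (k=6) deep below p1
        rnfl = rnfl.copy()
        rnfl[(16 * 6 - 8):(16 * 6 + 8)] = 45.0
        res = screen_eye(make_eye(rnfl, mrw, age=bands_rnfl.reference_age_years), bands_rnfl, bands_mrw, grid)
        assert len(res.records) == 1
        rec = res.records[0]
        assert rec.angle_deg == 45.0
        assert rec.type is MismatchType.HIGH_MRW_LOW_RNFL
        assert rec.stage1_group is ScreenGroup.G2_highMRW_lowRNFL
        assert rec.rnfl_class is RED and rec.mrw_class is not RED

    def test_floor_eye_yields_no_mismatches(self, bands_rnfl, bands_mrw, grid):
        """Both parameters below their 1st percentile everywhere (shared
        floor) is group 3 and never a mismatch."""
        res = screen_eye(
            make_eye(np.full(N_ASCANS, 40.0), np.full(N_SECTORS, 80.0)),
            bands_rnfl,
            bands_mrw,
            grid,
        )
        assert res.records == []
        assert res.group_counts[ScreenGroup.G3_bothLow] == 37

    def test_group_counts_conserve_37_sectors(self, screened_small_cohort):
        _, _, results = screened_small_cohort
        for res in results:
            total = sum(res.group_counts.values()) + res.n_missing
            assert total == 37

    def test_no_record_in_nasal_wedge(self, screened_small_cohort, grid):
        analysed = set(grid.analysis_angles.tolist())
        for res in screened_small_cohort[2]:
            for rec in res.records:
                assert rec.angle_deg in analysed
                assert not (142.5 <= rec.angle_deg <= 217.5)

    def test_records_sorted_by_angle(self, screened_small_cohort):
        for res in screened_small_cohort[2]:
            angles = [r.angle_deg for r in res.records]
            assert angles == sorted(angles)

    def test_missing_mrw_sector_skipped_and_counted(self, bands_rnfl, bands_mrw, grid):
        rnfl = np.full(N_ASCANS, 45.0)
        mrw = np.full(N_SECTORS, 300.0)
        mrw[6] = np.nan  # 45°
        res = screen_eye(make_eye(rnfl, mrw), bands_rnfl, bands_mrw, grid)
        assert res.n_missing == 1
        assert 45.0 not in res.screened_angles
        assert all(rec.angle_deg != 45.0 for rec in res.records)

    def test_order_invariance_across_eyes(self, small_cohort, bands_rnfl, bands_mrw, grid):
        eyes, _ = small_cohort
        fwd = [screen_eye(e, bands_rnfl, bands_mrw, grid) for e in eyes[:5]]
        rev = [screen_eye(e, bands_rnfl, bands_mrw, grid) for e in reversed(eyes[:5])]
        assert {r.eye_id: r.records for r in fwd} == {r.eye_id: r.records for r in rev}


class TestSklearnEstimator:
    def test_clone_and_params(self):
        from sklearn.base import clone

        est = TwoStageMismatchScreen(rnfl_high=66.0)
        assert clone(est).get_params()["rnfl_high"] == 66.0
        est.set_params(mrw_low=95.0)
        assert est.fit().cutoffs_.mrw_low == 95.0

    def test_predict_requires_fit(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            TwoStageMismatchScreen().predict(np.array([[45.0, 70.0, 90.0]]))

    def test_age_column_shifts_thresholds(self, bands_rnfl, bands_mrw):
        screen = TwoStageMismatchScreen(bands_rnfl=bands_rnfl, bands_mrw=bands_mrw).fit()
        p1m, _ = bands_mrw.thresholds_at(45.0)
        # MRW just below p1 at reference age: red -> no G2 mismatch;
        # an older eye's lower threshold turns it yellow -> mismatch
        row = [45.0, 45.0, max(p1m - 2.0, 131.0)]
        assert screen.predict(np.array([row]))[0] == "none"
        assert (
            screen.predict(np.array([row + [bands_mrw.reference_age_years + 20]]))[0]
            == "high_mrw_low_rnfl"
        )
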