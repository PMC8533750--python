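import shutil
from pathlib import Path

import pytest

import petfract as pf
from petfract.cohort import TAU_FD
from petfract.errors import AnalysisError, FixtureLoadError


class TestClassifyTrend:
    def test_zero_change_is_stable(self):
        assert pf.classify_trend(0.0, 0.02) == "stable"

    def test_interim_drop_beyond_band_is_deterioration(self):
        # 2.459 - 2.546 for a progressive-disease interim study
        assert pf.classify_trend(2.459 - 2.546, 0.02) == "deteriorated"

    def test_small_drop_within_band_is_stable(self):
        # 2.507 - 2.524 sits inside the 0.02 band
        assert pf.classify_trend(2.507 - 2.524, 0.02) == "stable"

    def test_rise_beyond_band_is_improvement(self):
        assert pf.classify_trend(0.05, 0.02) == "improved"

    def test_non_finite_delta_rejected(self):
        with pytest.raises(ValueError):
            pf.classify_trend(float("nan"))


class TestConcordance:
    def test_decrease_agrees_with_progression(self):
        assert pf.concordance(-0.087, "PMD", TAU_FD) is True

    def test_increase_disagrees_with_progression(self):
        assert pf.concordance(+0.012, "PMD", TAU_FD) is False

    def test_any_increase_agrees_with_partial_response(self):
        # the sign rule applies to responses; no stability band
        assert pf.concordance(+0.020, "PMR", TAU_FD) is True
        assert pf.concordance(+0.001, "CMR", TAU_FD) is True
        assert pf.concordance(-0.001, "PMR", TAU_FD) is False

    def test_stable_disease_uses_the_band(self):
        assert pf.concordance(+0.010, "SMD", TAU_FD) is True
        assert pf.concordance(-0.040, "SMD", TAU_FD) is False

    def test_baseline_outcome_rejected(self):
        with pytest.raises(ValueError):
            pf.concordance(0.1, "baseline", TAU_FD)


class TestFixtures:
    def test_cohort_shape(self, cohort_records):
        assert len(cohort_records.patients()) == 19
        assert len(cohort_records.controls()) == 8
        assert len(cohort_records) == 19 * 3 + 8

    def test_control_values_spot_checks(self, cohort_records):
        assert cohort_records.get("H3", "control").fd == pytest.approx(2.623)
        assert cohort_records.get("H5", "control").mfs == pytest.approx(2.538)

    def test_missing_fixture_raises(self, tmp_path):
        with pytest.raises(FixtureLoadError, match="not found"):
            pf.load_fixtures(tmp_path)

    def test_schema_mismatch_lists_columns(self, tmp_path):
        import petfract.cohort as cohort_mod

        src = Path(cohort_mod.__file__).parent / "data"
        for name in ("table1_clinical.csv", "table2_fd.csv", "table3_mfs.csv"):
            shutil.copy(src / name, tmp_path / name)
        (tmp_path / "table2_fd.csv").write_text("foo,bar\n1,2\n")
        with pytest.raises(FixtureLoadError, match="expected columns"):
            pf.load_fixtures(tmp_path)

    def test_empty_fixture_raises(self, tmp_path):
        import petfract.cohort as cohort_mod

        src = Path(cohort_mod.__file__).parent / "data"
        for name in ("table1_clinical.csv", "table2_fd.csv", "table3_mfs.csv"):
            shutil.copy(src / name, tmp_path / name)
        (tmp_path / "table3_mfs.csv").write_text("")
        with pytest.raises(FixtureLoadError, match="empty"):
            pf.load_fixtures(tmp_path)


class TestPublishedMatchingAnnotations:
    @pytest.mark.parametrize("measure,tau", [("FD", 0.025), ("MFS", 0.13)])
    def test_rule_reproduces_every_printed_flag(self, cohort_records, measure, tau):
        report = pf.cohort_summary(cohort_records, measure, tau_stable=tau)
        checked = 0
        for row in report.per_study:
            rec = cohort_records.get(row["subject"], row["stage"])
            assert row["concordant"] == rec.matching[measure], (
                row["subject"], row["stage"])
            checked += 1
        assert checked == 38


class TestCohortSummary:
    def test_fd_concordance_all_studies(self, cohort_records):
        r = pf.cohort_summary(cohort_records, "FD")
        assert (r.n_concordant, r.n_included) == (27, 38)
        assert r.percent_matching == 71.05

    def test_fd_concordance_without_colitis(self, cohort_records):
        r = pf.cohort_summary(cohort_records, "FD", exclude_colitis=True)
        assert r.n_excluded == 7
        assert (r.n_concordant, r.n_included) == (24, 31)
        assert r.percent_matching == 77.42

    def test_mfs_concordance_without_colitis(self, cohort_records):
        r = pf.cohort_summary(cohort_records, "MFS", exclude_colitis=True)
        assert (r.n_concordant, r.n_included) == (25, 31)
        assert r.percent_matching == 80.65

    def test_mfs_concordance_all_studies_matches_table_not_prose(self, cohort_records):
        # the printed table annotations give 28/38; see docs/methods.md
        r = pf.cohort_summary(cohort_records, "MFS")
        assert (r.n_concordant, r.n_included) == (28, 38)
        assert r.percent_matching == 73.68

    def test_all_concordant_toy_cohort(self):
        records = [
            pf.StudyRecord("X1", "baseline", fd=2.5),
            pf.StudyRecord("X1", "interim", outcome="PMR", fd=2.6),
            pf.StudyRecord("X1", "final", outcome="PMD", fd=2.4),
        ]
        r = pf.cohort_summary(records, "FD")
        assert r.percent_matching == 100.0

    def test_percent_invariant_to_record_order(self, cohort_records):
        forward = pf.cohort_summary(cohort_records, "FD")
        backward = pf.cohort_summary(list(cohort_records)[::-1], "FD")
        assert forward.percent_matching == backward.percent_matching

    def test_all_studies_excluded_raises(self):
        records = [
            pf.StudyRecord("X1", "baseline", fd=2.5),
            pf.StudyRecord("X1", "interim", outcome="PMD", fd=2.4,
                           irae_tags=("colitis",)),
        ]
        with pytest.raises(AnalysisError, match="excluded"):
            pf.cohort_summary(records, "FD", exclude_colitis=True)


class TestColitisCensus:
    def test_eight_studies_mention_colitis(self, cohort_records):
        assert pf.count_colitis_studies(cohort_records) == 8

    def test_non_specific_colitis_sign_is_not_an_exclusion(self, cohort_records):
        rec = cohort_records.get("P15", "final")
        assert rec.mentions_colitis() is True
        assert rec.colitis_irae() is False
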