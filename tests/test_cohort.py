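"""Cohort definitions: observability, >=2-diagnosis rule, washout, NYHA."""

import pandas as pd
import pytest

from hfclaims import HFCareStudy, assign_nyha, build_cohort, filter_observable
from hfclaims.codes import NYHA
from hfclaims.cohort import CohortOptions, age_band, quarter_of
from hfclaims.simulate import SimulationConfig, generate

from conftest import make_bundle, make_dx, make_patient

YEAR = 2011
STUDY = ("2009-01-01", "2013-12-31")


class TestFilterObservable:
    def test_fully_covered_alive_patient_kept(self):
        bundle = make_bundle([make_patient("a")])
        assert filter_observable(bundle, *STUDY, earliest_death="2011-01-01") == {"a"}

    def test_death_before_identification_year_excluded(self):
        bundle = make_bundle([make_patient("a", coverage=("2009-01-01", "2010-06-01"), death="2010-06-01")])
        assert filter_observable(bundle, *STUDY, earliest_death="2011-01-01") == set()

    def test_death_during_study_with_coverage_until_death_kept(self):
        bundle = make_bundle([make_patient("a", coverage=("2009-01-01", "2012-03-01"), death="2012-03-01")])
        assert filter_observable(bundle, *STUDY, earliest_death="2011-01-01") == {"a"}

    def test_interrupted_coverage_excluded(self):
        bundle = make_bundle([make_patient("a", coverage=("2009-06-01", "2013-12-31"))])
        assert filter_observable(bundle, *STUDY) == set()

    def test_invalid_window_is_config_error(self):
        bundle = make_bundle([make_patient("a")])
        with pytest.raises(ValueError):
            filter_observable(bundle, "2013-12-31", "2009-01-01")


class TestBuildCohort:
    def test_single_hf_code_excluded(self):
        bundle = make_bundle([make_patient("a")], [make_dx("a", "2011-03-01")])
        assert len(build_cohort(bundle, YEAR)) == 0

    def test_two_codes_index_quarter_and_incident(self):
        bundle = make_bundle(
            [make_patient("a")],
            [make_dx("a", "2011-02-10"), make_dx("a", "2011-07-01")],
        )
        cohort = build_cohort(bundle, YEAR)
        rec = cohort.iloc[0]
        assert rec["index_quarter"] == "2011Q1"
        assert rec["index_date"] == pd.Timestamp("2011-02-10")
        assert bool(rec["incident"])

    def test_washout_diagnosis_makes_patient_prevalent(self):
        bundle = make_bundle(
            [make_patient("a")],
            [
                make_dx("a", "2010-06-15"),  # inside the 4 preceding quarters
                make_dx("a", "2011-02-10"),
                make_dx("a", "2011-07-01"),
            ],
        )
        assert not bool(build_cohort(bundle, YEAR).iloc[0]["incident"])

    def test_diagnosis_just_outside_washout_keeps_incident(self):
        # index Q1-2011: washout is 2010Q1..2010Q4; a 2009Q4 code is outside
        bundle = make_bundle(
            [make_patient("a")],
            [
                make_dx("a", "2009-11-15"),
                make_dx("a", "2011-02-10"),
                make_dx("a", "2011-07-01"),
            ],
        )
        assert bool(build_cohort(bundle, YEAR).iloc[0]["incident"])

    def test_same_day_same_sector_duplicates_count_once(self):
        rows = [make_dx("a", "2011-03-01"), make_dx("a", "2011-03-01")]
        bundle = make_bundle([make_patient("a")], rows)
        assert len(build_cohort(bundle, YEAR)) == 0
        # the documented switch restores raw counting
        opts = CohortOptions(dedupe_same_day_sector=False)
        assert len(build_cohort(bundle, YEAR, options=opts)) == 1

    def test_same_day_different_sectors_count_separately(self):
        rows = [
            make_dx("a", "2011-03-01", sector="AMBULATORY"),
            make_dx("a", "2011-03-01", sector="HOSPITAL_INPATIENT", specialty="CARDIOLOGY"),
        ]
        bundle = make_bundle([make_patient("a")], rows)
        assert len(build_cohort(bundle, YEAR)) == 1

    def test_non_hf_codes_do_not_qualify(self):
        rows = [make_dx("a", "2011-03-01", icd="I10"), make_dx("a", "2011-05-01", icd="I10")]
        bundle = make_bundle([make_patient("a")], rows)
        assert len(build_cohort(bundle, YEAR)) == 0


class TestAssignNYHA:
    def frame(self, rows):
        return make_bundle([make_patient("a")], rows).diagnoses

    def test_last_documented_class_wins(self):
        dx = self.frame([make_dx("a", "2011-03-03", "I50.12"), make_dx("a", "2011-09-09", "I50.13")])
        assert assign_nyha(dx, YEAR) is NYHA.III

    def test_unspecific_codes_only_gives_other(self):
        dx = self.frame([make_dx("a", "2011-03-03", "I50.9"), make_dx("a", "2011-09-09", "I50.9")])
        assert assign_nyha(dx, YEAR) is NYHA.OTHER

    def test_same_day_tie_resolves_to_worse_class(self):
        dx = self.frame([make_dx("a", "2011-06-01", "I50.13"), make_dx("a", "2011-06-01", "I50.12")])
        assert assign_nyha(dx, YEAR) is NYHA.III

    def test_codes_outside_identification_year_ignored(self):
        dx = self.frame([make_dx("a", "2010-06-01", "I50.14"), make_dx("a", "2011-02-01", "I50.11")])
        assert assign_nyha(dx, YEAR) is NYHA.I


class TestCohortProperties:
    def test_partitions(self, paperlike_results):
        cohort = paperlike_results.cohort
        assert cohort["incident"].isin([True, False]).all()
        assert set(cohort["nyha"]).issubset({"I", "II", "III", "IV", "OTHER"})
        assert cohort["age_band"].isin(
            ["0-49"] + [f"{lo}-{lo+4}" for lo in range(50, 90, 5)] + [">=90"]
        ).all()

    def test_washout_flag_equals_brute_force_event_scan(self):
        bundle, _ = generate(SimulationConfig(n_patients=4000, seed=9))
        observable = filter_observable(bundle, *STUDY, earliest_death="2011-01-01")
        cohort = build_cohort(bundle, YEAR, observable_ids=observable)

        from hfclaims.codes import default_code_config, normalize_icd

        hf_codes = default_code_config().hf_codes_normalized
        dx = bundle.diagnoses
        dx_hf = dx[dx["icd_code"].map(normalize_icd).isin(hf_codes)]
        for rec in cohort.itertuples(index=False):
            iq = pd.Period(rec.index_quarter, freq="Q")
            events = dx_hf[dx_hf["patient_id"] == rec.patient_id]
            washout_hit = any(
                iq - 4 <= quarter_of(d) <= iq - 1 for d in events["event_date"]
            )
            assert rec.incident == (not washout_hit)

    def test_year_shift_invariance(self):
        cfg = SimulationConfig(n_patients=1500, seed=13)
        bundle, _ = generate(cfg)

        shifted = bundle.copy()
        offset = pd.DateOffset(years=2)
        shifted.patients["coverage_start"] += offset
        shifted.patients["coverage_end"] += offset
        shifted.patients["death_date"] += offset
        shifted.diagnoses["event_date"] += offset
        shifted.dispensations["dispense_date"] += offset
        shifted.activities["event_date"] += offset

        def run(b, year):
            obs = filter_observable(
                b, f"{year-2}-01-01", f"{year+2}-12-31", earliest_death=f"{year}-01-01"
            )
            return build_cohort(b, year, observable_ids=obs)

        a = run(bundle, YEAR).sort_values("patient_id").reset_index(drop=True)
        b = run(shifted, YEAR + 2).sort_values("patient_id").reset_index(drop=True)
        assert list(a["patient_id"]) == list(b["patient_id"])
        assert list(a["incident"]) == list(b["incident"])
        assert list(a["nyha"]) == list(b["nyha"])
        assert all(
            pd.Period(qa, freq="Q") + 8 == pd.Period(qb, freq="Q")
            for qa, qb in zip(a["index_quarter"], b["index_quarter"])
        )


@pytest.mark.parametrize(
    "age,band",
    [(0, "0-49"), (49, "0-49"), (50, "50-54"), (67, "65-69"), (89, "85-89"), (90, ">=90"), (101, ">=90")],
)
def test_age_bands(age, band):
    assert age_band(age) == band
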