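"""Shared fixtures: hand-built micro-bundles and one session-scoped
paper-like simulation reused by the recovery and acceptance tests."""

from __future__ import annotations

import pandas as pd
import pytest

from hfclaims import ClaimsBundle, HFCareStudy, preset_paperlike

DEFAULT_COVERAGE = ("2009-01-01", "2013-12-31")


def make_patient(pid, sex="M", birth_year=1940, coverage=DEFAULT_COVERAGE, death=None):
    return {
        "patient_id": pid,
        "sex": sex,
        "birth_year": birth_year,
        "coverage_start": pd.Timestamp(coverage[0]),
        "coverage_end": pd.Timestamp(coverage[1]),
        "death_date": pd.Timestamp(death) if death else pd.NaT,
    }


def make_dx(pid, date, icd="I50.9", sector="AMBULATORY", specialty="FAMILY_PRACTICE"):
    return {
        "patient_id": pid,
        "event_date": pd.Timestamp(date),
        "icd_code": icd,
        "sector": sector,
        "provider_specialty": specialty,
    }


def make_rx(pid, date, atc, supply=30):
    return {
        "patient_id": pid,
        "dispense_date": pd.Timestamp(date),
        "atc_code": atc,
        "supply_days": supply,
    }


def make_act(pid, date, kind="TREATMENT", sector="AMBULATORY", specialty="FAMILY_PRACTICE", echo=False):
    return {
        "patient_id": pid,
        "event_date": pd.Timestamp(date),
        "activity_kind": kind,
        "is_echocardiography": echo,
        "sector": sector,
        "provider_specialty": specialty,
    }


_PATIENT_COLS = ["patient_id", "sex", "birth_year", "coverage_start", "coverage_end", "death_date"]
_DX_COLS = ["patient_id", "event_date", "icd_code", "sector", "provider_specialty"]
_RX_COLS = ["patient_id", "dispense_date", "atc_code", "supply_days"]
_ACT_COLS = ["patient_id", "event_date", "activity_kind", "is_echocardiography", "sector", "provider_specialty"]


def make_bundle(patients, diagnoses=(), dispensations=(), activities=(), year=2011) -> ClaimsBundle:
    def frame(rows, cols, date_cols):
        df = pd.DataFrame(list(rows), columns=cols)
        for c in date_cols:
            df[c] = pd.to_datetime(df[c])
        return df

    return ClaimsBundle(
        patients=frame(patients, _PATIENT_COLS, ["coverage_start", "coverage_end", "death_date"]),
        diagnoses=frame(diagnoses, _DX_COLS, ["event_date"]),
        dispensations=frame(dispensations, _RX_COLS, ["dispense_date"]),
        activities=frame(activities, _ACT_COLS, ["event_date"]),
        metadata={"identification_year": year},
    )


@pytest.fixture(scope="session")
def paperlike_study():
    """One paper-like simulation (n=25,000, fixed seed) shared across tests."""
    return HFCareStudy.from_simulation(preset_paperlike(n_patients=25_000, seed=1))


@pytest.fixture(scope="session")
def paperlike_results(paperlike_study):
    return paperlike_study.fit()
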