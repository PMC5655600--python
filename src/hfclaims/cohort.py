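"""Study-population construction: observability, HF cohort, washout, NYHA.

The design is an incident-case washout design on quarter-granular claims:

* patients must be observable without interruption over the whole study
  window (default 1 Jan of identification_year-2 through 31 Dec of
  identification_year+2) or until death, and must not have died before the
  identification year;
* the prevalent HF cohort requires at least two HF-qualifying diagnoses in
  the identification year (duplicate same-day, same-sector rows count once);
* the index quarter is the calendar quarter of the first qualifying
  diagnosis; a patient is *incident* (newly diagnosed) when the four
  calendar quarters before the index quarter contain no HF diagnosis;
* NYHA class is the last class-specific code documented in the
  identification year (same-day ties resolve to the worse class); patients
  without any class-specific code form the OTHER group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .claims import ClaimsBundle
from .codes import NYHA, CodeConfig, default_code_config, normalize_icd

__all__ = [
    "quarter_of",
    "age_band",
    "AGE_BANDS",
    "filter_observable",
    "build_cohort",
    "assign_nyha",
]


def quarter_of(date) -> pd.Period:
    """Calendar quarter (pandas Period, freq='Q') containing *date*."""
    return pd.Period(pd.Timestamp(date), freq="Q")


#: 0-49, then 5-year bands, open-ended at 90.
AGE_BANDS = ["0-49"] + [f"{lo}-{lo + 4}" for lo in range(50, 90, 5)] + [">=90"]


def age_band(age: int) -> str:
    if age < 50:
        return "0-49"
    if age >= 90:
        return ">=90"
    lo = 5 * (age // 5)
    return f"{lo}-{lo + 4}"


def filter_observable(
    bundle: ClaimsBundle,
    study_start,
    study_end,
    *,
    earliest_death=None,
) -> set[str]:
    """IDs of patients observable without interruption over the study window.

    A patient qualifies when coverage spans [study_start, min(death,
    study_end)].  Patients who died before *earliest_death* (normally 1 Jan
    of the identification year) are excluded.
    """
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    if study_start >= study_end:
        raise ValueError("study_start must precede study_end")

    pat = bundle.patients
    death = pd.to_datetime(pat["death_date"])
    required_end = death.fillna(study_end).clip(upper=study_end)
    keep = (pd.to_datetime(pat["coverage_start"]) <= study_start) & (
        pd.to_datetime(pat["coverage_end"]) >= required_end
    )
    if earliest_death is not None:
        keep &= death.isna() | (death >= pd.Timestamp(earliest_death))
    return set(pat.loc[keep, "patient_id"].astype(str))


def _hf_events(
    diagnoses: pd.DataFrame, code_config: CodeConfig
) -> pd.DataFrame:
    """Diagnosis rows restricted to HF-qualifying codes, with a `nyha` column."""
    codes = diagnoses["icd_code"].astype(str).map(normalize_icd)
    is_hf = codes.isin(code_config.hf_codes_normalized)
    out = diagnoses.loc[is_hf].copy()
    out["nyha"] = codes[is_hf].map(lambda c: code_config.nyha_of(c).value)
    return out


def assign_nyha(
    diagnoses: pd.DataFrame,
    identification_year: int,
    *,
    code_config: Optional[CodeConfig] = None,
) -> NYHA:
    """NYHA label for one patient: last class-specific code in the year.

    Same-day ties resolve to the worse (higher) class.  Returns
    ``NYHA.OTHER`` when no class-specific code exists in the year.
    """
    cfg = code_config or default_code_config()
    events = _hf_events(diagnoses, cfg)
    events = events[events["event_date"].dt.year == identification_year]
    specific = events[events["nyha"].isin(["I", "II", "III", "IV"])]
    if specific.empty:
        return NYHA.OTHER
    ranks = specific["nyha"].map(lambda v: NYHA(v).rank)
    order = specific.assign(_rank=ranks).sort_values(["event_date", "_rank"])
    return NYHA(order.iloc[-1]["nyha"])


@dataclass(frozen=True)
class CohortOptions:
    """Switches documented as open choices in the cohort definition."""

    dedupe_same_day_sector: bool = True  # duplicate billing rows count once


def build_cohort(
    bundle: ClaimsBundle,
    identification_year: int,
    *,
    observable_ids: Optional[Iterable[str]] = None,
    code_config: Optional[CodeConfig] = None,
    options: CohortOptions = CohortOptions(),
) -> pd.DataFrame:
    """One row per prevalent-HF cohort member with derived per-patient facts.

    Columns: patient_id, index_date, index_quarter (str, e.g. "2011Q2"),
    incident, nyha, sex, age, age_band, hospitalized_in_id_year,
    died_in_study, death_date.
    """
    cfg = code_config or default_code_config()
    year = int(identification_year)

    pat = bundle.patients.copy()
    pat["patient_id"] = pat["patient_id"].astype(str)
    if observable_ids is not None:
        pat = pat[pat["patient_id"].isin(set(map(str, observable_ids)))]

    hf = _hf_events(bundle.diagnoses, cfg)
    hf["patient_id"] = hf["patient_id"].astype(str)
    hf = hf[hf["patient_id"].isin(set(pat["patient_id"]))]

    in_year = hf[hf["event_date"].dt.year == year]
    if options.dedupe_same_day_sector:
        counted = in_year.drop_duplicates(subset=["patient_id", "event_date", "sector"])
    else:
        counted = in_year
    n_events = counted.groupby("patient_id").size()
    member_ids = set(n_events[n_events >= 2].index)
    if not member_ids:
        return _empty_cohort()

    in_year_members = in_year[in_year["patient_id"].isin(member_ids)]
    index_date = in_year_members.groupby("patient_id")["event_date"].min()
    index_quarter = index_date.map(quarter_of)

    # washout: any HF diagnosis (any date) in the 4 quarters preceding index
    all_q = hf["event_date"].dt.to_period("Q")
    hf_q = pd.DataFrame({"patient_id": hf["patient_id"], "q": all_q})
    incident: dict[str, bool] = {}
    grouped = {pid: qs["q"] for pid, qs in hf_q.groupby("patient_id") if pid in member_ids}
    for pid in member_ids:
        iq = index_quarter[pid]
        qs = grouped.get(pid)
        washout = {iq - k for k in range(1, 5)}
        incident[pid] = not bool(qs.isin(washout).any()) if qs is not None else True

    # NYHA: last class-specific code in the identification year, worse on ties
    specific = in_year_members[in_year_members["nyha"].isin(["I", "II", "III", "IV"])].copy()
    nyha_label = {pid: NYHA.OTHER.value for pid in member_ids}
    if not specific.empty:
        specific["_rank"] = specific["nyha"].map(lambda v: NYHA(v).rank)
        specific = specific.sort_values(["event_date", "_rank"])
        for pid, rows in specific.groupby("patient_id"):
            nyha_label[pid] = rows.iloc[-1]["nyha"]

    # hospitalization during the identification year: any inpatient event
    inpat_ids: set[str] = set()
    for df, date_col in ((bundle.diagnoses, "event_date"), (bundle.activities, "event_date")):
        if len(df):
            mask = (df["sector"] == "HOSPITAL_INPATIENT") & (df[date_col].dt.year == year)
            inpat_ids |= set(df.loc[mask, "patient_id"].astype(str))

    demo = pat.set_index("patient_id")
    ids = sorted(member_ids)
    age = (year - demo.loc[ids, "birth_year"].astype(int)).astype(int)
    death = pd.to_datetime(demo.loc[ids, "death_date"])

    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "index_date": index_date[ids].to_numpy(),
            "index_quarter": [str(index_quarter[p]) for p in ids],
            "incident": [incident[p] for p in ids],
            "nyha": [nyha_label[p] for p in ids],
            "sex": demo.loc[ids, "sex"].to_numpy(),
            "age": age.to_numpy(),
            "age_band": [age_band(a) for a in age],
            "hospitalized_in_id_year": [p in inpat_ids for p in ids],
            "died_in_study": death.notna().to_numpy(),
            "death_date": death.to_numpy(),
        }
    )
    return cohort.reset_index(drop=True)


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "index_date": pd.Series(dtype="datetime64[ns]"),
            "index_quarter": pd.Series(dtype=str),
            "incident": pd.Series(dtype=bool),
            "nyha": pd.Series(dtype=str),
            "sex": pd.Series(dtype=str),
            "age": pd.Series(dtype=int),
            "age_band": pd.Series(dtype=str),
            "hospitalized_in_id_year": pd.Series(dtype=bool),
            "died_in_study": pd.Series(dtype=bool),
            "death_date": pd.Series(dtype="datetime64[ns]"),
        }
    )
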