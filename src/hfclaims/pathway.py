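"""Patient-pathway outputs for the incident (newly diagnosed) cohort.

Four reproductions of the study's pathway figures:

* *diagnosing attribution* — sector and physician specialty / hospital unit
  of each incident patient's first qualifying diagnosis (each patient counts
  exactly once; same-day multi-sector ties resolve by configurable
  precedence, hospital inpatient first);
* *quarterly contacts* — for eight quarters from the index quarter, the
  share of patients alive at quarter start with at least one office-based,
  hospital-inpatient, or hospital-outpatient contact (patients leave the
  denominator the quarter after death);
* *activity attribution* — HF-associated activity EVENTS (not patients) in
  the two-year follow-up, split into technical diagnostics vs treatment and
  grouped by sector and specialty;
* *echo uptake* — share of incident patients with at least one
  echocardiographic procedure during follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .claims import ClaimsBundle
from .codes import CodeConfig, default_code_config, normalize_icd

__all__ = [
    "PathwayTables",
    "PathwayOptions",
    "attribute_diagnosis",
    "quarterly_contacts",
    "attribute_activities",
    "echo_uptake",
    "compute_pathway",
]

#: same-day multi-sector index precedence: an admission on the diagnosis day
#: is the dominant clinical event.
SECTOR_PRECEDENCE = ("HOSPITAL_INPATIENT", "AMBULATORY", "HOSPITAL_OUTPATIENT")

CONTACT_TYPES = {
    "office": "AMBULATORY",
    "inpatient": "HOSPITAL_INPATIENT",
    "outpatient": "HOSPITAL_OUTPATIENT",
}


@dataclass(frozen=True)
class PathwayOptions:
    n_quarters: int = 8
    #: "index-quarter": Q1 is the quarter containing the diagnosis;
    #: "next-quarter": Q1 is the quarter after it (documented alternative).
    followup_origin: str = "index-quarter"
    sector_precedence: tuple[str, ...] = SECTOR_PRECEDENCE


@dataclass
class PathwayTables:
    diagnosing_attribution: pd.DataFrame
    quarterly_contacts: pd.DataFrame
    activity_attribution: pd.DataFrame
    echo_count: int
    echo_share: float


def _incident(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["incident"]].copy()


def _first_quarter(rec, origin: str) -> pd.Period:
    q = pd.Period(rec.index_quarter, freq="Q")
    return q + 1 if origin == "next-quarter" else q


# ---------------------------------------------------------------------------


def attribute_diagnosis(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    code_config: Optional[CodeConfig] = None,
    options: PathwayOptions = PathwayOptions(),
) -> pd.DataFrame:
    """Sector x specialty attribution of the first qualifying diagnosis.

    Returns a tidy table with counts and three share columns: within all
    settings, within the event's sector, and the sector's share of all
    settings.
    """
    cfg = code_config or default_code_config()
    inc = _incident(cohort)
    dx = bundle.diagnoses.copy()
    dx["patient_id"] = dx["patient_id"].astype(str)
    codes = dx["icd_code"].astype(str).map(normalize_icd)
    dx = dx[codes.isin(cfg.hf_codes_normalized)]

    prec = {s: i for i, s in enumerate(options.sector_precedence)}
    picks = []
    idx = inc.set_index("patient_id")["index_date"]
    dx_by_pid = dict(tuple(dx.groupby("patient_id")))
    for pid, index_date in idx.items():
        events = dx_by_pid.get(str(pid))
        day = events[events["event_date"] == index_date]
        day = day.assign(_prec=day["sector"].map(prec)).sort_values(
            ["_prec", "provider_specialty"], kind="stable"
        )
        best = day.iloc[0]
        picks.append({"patient_id": pid, "sector": best["sector"], "specialty": best["provider_specialty"]})
    picked = pd.DataFrame(picks, columns=["patient_id", "sector", "specialty"])

    total = len(picked)
    table = (
        picked.groupby(["sector", "specialty"]).size().rename("count").reset_index()
        if total
        else pd.DataFrame(columns=["sector", "specialty", "count"])
    )
    if total:
        table["share_all_settings"] = table["count"] / total
        sector_totals = table.groupby("sector")["count"].transform("sum")
        table["share_within_sector"] = table["count"] / sector_totals
        table["sector_share"] = sector_totals / total
    return table


def quarterly_contacts(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    options: PathwayOptions = PathwayOptions(),
) -> pd.DataFrame:
    """Contact shares per follow-up quarter with alive-in-quarter denominators.

    A contact is any diagnosis or activity event in the calendar quarter with
    the matching sector.  A patient is in the denominator of a quarter when
    alive at its start; the quarter containing the death still counts.
    """
    inc = _incident(cohort)
    events = pd.concat(
        [
            bundle.diagnoses[["patient_id", "event_date", "sector"]],
            bundle.activities[["patient_id", "event_date", "sector"]],
        ],
        ignore_index=True,
    )
    events["patient_id"] = events["patient_id"].astype(str)
    events["q"] = events["event_date"].dt.to_period("Q")
    by_pid = {pid: set(zip(grp["q"], grp["sector"])) for pid, grp in events.groupby("patient_id")}

    rows = []
    for k in range(options.n_quarters):
        denom = 0
        nums = {t: 0 for t in CONTACT_TYPES}
        for rec in inc.itertuples(index=False):
            q = _first_quarter(rec, options.followup_origin) + k
            death = rec.death_date
            if not pd.isna(death) and pd.Timestamp(death) < q.start_time:
                continue  # left the denominator the quarter after death
            denom += 1
            had = by_pid.get(str(rec.patient_id), set())
            for ctype, sector in CONTACT_TYPES.items():
                if (q, sector) in had:
                    nums[ctype] += 1
        for ctype in CONTACT_TYPES:
            rows.append(
                {
                    "quarter": k + 1,
                    "contact_type": ctype,
                    "numerator": nums[ctype],
                    "denominator": denom,
                    "share": nums[ctype] / denom if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _followup_window(rec, options: PathwayOptions) -> tuple[pd.Timestamp, pd.Timestamp]:
    q0 = _first_quarter(rec, options.followup_origin)
    start = q0.start_time
    end = (q0 + options.n_quarters - 1).end_time.normalize()
    death = rec.death_date
    if not pd.isna(death):
        end = min(end, pd.Timestamp(death))
    return start, end


def attribute_activities(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    options: PathwayOptions = PathwayOptions(),
) -> pd.DataFrame:
    """Activity-event attribution by (sector, specialty) within each kind.

    The unit of analysis is the activity event, not the patient, so counts
    may exceed the cohort size.  Shares are within activity kind.
    """
    inc = _incident(cohort)
    act = bundle.activities.copy()
    act["patient_id"] = act["patient_id"].astype(str)
    act_by_pid = dict(tuple(act.groupby("patient_id")))

    kept = []
    for rec in inc.itertuples(index=False):
        events = act_by_pid.get(str(rec.patient_id))
        if events is None:
            continue
        start, end = _followup_window(rec, options)
        kept.append(events[(events["event_date"] >= start) & (events["event_date"] <= end)])
    if not kept:
        return pd.DataFrame(columns=["activity_kind", "sector", "specialty", "count", "share_within_kind"])
    allev = pd.concat(kept, ignore_index=True)
    table = (
        allev.groupby(["activity_kind", "sector", "provider_specialty"])
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"provider_specialty": "specialty"})
    )
    kind_totals = table.groupby("activity_kind")["count"].transform("sum")
    table["share_within_kind"] = table["count"] / kind_totals
    return table


def echo_uptake(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    options: PathwayOptions = PathwayOptions(),
) -> tuple[int, float]:
    """(count, share) of incident patients with >=1 echocardiography in follow-up."""
    inc = _incident(cohort)
    if inc.empty:
        return 0, float("nan")
    echo = bundle.activities[bundle.activities["is_echocardiography"].astype(bool)]
    echo_by_pid = dict(tuple(echo.groupby(echo["patient_id"].astype(str))))
    n = 0
    for rec in inc.itertuples(index=False):
        events = echo_by_pid.get(str(rec.patient_id))
        if events is None:
            continue
        start, end = _followup_window(rec, options)
        if ((events["event_date"] >= start) & (events["event_date"] <= end)).any():
            n += 1
    return n, n / len(inc)


def compute_pathway(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    code_config: Optional[CodeConfig] = None,
    options: PathwayOptions = PathwayOptions(),
) -> PathwayTables:
    """All four pathway outputs for the incident subset of *cohort*."""
    count, share = echo_uptake(cohort, bundle, options=options)
    return PathwayTables(
        diagnosing_attribution=attribute_diagnosis(
            cohort, bundle, code_config=code_config, options=options
        ),
        quarterly_contacts=quarterly_contacts(cohort, bundle, options=options),
        activity_attribution=attribute_activities(cohort, bundle, options=options),
        echo_count=count,
        echo_share=share,
    )
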