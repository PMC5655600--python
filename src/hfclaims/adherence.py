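"""Medication episodes and guideline treatment-pattern classification.

Dispensations are turned into per-drug-class *coverage episodes* by gap
bridging: a dispensation covers ``supply_days`` consecutive days; a refill
whose uncovered gap after the previous covered day is at most
``gap_tolerance`` days (default 90, "three months") extends the episode,
otherwise a new episode begins.  ACE inhibitors and ARBs are additionally
pooled into a merged renin-angiotensin (RAS) blocker track, because the
patterns require "ACE inhibitor OR ARB" and a switch between the two must
not break coverage.

Two guideline-derived patterns are assessed per NYHA class over the two
years after first diagnosis (censored at death):

===========  =============================================  =====================
NYHA class   strict                                          less strict
===========  =============================================  =====================
I            RAS blocker                                     same
II           RAS blocker + beta-blocker + diuretic           same
III-IV       RAS blocker + beta-blocker + diuretic + MRA     without the MRA
===========  =============================================  =====================

A required term is met when bridged coverage begins within ``gap_tolerance``
days of the index date (the index date acts as a virtual previously covered
day) and extends, with no gap exceeding the tolerance, to the censor date
(death or window end).  MRA substances count toward the diuretic term by
default (an MRA is a potassium-sparing diuretic); switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import NYHA, CodeConfig, DrugClass, default_code_config

__all__ = [
    "CoverageEpisode",
    "AdherenceVerdict",
    "AdherenceOptions",
    "RAS",
    "required_classes",
    "build_episodes",
    "classify_adherence",
    "classify_bundle",
    "stratify",
]

#: pooled ACE-inhibitor/ARB track label
RAS = "RAS"

GAP_TOLERANCE_DAYS = 90
WINDOW_DAYS = 730


@dataclass(frozen=True)
class CoverageEpisode:
    """Maximal run of covered days for one drug-class track (inclusive ends)."""

    drug_class: str
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class AdherenceOptions:
    gap_tolerance: int = GAP_TOLERANCE_DAYS
    window_days: int = WINDOW_DAYS
    mra_counts_as_diuretic: bool = True
    #: assess only initiation within the first quarter after index instead of
    #: sustained two-year coverage (documented reporting variant)
    first_quarter_initiation: bool = False


@dataclass
class AdherenceVerdict:
    """Per-patient pattern verdicts with the episode evidence trail."""

    patient_id: str
    nyha: NYHA
    strict: Optional[bool]
    less_strict: Optional[bool]
    censor_date: Optional[pd.Timestamp]
    episodes: Mapping[str, Sequence[CoverageEpisode]] = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        """False for NYHA 'OTHER' patients, who are excluded from denominators."""
        return self.strict is not None


def required_classes(nyha: NYHA, pattern: str) -> tuple[str, ...]:
    """Drug-class terms a pattern requires for the given NYHA class."""
    if nyha not in (NYHA.I, NYHA.II, NYHA.III, NYHA.IV):
        raise ValueError("pattern requirements are defined for NYHA I-IV only")
    if pattern not in ("strict", "less_strict"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if nyha is NYHA.I:
        return (RAS,)
    base = (RAS, DrugClass.BETA_BLOCKER.value, DrugClass.DIURETIC.value)
    if pattern == "strict" and nyha in (NYHA.III, NYHA.IV):
        return base + (DrugClass.MRA.value,)
    return base


# ---------------------------------------------------------------------------
# episode construction
# ---------------------------------------------------------------------------

def build_episodes(
    dispensations: pd.DataFrame,
    *,
    gap_tolerance: int = GAP_TOLERANCE_DAYS,
    code_config: Optional[CodeConfig] = None,
    mra_counts_as_diuretic: bool = True,
    default_supply_days: int = 30,
) -> dict[str, list[CoverageEpisode]]:
    """Gap-bridged coverage episodes per drug-class track for ONE patient.

    Tracks are the five pattern classes plus the pooled ``RAS`` track.
    Combination products feed every constituent class; MRA dispensations
    also feed the diuretic track unless disabled.
    """
    cfg = code_config or default_code_config()
    fills: dict[str, list[tuple[pd.Timestamp, int]]] = {}
    for row in dispensations.itertuples(index=False):
        supply = getattr(row, "supply_days", None)
        if supply is None or pd.isna(supply):
            supply = default_supply_days
        supply = int(supply)
        if supply < 1:
            raise ValueError(f"supply_days must be >= 1, got {supply}")
        classes = cfg.classify_atc(str(row.atc_code))
        tracks: set[str] = set()
        for dc in classes:
            tracks.add(dc.value)
            if dc in (DrugClass.ACEI, DrugClass.ARB):
                tracks.add(RAS)
            if dc is DrugClass.MRA and mra_counts_as_diuretic:
                tracks.add(DrugClass.DIURETIC.value)
        date = pd.Timestamp(row.dispense_date)
        for t in tracks:
            fills.setdefault(t, []).append((date, supply))

    episodes: dict[str, list[CoverageEpisode]] = {}
    one_day = pd.Timedelta(days=1)
    for track, items in fills.items():
        items.sort(key=lambda x: x[0])
        eps: list[CoverageEpisode] = []
        cur_start = cur_end = None
        for date, supply in items:
            covered_end = date + pd.Timedelta(days=supply - 1)
            if cur_end is None:
                cur_start, cur_end = date, covered_end
                continue
            gap = (date - cur_end).days - 1  # uncovered days between
            if gap <= gap_tolerance:
                cur_end = max(cur_end, covered_end)
            else:
                eps.append(CoverageEpisode(track, cur_start, cur_end))
                cur_start, cur_end = date, covered_end
        if cur_end is not None:
            eps.append(CoverageEpisode(track, cur_start, cur_end))
        episodes[track] = eps
    return episodes


def _term_met(
    episodes: Sequence[CoverageEpisode],
    index_date: pd.Timestamp,
    censor_date: pd.Timestamp,
    gap_tolerance: int,
) -> bool:
    """Bridged coverage from index to censor with all gaps <= tolerance.

    The index date is a virtual covered day (initiation grace) and the censor
    date must lie within the tolerance of the last covered day.  Episodes are
    separated by more than the tolerance by construction, so the requirement
    reduces to a single episode satisfying both boundary conditions.
    """
    for ep in episodes:
        start_gap = (ep.start - index_date).days - 1  # uncovered days after index
        end_gap = (censor_date - ep.end).days  # days from last covered day to censor
        if start_gap <= gap_tolerance and end_gap <= gap_tolerance:
            return True
    return False


def _term_initiated(
    episodes: Sequence[CoverageEpisode],
    index_date: pd.Timestamp,
    censor_date: pd.Timestamp,
) -> bool:
    """First-quarter variant: any coverage within 90 days of the index date."""
    limit = min(index_date + pd.Timedelta(days=90), censor_date)
    return any(ep.start <= limit and ep.end >= index_date for ep in episodes)


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def classify_adherence(
    patient_id: str,
    nyha: NYHA,
    index_date,
    episodes: Mapping[str, Sequence[CoverageEpisode]],
    *,
    death_date=None,
    options: AdherenceOptions = AdherenceOptions(),
) -> AdherenceVerdict:
    """Strict / less-strict pattern verdicts for one cohort patient.

    Patients without a specific NYHA class are not assessable; they receive
    an excluded sentinel (both verdicts ``None``), not an error.
    """
    index_date = pd.Timestamp(index_date)
    window_end = index_date + pd.Timedelta(days=options.window_days)
    censor = window_end
    if death_date is not None and not pd.isna(death_date):
        censor = min(censor, pd.Timestamp(death_date))

    if nyha is NYHA.OTHER:
        return AdherenceVerdict(patient_id, nyha, None, None, censor, episodes)

    def met(track: str) -> bool:
        eps = episodes.get(track, ())
        if options.first_quarter_initiation:
            return _term_initiated(eps, index_date, censor)
        return _term_met(eps, index_date, censor, options.gap_tolerance)

    less = all(met(t) for t in required_classes(nyha, "less_strict"))
    # strict adds at most the MRA term, so evaluate incrementally
    strict = less and all(
        met(t) for t in required_classes(nyha, "strict") if t not in required_classes(nyha, "less_strict")
    )
    return AdherenceVerdict(patient_id, nyha, strict, less, censor, episodes)


def classify_bundle(
    cohort: pd.DataFrame,
    dispensations: pd.DataFrame,
    *,
    code_config: Optional[CodeConfig] = None,
    options: AdherenceOptions = AdherenceOptions(),
) -> pd.DataFrame:
    """Verdicts for every cohort patient; returns a tidy DataFrame.

    Columns: patient_id, nyha, eligible, strict, less_strict, censor_date.
    """
    cfg = code_config or default_code_config()
    disp = dispensations.copy()
    disp["patient_id"] = disp["patient_id"].astype(str)
    by_patient = dict(tuple(disp.groupby("patient_id")))
    empty = disp.iloc[0:0]

    rows = []
    for rec in cohort.itertuples(index=False):
        pid = str(rec.patient_id)
        nyha = NYHA(rec.nyha)
        eps = build_episodes(
            by_patient.get(pid, empty),
            gap_tolerance=options.gap_tolerance,
            code_config=cfg,
            mra_counts_as_diuretic=options.mra_counts_as_diuretic,
        )
        verdict = classify_adherence(
            pid,
            nyha,
            rec.index_date,
            eps,
            death_date=getattr(rec, "death_date", None),
            options=options,
        )
        rows.append(
            {
                "patient_id": pid,
                "nyha": nyha.value,
                "eligible": verdict.eligible,
                "strict": verdict.strict,
                "less_strict": verdict.less_strict,
                "censor_date": verdict.censor_date,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified summaries
# ---------------------------------------------------------------------------

def _share(num: int, den: int) -> float:
    return num / den if den else float("nan")


def stratify(verdicts: pd.DataFrame, cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Strict / less-strict shares by NYHA class, age band, sex,
    identification-year hospitalization, and death, plus outcome shares within
    adherent vs non-adherent groups.

    Empty strata report NaN shares, never zero.
    """
    merged = verdicts.merge(
        cohort[
            ["patient_id", "age_band", "sex", "hospitalized_in_id_year", "died_in_study"]
        ],
        on="patient_id",
        how="left",
    )
    eligible = merged[merged["eligible"].astype(bool)].copy()

    def by(col: str) -> pd.DataFrame:
        rows = []
        for value, grp in eligible.groupby(col, dropna=False):
            n = len(grp)
            rows.append(
                {
                    col: value,
                    "n": n,
                    "strict_n": int(grp["strict"].sum()),
                    "strict_share": _share(int(grp["strict"].sum()), n),
                    "less_strict_n": int(grp["less_strict"].sum()),
                    "less_strict_share": _share(int(grp["less_strict"].sum()), n),
                }
            )
        return pd.DataFrame(rows)

    out = {
        "overall": pd.DataFrame(
            [
                {
                    "n": len(eligible),
                    "strict_n": int(eligible["strict"].sum()),
                    "strict_share": _share(int(eligible["strict"].sum()), len(eligible)),
                    "less_strict_n": int(eligible["less_strict"].sum()),
                    "less_strict_share": _share(
                        int(eligible["less_strict"].sum()), len(eligible)
                    ),
                }
            ]
        ),
        "by_nyha": by("nyha"),
        "by_age_band": by("age_band"),
        "by_sex": by("sex"),
        "by_hospitalized": by("hospitalized_in_id_year"),
        "by_died": by("died_in_study"),
    }

    # outcome shares within strict-adherent vs non-adherent patients
    rows = []
    for label, grp in (
        ("strict_adherent", eligible[eligible["strict"] == True]),  # noqa: E712
        ("not_strict_adherent", eligible[eligible["strict"] == False]),  # noqa: E712
    ):
        n = len(grp)
        rows.append(
            {
                "group": label,
                "n": n,
                "hospitalized_share": _share(int(grp["hospitalized_in_id_year"].sum()), n),
                "died_share": _share(int(grp["died_in_study"].sum()), n),
            }
        )
    out["outcomes_by_adherence"] = pd.DataFrame(rows)
    return out
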