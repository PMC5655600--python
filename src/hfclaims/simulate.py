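"""Synthetic SHI-claims generator with per-patient ground truth.

The generator emulates the statistical structure the analysis assumes: a
five-year observability window around an identification year, a prevalent
heart-failure cohort defined by >=2 coded diagnoses in that year, an
incident subgroup with a clean four-quarter washout, an NYHA-coded severity
mix, class-dependent prescription persistence, mortality, hospitalization,
and a configurable sector/specialty mix for diagnoses and activities.

Dispensation streams are written *constructively from the adherence label*:
a patient drawn adherent receives refill streams whose gaps never exceed the
tolerance by construction, while a non-adherent patient either lacks a
required drug class entirely, starts it too late, or has exactly one
super-threshold gap.  This makes the ground-truth table a sharp oracle for
the adherence engine (the two share the episode semantics).

Everything is driven by one ``numpy.random.default_rng`` seed, so a fixed
config reproduces byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .claims import ClaimsBundle
from .codes import NYHA

__all__ = ["SimulationConfig", "ConfigError", "generate", "preset_paperlike"]


class ConfigError(ValueError):
    pass


# representative single-substance ATC codes per pattern class
ATC_ACEI = "C09AA02"  # enalapril
ATC_ARB = "C09CA01"  # losartan
ATC_BETA_BLOCKER = "C07AB02"  # metoprolol
ATC_DIURETIC = "C03CA01"  # furosemide
ATC_MRA = "C03DA01"  # spironolactone

OTHER_CV_POOL = ["C08CA01", "C10AA01", "B01AC06"]  # amlodipine, simvastatin, ASA
BACKGROUND_ATC_POOL = ["C10AA01", "N02BE01", "A02BC01", "C08CA01", "C07AB02"]
BACKGROUND_ICD_POOL = ["I10", "E11.9", "J45.9", "M54.5", "E78.0"]

GENERIC_HF_CODES = ["I50.9", "I50.1", "I50.19", "I11.0", "I50.01", "I50.0", "I13.0"]
GENERIC_HF_WEIGHTS = [0.35, 0.20, 0.15, 0.15, 0.05, 0.05, 0.05]
NYHA_CODE = {"I": "I50.11", "II": "I50.12", "III": "I50.13", "IV": "I50.14"}


def _dist(d: dict) -> tuple[list, np.ndarray]:
    keys = list(d)
    probs = np.asarray([d[k] for k in keys], dtype=float)
    return keys, probs / probs.sum()


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic claims bundle.

    All fractions are probabilities in [0, 1]; the NYHA distribution must sum
    to 1.  ``gap_day_distribution`` gives the (low, high) bounds of the
    uniform uncovered-day gap between adherent refills and must stay at or
    below ``gap_tolerance`` so constructive adherence labels remain exact.
    """

    n_patients: int = 25_000
    identification_year: int = 2011
    seed: int = 0

    # population structure
    observable_fraction: float = 0.766
    hf_prevalence: float = 0.0396
    incident_fraction: float = 0.213
    female_fraction_hf: float = 0.54

    # severity coding
    nyha_coded_fraction: float = 0.209
    nyha_distribution: dict = field(
        default_factory=lambda: {"I": 0.136, "II": 0.425, "III": 0.311, "IV": 0.128}
    )

    # treatment-pattern adherence (per NYHA class, strict pattern)
    adherence_prob_strict: dict = field(
        default_factory=lambda: {"I": 0.62, "II": 0.56, "III": 0.33, "IV": 0.211}
    )
    #: P(MRA given | class III-IV patient meets the less-strict pattern);
    #: determines the less-strict probability as strict / mra_given_eligible.
    mra_given_eligible: float = 0.3955
    ras_switch_prob: float = 0.2

    # dispensation mechanics
    gap_day_distribution: tuple = (0, 60)
    supply_days: int = 30
    gap_tolerance: int = 90
    window_days: int = 730

    # outcomes
    annual_mortality: float = 0.06
    hospitalization_prob: float = 0.64

    # diagnosing sector / specialty
    ambulatory_dx_fraction: float = 0.632
    hospital_outpatient_dx_fraction: float = 0.002
    family_practice_dx_fraction: float = 0.616
    ambulatory_dx_specialty: dict = field(
        default_factory=lambda: {"CARDIOLOGY": 0.148, "OTHER_INTERNAL_MEDICINE": 0.12, "OTHER": 0.116}
    )
    inpatient_dx_specialty: dict = field(
        default_factory=lambda: {
            "CARDIOLOGY": 0.193,
            "OTHER_INTERNAL_MEDICINE": 0.54,
            "SURGERY": 0.12,
            "OTHER": 0.147,
        }
    )
    outpatient_dx_specialty: dict = field(
        default_factory=lambda: {"CARDIOLOGY": 0.3, "OTHER_INTERNAL_MEDICINE": 0.4, "OTHER": 0.3}
    )

    # follow-up contacts and activities
    office_contact_prob: float = 0.98
    inpatient_contact_prob: float = 0.15
    outpatient_contact_prob: float = 0.045
    echo_prob: float = 0.37
    tech_rate_per_year: float = 0.55
    ambulatory_tech_fraction: float = 0.83
    amb_tech_mix: dict = field(
        default_factory=lambda: {
            "CARDIOLOGY": 0.607,
            "OTHER_INTERNAL_MEDICINE": 0.256,
            "FAMILY_PRACTICE": 0.10,
            "OTHER": 0.037,
        }
    )
    hosp_tech_mix: dict = field(
        default_factory=lambda: {
            "CARDIOLOGY": 0.50,
            "OTHER_INTERNAL_MEDICINE": 0.325,
            "SURGERY": 0.08,
            "OTHER": 0.095,
        }
    )
    amb_treat_mix: dict = field(
        default_factory=lambda: {
            "FAMILY_PRACTICE": 0.885,
            "CARDIOLOGY": 0.035,
            "OTHER_INTERNAL_MEDICINE": 0.045,
            "OTHER": 0.035,
        }
    )
    hosp_treat_mix: dict = field(
        default_factory=lambda: {
            "CARDIOLOGY": 0.331,
            "OTHER_INTERNAL_MEDICINE": 0.247,
            "SURGERY": 0.301,
            "OTHER": 0.121,
        }
    )

    # negatives
    background_hf_code_prob: float = 0.03
    background_annual_mortality: float = 0.02

    # ------------------------------------------------------------------
    def validate(self) -> None:
        fracs = {
            "observable_fraction": self.observable_fraction,
            "hf_prevalence": self.hf_prevalence,
            "incident_fraction": self.incident_fraction,
            "nyha_coded_fraction": self.nyha_coded_fraction,
            "mra_given_eligible": self.mra_given_eligible,
            "annual_mortality": self.annual_mortality,
            "hospitalization_prob": self.hospitalization_prob,
            "ambulatory_dx_fraction": self.ambulatory_dx_fraction,
            "hospital_outpatient_dx_fraction": self.hospital_outpatient_dx_fraction,
            "family_practice_dx_fraction": self.family_practice_dx_fraction,
            "office_contact_prob": self.office_contact_prob,
            "echo_prob": self.echo_prob,
            "background_hf_code_prob": self.background_hf_code_prob,
        }
        for name, value in fracs.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for cls, p in self.adherence_prob_strict.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigError(f"adherence_prob_strict[{cls}] must be in [0, 1]")
        total = sum(self.nyha_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"nyha_distribution must sum to 1, got {total}")
        if self.ambulatory_dx_fraction + self.hospital_outpatient_dx_fraction > 1.0:
            raise ConfigError("diagnosing-sector fractions exceed 1")
        lo, hi = self.gap_day_distribution
        if not (0 <= lo <= hi):
            raise ConfigError("gap_day_distribution bounds must satisfy 0 <= low <= high")
        if hi > self.gap_tolerance:
            raise ConfigError("gap_day_distribution high bound must not exceed gap_tolerance")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if self.supply_days < 1:
            raise ConfigError("supply_days must be >= 1")
        if self.window_days < 1:
            raise ConfigError("window_days must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_day_distribution"] = list(self.gap_day_distribution)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "gap_day_distribution" in d:
            d["gap_day_distribution"] = tuple(d["gap_day_distribution"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def study_start(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.identification_year - 2}-01-01")

    @property
    def study_end(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.identification_year + 2}-12-31")

    def less_strict_prob(self, nyha: str) -> float:
        """Per-class probability of meeting the less-strict pattern."""
        p = float(self.adherence_prob_strict[nyha])
        if nyha in ("III", "IV"):
            return min(1.0, p / self.mra_given_eligible) if self.mra_given_eligible > 0 else 1.0
        return p


def preset_paperlike(n_patients: int = 25_000, seed: int = 0) -> SimulationConfig:
    """The documented preset: defaults calibrated to the published study's
    printed marginals (incident share 21.3%, ambulatory diagnoses 63.2%,
    family practice 61.6%, NYHA mix 13.6/42.5/31.1/12.8%, overall strict
    adherence ~45.1% and less-strict ~65.0%)."""
    return SimulationConfig(n_patients=n_patients, seed=seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_DAY = pd.Timedelta(days=1)


def _rand_date(rng, start: pd.Timestamp, end: pd.Timestamp) -> pd.Timestamp:
    span = (end - start).days
    return start + pd.Timedelta(days=int(rng.integers(0, span + 1))) if span > 0 else start


def _choice(rng, mix: dict) -> str:
    keys, probs = _dist(mix)
    return keys[int(rng.choice(len(keys), p=probs))]


class _Builder:
    """Accumulates event rows for one bundle."""

    def __init__(self):
        self.patients: list[dict] = []
        self.diagnoses: list[dict] = []
        self.dispensations: list[dict] = []
        self.activities: list[dict] = []
        self.truth: list[dict] = []

    def patient(self, **kw):
        self.patients.append(kw)

    def dx(self, pid, date, code, sector, specialty):
        self.diagnoses.append(
            {
                "patient_id": pid,
                "event_date": date,
                "icd_code": code,
                "sector": sector,
                "provider_specialty": specialty,
            }
        )

    def rx(self, pid, date, atc, supply):
        self.dispensations.append(
            {"patient_id": pid, "dispense_date": date, "atc_code": atc, "supply_days": int(supply)}
        )

    def act(self, pid, date, kind, sector, specialty, echo=False):
        self.activities.append(
            {
                "patient_id": pid,
                "event_date": date,
                "activity_kind": kind,
                "is_echocardiography": bool(echo),
                "sector": sector,
                "provider_specialty": specialty,
            }
        )


def _refill_stream(rng, cfg: SimulationConfig, first_fill, censor) -> list[pd.Timestamp]:
    """Fill dates whose bridged coverage runs from first_fill to the censor
    date with every uncovered gap <= gap_tolerance (gaps drawn from the
    configured uniform bounds, which validate() caps at the tolerance)."""
    if first_fill > censor:
        return []
    lo, hi = cfg.gap_day_distribution
    fills = []
    fill = pd.Timestamp(first_fill)
    while True:
        fills.append(fill)
        covered_end = fill + pd.Timedelta(days=cfg.supply_days - 1)
        if covered_end >= censor:
            break
        nxt = covered_end + _DAY + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
        if nxt > censor:
            break  # remaining tail is at most one gap, i.e. <= tolerance
        fill = nxt
    return fills


def _covered_stream(rng, cfg, index_date, censor) -> list[pd.Timestamp]:
    first = index_date + pd.Timedelta(days=int(rng.integers(0, 15)))
    return _refill_stream(rng, cfg, first, censor)


def _violating_stream(rng, cfg, index_date, censor) -> list[pd.Timestamp]:
    """A stream guaranteed to fail the pattern term for this class.

    Long windows get a single super-threshold mid-window gap; short windows
    (or by chance) get a start later than the initiation grace allows.
    """
    window = (censor - index_date).days
    if window >= 240 and rng.random() < 0.6:
        # piece 1 covers the first third, then one gap > tolerance
        mid = index_date + pd.Timedelta(days=window // 3)
        piece1 = _covered_stream(rng, cfg, index_date, mid)
        p1_end = piece1[-1] + pd.Timedelta(days=cfg.supply_days - 1)
        restart = p1_end + pd.Timedelta(days=cfg.gap_tolerance + int(rng.integers(25, 71)) + 1)
        piece2 = _refill_stream(rng, cfg, restart, censor)
        return piece1 + piece2
    late = index_date + pd.Timedelta(days=cfg.gap_tolerance + int(rng.integers(30, 121)))
    return _refill_stream(rng, cfg, late, censor)


def _emit_class_stream(b, rng, cfg, pid, atc, dates):
    for d in dates:
        b.rx(pid, d, atc, cfg.supply_days)


def _emit_ras(b, rng, cfg, pid, dates):
    """RAS-blocker fills; some patients switch ACEI <-> ARB mid-stream, which
    must keep the pooled track continuous."""
    if not dates:
        return
    first, second = (ATC_ACEI, ATC_ARB) if rng.random() < 0.5 else (ATC_ARB, ATC_ACEI)
    if len(dates) >= 3 and rng.random() < cfg.ras_switch_prob:
        split = int(rng.integers(1, len(dates)))
        for d in dates[:split]:
            b.rx(pid, d, first, cfg.supply_days)
        for d in dates[split:]:
            b.rx(pid, d, second, cfg.supply_days)
    else:
        for d in dates:
            b.rx(pid, d, first, cfg.supply_days)


_CLASS_ATC = {
    "RAS": None,  # handled by _emit_ras
    "BETA_BLOCKER": ATC_BETA_BLOCKER,
    "DIURETIC": ATC_DIURETIC,
    "MRA": ATC_MRA,
}


def _required_less(nyha: str) -> list[str]:
    return ["RAS"] if nyha == "I" else ["RAS", "BETA_BLOCKER", "DIURETIC"]


def _hf_patient(b: _Builder, rng, cfg: SimulationConfig, pid: str) -> None:
    year = cfg.identification_year
    sex = "F" if rng.random() < cfg.female_fraction_hf else "M"
    age = int(np.clip(round(rng.normal(74, 11)), 35, 99))
    birth_year = year - age

    # index diagnosis in Jan-Nov so a later same-year diagnosis always fits
    index_date = _rand_date(rng, pd.Timestamp(f"{year}-01-01"), pd.Timestamp(f"{year}-11-30"))
    iq = pd.Period(index_date, freq="Q")

    died = rng.random() < 1 - (1 - cfg.annual_mortality) ** 2
    death_date = index_date + pd.Timedelta(days=int(rng.integers(30, cfg.window_days + 1))) if died else pd.NaT
    censor = min(index_date + pd.Timedelta(days=cfg.window_days), death_date) if died else index_date + pd.Timedelta(days=cfg.window_days)
    coverage_end = death_date if died else cfg.study_end

    incident = rng.random() < cfg.incident_fraction
    nyha = "OTHER"
    if rng.random() < cfg.nyha_coded_fraction:
        keys, probs = _dist(cfg.nyha_distribution)
        nyha = keys[int(rng.choice(len(keys), p=probs))]

    # --- diagnosing sector / specialty of the index event ---
    u = rng.random()
    if u < cfg.ambulatory_dx_fraction:
        sector = "AMBULATORY"
        if rng.random() < cfg.family_practice_dx_fraction:
            specialty = "FAMILY_PRACTICE"
        else:
            mix = dict(cfg.ambulatory_dx_specialty)
            specialty = _choice(rng, mix)
    elif u < cfg.ambulatory_dx_fraction + cfg.hospital_outpatient_dx_fraction:
        sector = "HOSPITAL_OUTPATIENT"
        specialty = _choice(rng, cfg.outpatient_dx_specialty)
    else:
        sector = "HOSPITAL_INPATIENT"
        specialty = _choice(rng, cfg.inpatient_dx_specialty)
    index_sector = sector

    # --- diagnosis events ---
    def generic_code():
        return GENERIC_HF_CODES[int(rng.choice(len(GENERIC_HF_CODES), p=GENERIC_HF_WEIGHTS))]

    def dx_sector_specialty():
        v = rng.random()
        if v < 0.75:
            s = "AMBULATORY"
            sp = (
                "FAMILY_PRACTICE"
                if rng.random() < cfg.family_practice_dx_fraction
                else _choice(rng, cfg.ambulatory_dx_specialty)
            )
        elif v < 0.98:
            s = "HOSPITAL_INPATIENT"
            sp = _choice(rng, cfg.inpatient_dx_specialty)
        else:
            s = "HOSPITAL_OUTPATIENT"
            sp = _choice(rng, cfg.outpatient_dx_specialty)
        return s, sp

    last_dx_day = min(pd.Timestamp(f"{year}-12-31"), censor)
    n_extra = 1 + int(rng.poisson(1.5))
    extra_dates = [
        _rand_date(rng, index_date + _DAY, last_dx_day) for _ in range(n_extra)
    ]
    year_events = [(index_date, sector, specialty)] + [
        (d, *dx_sector_specialty()) for d in sorted(extra_dates)
    ]

    codes = [generic_code() for _ in year_events]
    if nyha != "OTHER":
        # every class-specific code carries the true class; force at least one
        marked = [i for i in range(len(codes)) if rng.random() < 0.6]
        if not marked:
            marked = [len(codes) - 1]
        for i in marked:
            codes[i] = NYHA_CODE[nyha]
    for (d, s, sp), code in zip(year_events, codes):
        b.dx(pid, d, code, s, sp)

    if not incident:
        # pre-index HF diagnoses: inside the washout (the four quarters before
        # the index quarter) but strictly before the identification year, so
        # the first in-year diagnosis remains the index event
        last_allowed = pd.Period(f"{year - 1}Q4", freq="Q")
        choices = [iq - k for k in range(1, 5) if iq - k <= last_allowed]
        for _ in range(1 + int(rng.poisson(0.8))):
            wq = choices[int(rng.integers(0, len(choices)))]
            d = _rand_date(rng, wq.start_time, wq.end_time.normalize())
            s, sp = dx_sector_specialty()
            b.dx(pid, d, generic_code(), s, sp)

    # --- quarterly contact activities over 8 follow-up quarters ---
    for k in range(8):
        q = iq + k
        qstart = q.start_time
        qend = min(q.end_time.normalize(), coverage_end if died else cfg.study_end)
        if died and qstart > death_date:
            break
        if qend < qstart:
            continue
        if rng.random() < cfg.office_contact_prob:
            b.act(pid, _rand_date(rng, qstart, qend), "TREATMENT", "AMBULATORY", _choice(rng, cfg.amb_treat_mix))
        if rng.random() < cfg.inpatient_contact_prob:
            b.act(pid, _rand_date(rng, qstart, qend), "TREATMENT", "HOSPITAL_INPATIENT", _choice(rng, cfg.hosp_treat_mix))
        if rng.random() < cfg.outpatient_contact_prob:
            b.act(pid, _rand_date(rng, qstart, qend), "TREATMENT", "HOSPITAL_OUTPATIENT", _choice(rng, cfg.hosp_treat_mix))

    # extra identification-year hospitalization toward the configured rate
    p_inpt_dx = 1 - cfg.ambulatory_dx_fraction - cfg.hospital_outpatient_dx_fraction
    p_extra = max(0.0, (cfg.hospitalization_prob - p_inpt_dx) / (1 - p_inpt_dx)) if p_inpt_dx < 1 else 0.0
    if index_sector != "HOSPITAL_INPATIENT" and rng.random() < p_extra:
        d = _rand_date(rng, index_date, min(pd.Timestamp(f"{year}-12-31"), censor))
        b.act(pid, d, "TREATMENT", "HOSPITAL_INPATIENT", _choice(rng, cfg.hosp_treat_mix))

    # --- technical diagnostics and echocardiography ---
    alive_days = (censor - index_date).days
    n_tech = int(rng.poisson(cfg.tech_rate_per_year * alive_days / 365.0))
    for _ in range(n_tech):
        d = _rand_date(rng, index_date, censor)
        if rng.random() < cfg.ambulatory_tech_fraction:
            b.act(pid, d, "TECHNICAL_DIAGNOSTIC", "AMBULATORY", _choice(rng, cfg.amb_tech_mix))
        else:
            b.act(pid, d, "TECHNICAL_DIAGNOSTIC", "HOSPITAL_INPATIENT", _choice(rng, cfg.hosp_tech_mix))
    if rng.random() < cfg.echo_prob:
        d = _rand_date(rng, index_date, censor)
        s = "AMBULATORY" if rng.random() < 0.6 else "HOSPITAL_INPATIENT"
        b.act(pid, d, "TECHNICAL_DIAGNOSTIC", s, "CARDIOLOGY", echo=True)

    # --- dispensations, constructive from the adherence label ---
    strict: Optional[bool] = None
    less: Optional[bool] = None
    if nyha != "OTHER":
        p_strict = float(cfg.adherence_prob_strict[nyha])
        p_less = cfg.less_strict_prob(nyha)
        u = rng.random()
        strict = u < p_strict
        less = u < p_less  # nested draw: strict => less_strict by construction

        required = _required_less(nyha)
        covered = list(required)
        violate: Optional[str] = None
        if not less:
            violate = required[int(rng.integers(0, len(required)))]
            if rng.random() < 0.5:
                covered.remove(violate)  # drop the class entirely
                mode = "drop"
            else:
                mode = "gap"
        else:
            mode = "none"

        for track in covered:
            if track == violate and mode == "gap":
                dates = _violating_stream(rng, cfg, index_date, censor)
            else:
                dates = _covered_stream(rng, cfg, index_date, censor)
            if track == "RAS":
                _emit_ras(b, rng, cfg, pid, dates)
            else:
                _emit_class_stream(b, rng, cfg, pid, _CLASS_ATC[track], dates)
        if strict and nyha in ("III", "IV"):
            _emit_class_stream(
                b, rng, cfg, pid, ATC_MRA, _covered_stream(rng, cfg, index_date, censor)
            )
    else:
        # uncoded HF: sporadic cardiovascular therapy, no continuity guarantee
        for atc in (ATC_ACEI, ATC_BETA_BLOCKER, ATC_DIURETIC):
            if rng.random() < 0.5:
                for _ in range(int(rng.integers(2, 7))):
                    b.rx(pid, _rand_date(rng, index_date, censor), atc, cfg.supply_days)

    for _ in range(int(rng.integers(0, 3))):
        atc = OTHER_CV_POOL[int(rng.integers(0, len(OTHER_CV_POOL)))]
        b.rx(pid, _rand_date(rng, index_date, censor), atc, cfg.supply_days)

    b.patient(
        patient_id=pid,
        sex=sex,
        birth_year=birth_year,
        coverage_start=cfg.study_start,
        coverage_end=coverage_end,
        death_date=death_date,
    )
    b.truth.append(
        {
            "patient_id": pid,
            "is_hf": True,
            "incident": incident,
            "nyha": nyha,
            "strict": strict,
            "less_strict": less,
            "index_date": index_date,
            "index_sector": index_sector,
            "death_date": death_date,
        }
    )


def _background_patient(b: _Builder, rng, cfg: SimulationConfig, pid: str, observable: bool) -> None:
    year = cfg.identification_year
    sex = "F" if rng.random() < 0.51 else "M"
    birth_year = year - int(rng.integers(18, 96))

    if observable:
        coverage_start = cfg.study_start
        died = rng.random() < 1 - (1 - cfg.background_annual_mortality) ** 3
        death_date = _rand_date(rng, pd.Timestamp(f"{year}-01-01"), cfg.study_end) if died else pd.NaT
        coverage_end = death_date if died else cfg.study_end
    elif rng.random() < 0.5:
        # enrolled too late to be observable over the full window
        coverage_start = _rand_date(rng, cfg.study_start + _DAY, pd.Timestamp(f"{year}-12-31"))
        death_date = pd.NaT
        coverage_end = cfg.study_end
    else:
        # died before the identification year
        coverage_start = cfg.study_start
        death_date = _rand_date(rng, cfg.study_start, pd.Timestamp(f"{year - 1}-12-31"))
        coverage_end = death_date

    first = coverage_start
    last = coverage_end

    for _ in range(int(rng.poisson(1.5))):
        code = BACKGROUND_ICD_POOL[int(rng.integers(0, len(BACKGROUND_ICD_POOL)))]
        b.dx(pid, _rand_date(rng, first, last), code, "AMBULATORY", "FAMILY_PRACTICE")
    if observable and rng.random() < cfg.background_hf_code_prob:
        # a single HF code must NOT qualify for the cohort (>=2 rule)
        lo = max(first, pd.Timestamp(f"{year}-01-01"))
        hi = min(last, pd.Timestamp(f"{year}-12-31"))
        if lo <= hi:
            b.dx(pid, _rand_date(rng, lo, hi), "I50.9", "AMBULATORY", "FAMILY_PRACTICE")
    for _ in range(int(rng.poisson(2.0))):
        atc = BACKGROUND_ATC_POOL[int(rng.integers(0, len(BACKGROUND_ATC_POOL)))]
        b.rx(pid, _rand_date(rng, first, last), atc, cfg.supply_days)
    for _ in range(int(rng.poisson(2.0))):
        b.act(pid, _rand_date(rng, first, last), "TREATMENT", "AMBULATORY", "FAMILY_PRACTICE")

    b.patient(
        patient_id=pid,
        sex=sex,
        birth_year=birth_year,
        coverage_start=coverage_start,
        coverage_end=coverage_end,
        death_date=death_date,
    )
    b.truth.append(
        {
            "patient_id": pid,
            "is_hf": False,
            "incident": pd.NA,
            "nyha": "",
            "strict": pd.NA,
            "less_strict": pd.NA,
            "index_date": pd.NaT,
            "index_sector": "",
            "death_date": death_date,
        }
    )


def generate(config: SimulationConfig) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle and its ground-truth table.

    Determinism: the whole bundle derives from one ``default_rng(seed)``
    stream walked in fixed patient order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    b = _Builder()

    for i in range(config.n_patients):
        pid = f"P{i:07d}"
        observable = rng.random() < config.observable_fraction
        if observable and rng.random() < config.hf_prevalence:
            _hf_patient(b, rng, config, pid)
        else:
            _background_patient(b, rng, config, pid, observable)

    patients = pd.DataFrame(b.patients)
    diagnoses = pd.DataFrame(
        b.diagnoses, columns=["patient_id", "event_date", "icd_code", "sector", "provider_specialty"]
    )
    dispensations = pd.DataFrame(
        b.dispensations, columns=["patient_id", "dispense_date", "atc_code", "supply_days"]
    )
    activities = pd.DataFrame(
        b.activities,
        columns=["patient_id", "event_date", "activity_kind", "is_echocardiography", "sector", "provider_specialty"],
    )
    truth = pd.DataFrame(b.truth)

    # hospitalization ground truth from what was actually emitted
    inpat: set[str] = set()
    for df, col in ((diagnoses, "event_date"), (activities, "event_date")):
        if len(df):
            mask = (df["sector"] == "HOSPITAL_INPATIENT") & (
                pd.to_datetime(df[col]).dt.year == config.identification_year
            )
            inpat |= set(df.loc[mask, "patient_id"])
    truth["hospitalized"] = truth["patient_id"].isin(inpat)

    for df, col in ((diagnoses, "event_date"), (dispensations, "dispense_date"), (activities, "event_date")):
        if len(df):
            df[col] = pd.to_datetime(df[col])
    for col in ("coverage_start", "coverage_end", "death_date"):
        patients[col] = pd.to_datetime(patients[col])

    metadata = {
        "generator": "hfclaims.simulate",
        "identification_year": config.identification_year,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    bundle = ClaimsBundle(patients, diagnoses, dispensations, activities, metadata)
    return bundle, truth
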