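"""Claims record schema, validation, and bundle I/O.

A :class:`ClaimsBundle` is the unit of pipeline input: four linked tables
(patients, diagnoses, dispensations, activities) plus a metadata mapping.
Tables are pandas DataFrames with ISO-8601 dates parsed to ``datetime64``;
on disk they are plain UTF-8 CSV files with a header row and a YAML metadata
sidecar, so a bundle round-trips bit-exactly.

Validation is total: any malformed input yields a :class:`SchemaError`
listing every offending file/row rather than a bare traceback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .codes import Sector, Specialty

__all__ = [
    "ClaimsBundle",
    "SchemaError",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "TABLE_FILES",
]

#: on-disk file name per table attribute
TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "dispensations": "dispensations.csv",
    "activities": "activities.csv",
}
METADATA_FILE = "metadata.yaml"

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "coverage_start", "coverage_end", "death_date"]
DIAGNOSIS_COLUMNS = ["patient_id", "event_date", "icd_code", "sector", "provider_specialty"]
DISPENSATION_COLUMNS = ["patient_id", "dispense_date", "atc_code", "supply_days"]
ACTIVITY_COLUMNS = ["patient_id", "event_date", "activity_kind", "is_echocardiography", "sector", "provider_specialty"]

_COLUMNS = {
    "patients": PATIENT_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "dispensations": DISPENSATION_COLUMNS,
    "activities": ACTIVITY_COLUMNS,
}
_DATE_COLUMNS = {
    "patients": ["coverage_start", "coverage_end", "death_date"],
    "diagnoses": ["event_date"],
    "dispensations": ["dispense_date"],
    "activities": ["event_date"],
}

ACTIVITY_KINDS = ("TECHNICAL_DIAGNOSTIC", "TREATMENT")


class SchemaError(ValueError):
    """Raised when a bundle violates the documented schema; carries all issues."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues[:20]) + ("" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"))


@dataclass
class ClaimsBundle:
    """Four linked claims tables plus provenance metadata."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    activities: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def identification_year(self) -> int | None:
        year = self.metadata.get("identification_year")
        return int(year) if year is not None else None

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.diagnoses.copy(),
            self.dispensations.copy(),
            self.activities.copy(),
            dict(self.metadata),
        )


def empty_bundle(metadata: dict | None = None) -> ClaimsBundle:
    """A valid bundle with zero rows in every table."""
    tables = {}
    for name, cols in _COLUMNS.items():
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
        for c in _DATE_COLUMNS[name]:
            df[c] = pd.Series(dtype="datetime64[ns]")
        tables[name] = df
    return ClaimsBundle(metadata=dict(metadata or {}), **tables)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: ClaimsBundle, *, max_issues: int = 1000) -> list[str]:
    """Return a list of human-readable schema violations (empty when valid).

    Every message names the table and the 0-based row of the offending record.
    """
    issues: list[str] = []

    def add(msg: str) -> None:
        if len(issues) < max_issues:
            issues.append(msg)

    for name, cols in _COLUMNS.items():
        df = bundle.table(name)
        missing = [c for c in cols if c not in df.columns]
        for c in missing:
            add(f"{name}: missing column {c!r}")
    if issues:
        return issues

    pat = bundle.patients
    known_ids = set(pat["patient_id"].astype(str))
    if pat["patient_id"].duplicated().any():
        for row in pat.index[pat["patient_id"].duplicated()]:
            add(f"patients row {row}: duplicate patient_id {pat.at[row, 'patient_id']!r}")

    bad_sex = ~pat["sex"].isin(["M", "F"])
    for row in pat.index[bad_sex]:
        add(f"patients row {row}: sex must be M or F, got {pat.at[row, 'sex']!r}")

    bad_span = pat["coverage_start"] > pat["coverage_end"]
    for row in pat.index[bad_span.fillna(False)]:
        add(f"patients row {row}: coverage_start after coverage_end")

    has_death = pat["death_date"].notna()
    out_of_cov = has_death & (
        (pat["death_date"] < pat["coverage_start"]) | (pat["death_date"] > pat["coverage_end"])
    )
    for row in pat.index[out_of_cov]:
        add(f"patients row {row}: death_date outside coverage interval")

    sectors = {s.value for s in Sector}
    specialties = {s.value for s in Specialty}

    for name in ("diagnoses", "activities"):
        df = bundle.table(name)
        for row in df.index[~df["patient_id"].astype(str).isin(known_ids)]:
            add(f"{name} row {row}: orphan patient_id {df.at[row, 'patient_id']!r}")
        for row in df.index[~df["sector"].isin(sectors)]:
            add(f"{name} row {row}: unknown sector {df.at[row, 'sector']!r}")
        for row in df.index[~df["provider_specialty"].isin(specialties)]:
            add(f"{name} row {row}: unknown specialty {df.at[row, 'provider_specialty']!r}")
        for row in df.index[df["event_date"].isna()]:
            add(f"{name} row {row}: unparseable or missing event_date")

    disp = bundle.dispensations
    for row in disp.index[~disp["patient_id"].astype(str).isin(known_ids)]:
        add(f"dispensations row {row}: orphan patient_id {disp.at[row, 'patient_id']!r}")
    supply = pd.to_numeric(disp["supply_days"], errors="coerce")
    for row in disp.index[~(supply >= 1)]:
        add(f"dispensations row {row}: supply_days must be a positive integer")
    for row in disp.index[disp["dispense_date"].isna()]:
        add(f"dispensations row {row}: unparseable or missing dispense_date")

    act = bundle.activities
    bad_kind = ~act["activity_kind"].isin(ACTIVITY_KINDS)
    for row in act.index[bad_kind]:
        add(f"activities row {row}: unknown activity_kind {act.at[row, 'activity_kind']!r}")
    echo = act["is_echocardiography"].astype(bool) & (act["activity_kind"] != "TECHNICAL_DIAGNOSTIC")
    for row in act.index[echo]:
        add(f"activities row {row}: echocardiography must be a TECHNICAL_DIAGNOSTIC activity")

    # event dates must fall inside the patient's coverage interval
    cov = pat.set_index(pat["patient_id"].astype(str))[["coverage_start", "coverage_end"]]
    for name, date_col in (("diagnoses", "event_date"), ("dispensations", "dispense_date"), ("activities", "event_date")):
        df = bundle.table(name)
        ids = df["patient_id"].astype(str)
        linked = ids.isin(known_ids) & df[date_col].notna()
        if not linked.any():
            continue
        sub = df.loc[linked]
        starts = cov["coverage_start"].reindex(ids[linked]).to_numpy()
        ends = cov["coverage_end"].reindex(ids[linked]).to_numpy()
        dates = sub[date_col].to_numpy()
        outside = (dates < starts) | (dates > ends)
        for row in sub.index[outside]:
            add(f"{name} row {row}: {date_col} outside patient coverage interval")

    return issues


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_dates(df: pd.DataFrame, table: str, issues: list[str]) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for row in df.index[bad]:
            issues.append(f"{table} row {row}: unparseable date {raw[row]!r} in {col}")
        df[col] = parsed
    return df


def read_bundle(directory: Path | str | Mapping[str, Path | str], *, validate: bool = True) -> ClaimsBundle:
    """Read a bundle from a directory (or an explicit table->path mapping).

    Raises :class:`SchemaError` naming every offending file and row when the
    files violate the documented schema.
    """
    if isinstance(directory, Mapping):
        paths = {name: Path(p) for name, p in directory.items()}
        meta_path = None
    else:
        root = Path(directory)
        paths = {name: root / fname for name, fname in TABLE_FILES.items()}
        meta_path = root / METADATA_FILE

    issues: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing bundle file: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str, "icd_code": str, "atc_code": str})
        missing = [c for c in _COLUMNS[name] if c not in df.columns]
        if missing:
            issues.append(f"{name}: missing column(s) {missing} in {path.name}")
            continue
        df = _parse_dates(df, name, issues)
        if "supply_days" in df.columns:
            df["supply_days"] = pd.to_numeric(df["supply_days"], errors="coerce")
        if "is_echocardiography" in df.columns:
            df["is_echocardiography"] = df["is_echocardiography"].astype(bool)
        if "birth_year" in df.columns:
            df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce").astype("Int64")
        tables[name] = df
    if issues:
        raise SchemaError(issues)

    metadata: dict = {}
    if meta_path is not None and meta_path.exists():
        metadata = yaml.safe_load(meta_path.read_text()) or {}

    bundle = ClaimsBundle(metadata=metadata, **tables)
    if validate:
        problems = validate_bundle(bundle)
        if problems:
            raise SchemaError(problems)
    return bundle


def _format_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = df.copy()
    for col in _DATE_COLUMNS[table]:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    return out


def write_bundle(bundle: ClaimsBundle, directory: Path | str) -> dict[str, Path]:
    """Write the four CSV tables plus the YAML metadata sidecar.

    Output is deterministic (stable column order, ISO dates, empty string for
    missing death dates), so identical bundles produce identical bytes.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        df = _format_dates(bundle.table(name)[_COLUMNS[name]], name)
        if name == "dispensations" and len(df):
            df["supply_days"] = df["supply_days"].astype(int)
        path = root / fname
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    meta_path = root / METADATA_FILE
    meta_path.write_text(yaml.safe_dump(_plain(bundle.metadata), sort_keys=True))
    written["metadata"] = meta_path
    return written


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
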