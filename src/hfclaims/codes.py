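"""Code-system mappings: heart-failure ICD-10-GM codes and ATC drug classes.

German statutory health-insurance (SHI) claims identify diagnoses with
ICD-10-GM codes and dispensed drugs with ATC codes.  This module holds the
two mappings the whole analysis hangs on:

* the heart-failure inclusion code set (I50.x, I11.0, I13.0, I13.2), four of
  which (I50.11-I50.14) carry an explicit NYHA functional class I-IV;
* a longest-prefix ATC rule table mapping dispensations to the five drug
  classes of the guideline treatment patterns (ACE inhibitor, ARB,
  beta-blocker, diuretic, MRA) plus a catch-all OTHER_CV bucket.

Both tables ship as CSV package data and can be replaced with a user file
(``CodeConfig.from_files`` / the ``--code-config`` CLI option).  Combination
products (e.g. an ACE inhibitor + diuretic fixed combination) count toward
every constituent class, so ``classify_atc`` returns a *set* of classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Optional

import pandas as pd

__all__ = [
    "NYHA",
    "DrugClass",
    "Sector",
    "Specialty",
    "HFCodeEntry",
    "CodeConfig",
    "normalize_icd",
    "classify_icd",
    "classify_atc",
    "default_code_config",
]


class NYHA(str, enum.Enum):
    """NYHA functional class; OTHER = heart failure without a specific class code."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    OTHER = "OTHER"

    @property
    def rank(self) -> int:
        """Severity rank (I=1 .. IV=4, OTHER=0); used for worst-class tie-breaks."""
        return {"I": 1, "II": 2, "III": 3, "IV": 4, "OTHER": 0}[self.value]


#: NYHA classes eligible for pattern assessment (OTHER is excluded).
SPECIFIC_NYHA = (NYHA.I, NYHA.II, NYHA.III, NYHA.IV)


class DrugClass(str, enum.Enum):
    ACEI = "ACEI"
    ARB = "ARB"
    BETA_BLOCKER = "BETA_BLOCKER"
    DIURETIC = "DIURETIC"
    MRA = "MRA"
    OTHER_CV = "OTHER_CV"


class Sector(str, enum.Enum):
    AMBULATORY = "AMBULATORY"
    HOSPITAL_INPATIENT = "HOSPITAL_INPATIENT"
    HOSPITAL_OUTPATIENT = "HOSPITAL_OUTPATIENT"


class Specialty(str, enum.Enum):
    """Physician specialty (ambulatory) or hospital unit, on one shared axis."""

    FAMILY_PRACTICE = "FAMILY_PRACTICE"
    CARDIOLOGY = "CARDIOLOGY"
    OTHER_INTERNAL_MEDICINE = "OTHER_INTERNAL_MEDICINE"
    SURGERY = "SURGERY"
    OTHER = "OTHER"


@dataclass(frozen=True)
class HFCodeEntry:
    """One heart-failure qualifying ICD-10-GM code with its NYHA label."""

    icd_code: str  # dotted dialect, as catalogued
    nyha_label: NYHA
    description: str = ""


def normalize_icd(code: str) -> str:
    """Normalize an ICD-10-GM code to the undotted upper-case dialect.

    Claims extracts vary between dotted ("I50.13") and undotted ("I5013")
    forms; internally everything is undotted.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError("ICD code must be a non-empty string")
    return code.strip().upper().replace(".", "")


class CodeConfig:
    """The pair of replaceable code tables driving classification."""

    def __init__(self, icd_table: pd.DataFrame, atc_table: pd.DataFrame):
        self._entries: dict[str, HFCodeEntry] = {}
        for row in icd_table.itertuples(index=False):
            entry = HFCodeEntry(
                icd_code=row.icd_code,
                nyha_label=NYHA(row.nyha_label),
                description=getattr(row, "description", "") or "",
            )
            key = normalize_icd(entry.icd_code)
            if key in self._entries:
                raise ValueError(f"duplicate HF ICD code {entry.icd_code!r}")
            self._entries[key] = entry

        self._atc_rules: dict[str, FrozenSet[DrugClass]] = {}
        for row in atc_table.itertuples(index=False):
            prefix = str(row.atc_prefix).strip().upper()
            classes = frozenset(
                DrugClass(c.strip()) for c in str(row.drug_classes).split(";") if c.strip()
            )
            if prefix in self._atc_rules and self._atc_rules[prefix] != classes:
                raise ValueError(f"conflicting ATC rules for prefix {prefix!r}")
            self._atc_rules[prefix] = classes
        self._max_prefix_len = max((len(p) for p in self._atc_rules), default=0)

    # -- constructors -----------------------------------------------------
    @classmethod
    def default(cls) -> "CodeConfig":
        base = resources.files("hfclaims") / "tables"
        with resources.as_file(base / "hf_icd_codes.csv") as icd_path, resources.as_file(
            base / "atc_rules.csv"
        ) as atc_path:
            return cls.from_files(icd_path, atc_path)

    @classmethod
    def from_files(cls, icd_path: Path | str, atc_path: Path | str) -> "CodeConfig":
        return cls(pd.read_csv(icd_path), pd.read_csv(atc_path))

    # -- accessors --------------------------------------------------------
    @property
    def hf_entries(self) -> tuple[HFCodeEntry, ...]:
        return tuple(self._entries.values())

    @property
    def hf_codes_normalized(self) -> frozenset[str]:
        return frozenset(self._entries)

    def nyha_of(self, normalized_code: str) -> Optional[NYHA]:
        entry = self._entries.get(normalized_code)
        return entry.nyha_label if entry is not None else None

    # -- classification ---------------------------------------------------
    def classify_icd(self, code: str) -> Optional[HFCodeEntry]:
        """Return the HF code entry for *code*, or None when not HF-qualifying.

        Accepts dotted and undotted dialects; never errors on unknown codes
        (only on empty / non-string input).
        """
        return self._entries.get(normalize_icd(code))

    def classify_atc(self, atc: str) -> FrozenSet[DrugClass]:
        """Map an ATC code to its drug class(es) by longest-prefix match.

        Combination products return every constituent class.  Codes matching
        no rule return an empty set (the distinguished "unmapped" result).
        """
        if not isinstance(atc, str) or len(atc.strip()) < 3:
            raise ValueError("ATC code must be a string of length >= 3")
        code = atc.strip().upper()
        for n in range(min(len(code), self._max_prefix_len), 0, -1):
            rule = self._atc_rules.get(code[:n])
            if rule is not None:
                return rule
        return frozenset()


_DEFAULT: Optional[CodeConfig] = None


def default_code_config() -> CodeConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CodeConfig.default()
    return _DEFAULT


def classify_icd(code: str) -> Optional[HFCodeEntry]:
    """Module-level :meth:`CodeConfig.classify_icd` on the bundled tables."""
    return default_code_config().classify_icd(code)


def classify_atc(atc: str) -> FrozenSet[DrugClass]:
    """Module-level :meth:`CodeConfig.classify_atc` on the bundled tables."""
    return default_code_config().classify_atc(atc)
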