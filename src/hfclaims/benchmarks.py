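"""Published headline figures and their arithmetic recomputation.

The pipeline's design follows a large retrospective study of heart-failure
care in German statutory health-insurance claims (identification year 2011,
~3.1 million observable insurees).  The study's raw database is proprietary,
but every headline proportion was published together with its numerator and
denominator; this module stores those count pairs and recomputes each
percentage, checking agreement at the printed precision.  It is the
fast, data-free leg of the reproduction contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PUBLISHED_COUNTS", "recompute", "arithmetic_checks"]


@dataclass(frozen=True)
class PublishedShare:
    name: str
    description: str
    numerator: int
    denominator: int
    published_pct: float
    decimals: int  # precision at which the percentage was printed


#: count / percentage pairs printed in the study's results
PUBLISHED_COUNTS: tuple[PublishedShare, ...] = (
    PublishedShare(
        "hf_prevalence_pct",
        "patients with >=2 HF-coded diagnoses among observable insurees",
        123_925,
        3_132_337,
        4.0,
        0,
    ),
    PublishedShare(
        "incident_share_pct",
        "newly diagnosed (clean one-year washout) among the HF cohort",
        26_368,
        123_925,
        21.3,
        1,
    ),
    PublishedShare(
        "ambulatory_diagnosis_share_pct",
        "first diagnoses made in the ambulatory (office-based) setting",
        16_653,
        26_368,
        63.2,
        1,
    ),
    PublishedShare(
        "inpatient_diagnosis_share_pct",
        "first diagnoses made in the hospital inpatient setting",
        9_653,
        26_368,
        36.6,
        1,
    ),
    PublishedShare(
        "echo_uptake_pct",
        "incident patients with an echocardiographic assessment in follow-up",
        9_728,
        26_368,
        37.0,
        0,
    ),
    PublishedShare(
        "nyha_coded_share_pct",
        "HF cohort members with a specific NYHA class code",
        25_863,
        123_925,
        20.9,
        1,
    ),
    PublishedShare("nyha_I_share_pct", "NYHA class I among classed patients", 3_518, 25_863, 13.6, 1),
    PublishedShare("nyha_II_share_pct", "NYHA class II among classed patients", 10_992, 25_863, 42.5, 1),
    PublishedShare("nyha_III_share_pct", "NYHA class III among classed patients", 8_039, 25_863, 31.1, 1),
    PublishedShare("nyha_IV_share_pct", "NYHA class IV among classed patients", 3_314, 25_863, 12.8, 1),
    PublishedShare(
        "strict_pattern_share_pct",
        "NYHA-classed patients treated per the strict pattern",
        11_669,
        25_863,
        45.1,
        1,
    ),
)


def recompute(entry: PublishedShare) -> float:
    """Percentage from the published counts, rounded to the printed precision."""
    if entry.denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * entry.numerator / entry.denominator, entry.decimals)


def arithmetic_checks() -> pd.DataFrame:
    """Recompute every published count/percentage pair; one row per figure.

    The `passed` column records agreement with the printed percentage at its
    printed precision.
    """
    rows = []
    for entry in PUBLISHED_COUNTS:
        value = recompute(entry)
        rows.append(
            {
                "name": entry.name,
                "numerator": entry.numerator,
                "denominator": entry.denominator,
                "computed_pct": value,
                "published_pct": entry.published_pct,
                "decimals": entry.decimals,
                "passed": value == round(entry.published_pct, entry.decimals),
            }
        )
    return pd.DataFrame(rows)
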