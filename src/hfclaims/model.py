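"""Model/Results facade over the claims-analysis pipeline.

:class:`HFCareStudy` is built from a :class:`~hfclaims.claims.ClaimsBundle`
(read from disk, or simulated); ``fit()`` runs observability filtering,
cohort construction, pathway attribution and pattern classification, and
returns an :class:`HFCareResults` carrying the derived tables, the headline
proportion estimates with binomial standard errors, and a ``summary()``
table.

    >>> from hfclaims import HFCareStudy, preset_paperlike
    >>> study = HFCareStudy.from_simulation(preset_paperlike(seed=1))
    >>> res = study.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import adherence as adh
from . import pathway as pw
from .claims import ClaimsBundle, read_bundle
from .codes import CodeConfig, default_code_config
from .cohort import CohortOptions, build_cohort, filter_observable
from .simulate import SimulationConfig, generate

__all__ = ["HFCareStudy", "HFCareResults"]


class HFCareStudy:
    """Heart-failure care-pathway and treatment-pattern study on one bundle.

    Parameters
    ----------
    bundle
        The four linked claims tables.
    identification_year
        Year whose diagnoses define the cohort; defaults to the bundle's
        metadata.
    study_start, study_end
        Observability window; default is the two calendar years before and
        after the identification year.
    """

    def __init__(
        self,
        bundle: ClaimsBundle,
        identification_year: Optional[int] = None,
        *,
        study_start=None,
        study_end=None,
        code_config: Optional[CodeConfig] = None,
        cohort_options: CohortOptions = CohortOptions(),
        pathway_options: pw.PathwayOptions = pw.PathwayOptions(),
        adherence_options: adh.AdherenceOptions = adh.AdherenceOptions(),
        ground_truth: Optional[pd.DataFrame] = None,
    ):
        self.bundle = bundle
        year = identification_year or bundle.identification_year
        if year is None:
            raise ValueError("identification_year not given and absent from bundle metadata")
        self.identification_year = int(year)
        self.study_start = pd.Timestamp(study_start or f"{self.identification_year - 2}-01-01")
        self.study_end = pd.Timestamp(study_end or f"{self.identification_year + 2}-12-31")
        self.code_config = code_config or default_code_config()
        self.cohort_options = cohort_options
        self.pathway_options = pathway_options
        self.adherence_options = adherence_options
        self.ground_truth = ground_truth

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_directory(cls, directory, **kwargs) -> "HFCareStudy":
        return cls(read_bundle(directory), **kwargs)

    @classmethod
    def from_simulation(cls, config: SimulationConfig, **kwargs) -> "HFCareStudy":
        bundle, truth = generate(config)
        return cls(
            bundle,
            identification_year=config.identification_year,
            ground_truth=truth,
            **kwargs,
        )

    # -- estimation --------------------------------------------------------
    def fit(self) -> "HFCareResults":
        observable = filter_observable(
            self.bundle,
            self.study_start,
            self.study_end,
            earliest_death=pd.Timestamp(f"{self.identification_year}-01-01"),
        )
        cohort = build_cohort(
            self.bundle,
            self.identification_year,
            observable_ids=observable,
            code_config=self.code_config,
            options=self.cohort_options,
        )
        pathway = pw.compute_pathway(
            cohort, self.bundle, code_config=self.code_config, options=self.pathway_options
        )
        verdicts = adh.classify_bundle(
            cohort,
            self.bundle.dispensations,
            code_config=self.code_config,
            options=self.adherence_options,
        )
        strata = adh.stratify(verdicts, cohort)
        return HFCareResults(
            model=self,
            n_observable=len(observable),
            cohort=cohort,
            pathway=pathway,
            verdicts=verdicts,
            strata=strata,
        )


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n)) if n else float("nan")


@dataclass
class HFCareResults:
    """Fitted study: derived tables plus headline proportion estimates."""

    model: HFCareStudy
    n_observable: int
    cohort: pd.DataFrame
    pathway: pw.PathwayTables
    verdicts: pd.DataFrame
    strata: dict
    _estimates: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        self._estimates = self._compute_estimates()

    # -- headline estimates --------------------------------------------
    def _compute_estimates(self) -> pd.DataFrame:
        rows = []

        def add(name: str, num: int, den: int):
            p = num / den if den else float("nan")
            rows.append(
                {"estimate": name, "numerator": num, "denominator": den, "share": p, "se": _binom_se(p, den) if den else float("nan")}
            )

        cohort = self.cohort
        n_cohort = len(cohort)
        add("hf_cohort_of_observable", n_cohort, self.n_observable)
        add("incident_share", int(cohort["incident"].sum()), n_cohort)

        dx = self.pathway.diagnosing_attribution
        n_inc = int(cohort["incident"].sum())
        if len(dx):
            amb = int(dx.loc[dx["sector"] == "AMBULATORY", "count"].sum())
            add("ambulatory_diagnosis_share", amb, n_inc)
            fp = int(
                dx.loc[
                    (dx["sector"] == "AMBULATORY") & (dx["specialty"] == "FAMILY_PRACTICE"),
                    "count",
                ].sum()
            )
            add("family_practice_share_of_ambulatory", fp, amb)
        add("echo_uptake", self.pathway.echo_count, n_inc)

        classed = cohort[cohort["nyha"] != "OTHER"]
        add("nyha_coded_share", len(classed), n_cohort)
        for cls in ("I", "II", "III", "IV"):
            add(f"nyha_{cls}_share", int((classed["nyha"] == cls).sum()), len(classed))

        overall = self.strata["overall"].iloc[0]
        add("strict_pattern_share", int(overall["strict_n"]), int(overall["n"]))
        add("less_strict_pattern_share", int(overall["less_strict_n"]), int(overall["n"]))
        return pd.DataFrame(rows).set_index("estimate")

    @property
    def estimates(self) -> pd.Series:
        """Headline proportions (shares in [0, 1])."""
        return self._estimates["share"]

    @property
    def bse(self) -> pd.Series:
        """Binomial standard errors of :attr:`estimates`."""
        return self._estimates["se"]

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        header = ["estimate", "num", "den", "share", "se"]
        table_rows = [
            [
                name,
                f"{int(row['numerator'])}",
                f"{int(row['denominator'])}",
                f"{row['share']:.4f}" if np.isfinite(row["share"]) else "nan",
                f"{row['se']:.4f}" if np.isfinite(row["se"]) else "nan",
            ]
            for name, row in self._estimates.iterrows()
        ]
        title = (
            f"HF claims study, identification year {self.model.identification_year} "
            f"(n observable={self.n_observable}, cohort={len(self.cohort)})"
        )
        return str(SimpleTable(table_rows, header, title=title))

    # -- plotting (convenience) ------------------------------------------
    def plot_adherence_by_nyha(self, ax=None):
        """Bar chart of strict / less-strict shares per NYHA class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.strata["by_nyha"].set_index("nyha").reindex(["I", "II", "III", "IV"])
        x = np.arange(len(tab))
        ax.bar(x - 0.2, 100 * tab["strict_share"], width=0.4, label="strict")
        ax.bar(x + 0.2, 100 * tab["less_strict_share"], width=0.4, label="less strict")
        ax.set_xticks(x, tab.index)
        ax.set_xlabel("NYHA class")
        ax.set_ylabel("patients treated per pattern (%)")
        ax.legend()
        return ax

    def plot_quarterly_contacts(self, ax=None):
        """Contact shares per follow-up quarter by contact type."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qc = self.pathway.quarterly_contacts
        for ctype, grp in qc.groupby("contact_type"):
            ax.plot(grp["quarter"], 100 * grp["share"], marker="o", label=ctype)
        ax.set_xlabel("quarter after diagnosis")
        ax.set_ylabel("patients with >=1 contact (%)")
        ax.set_ylim(0, 105)
        ax.legend()
        return ax
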