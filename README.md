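# hfclaims

Heart-failure care pathways and guideline treatment patterns from German
statutory health-insurance (SHI) claims — as a tested, reusable pipeline
with a synthetic claims generator.

## The problem

Claims databases record, for every insuree, coded diagnoses (ICD-10-GM),
drug dispensations (ATC), and billed activities across the ambulatory and
hospital sectors. Pharmacoepidemiologists use them to answer two kinds of
question about chronic heart failure (HF):

1. **Pathways** — where is HF first diagnosed (office vs hospital, family
   practitioner vs cardiologist), which physicians treat patients and run
   technical diagnostics afterwards, and how often are patients seen per
   quarter?
2. **Treatment patterns** — what share of patients receives the
   guideline-recommended drug regimen for their NYHA class during the two
   years after diagnosis?

`hfclaims` implements the full analysis for an *incident-case washout
design* on quarter-granular claims:

* **Cohort**: patients observable without interruption over a five-year
  window (identification year ± 2 years, or until death), with ≥ 2
  HF-qualifying diagnoses (I50.x, I11.0, I13.0, I13.2) in the
  identification year. The *index quarter* is the quarter of the first
  qualifying diagnosis; a patient is *incident* when the four preceding
  quarters contain no HF diagnosis. NYHA class is the last class-specific
  code (I50.11–I50.14 ↦ I–IV) documented in the identification year.
* **Medication episodes**: a dispensation covers `supply_days` days;
  refills bridge gaps of up to 90 days ("three months") into *coverage
  episodes* per drug class, with ACE inhibitors and ARBs pooled into one
  renin–angiotensin (RAS) blocker track.
* **Patterns** (per NYHA class, strict / less strict):

  | NYHA | strict | less strict |
  |------|--------|-------------|
  | I | ACEi∨ARB | same |
  | II | (ACEi∨ARB) ∧ β-blocker ∧ diuretic | same |
  | III–IV | (ACEi∨ARB) ∧ β-blocker ∧ diuretic ∧ MRA | without the MRA |

  A term is met when bridged coverage starts within 90 days of the index
  date and runs, with no gap over 90 days, to death or the end of the
  two-year window. Results are stratified by NYHA class, age band, sex,
  identification-year hospitalization, and death.

Real SHI extracts are proprietary, so the package ships a **synthetic
claims generator** whose dispensation streams are constructed *from* the
adherence label (never labelled post hoc), giving an exact ground-truth
oracle for every pipeline stage.

## Worked example

```python
from hfclaims import HFCareStudy, preset_paperlike

study = HFCareStudy.from_simulation(preset_paperlike(n_patients=25_000, seed=1))
results = study.fit()
print(results.summary())
```

```
HF claims study, identification year 2011 (n observable=19311, cohort=767)
===========================================================
              estimate              num  den  share    se
-----------------------------------------------------------
            hf_cohort_of_observable 767 19311 0.0397 0.0014
                     incident_share 171   767 0.2229 0.0150
         ambulatory_diagnosis_share 102   171 0.5965 0.0375
family_practice_share_of_ambulatory  66   102 0.6471 0.0473
                        echo_uptake  58   171 0.3392 0.0362
                   nyha_coded_share 169   767 0.2203 0.0150
                       nyha_I_share  21   169 0.1243 0.0254
                      nyha_II_share  70   169 0.4142 0.0379
                     nyha_III_share  61   169 0.3609 0.0369
                      nyha_IV_share  17   169 0.1006 0.0231
               strict_pattern_share  71   169 0.4201 0.0380
          less_strict_pattern_share 112   169 0.6627 0.0364
-----------------------------------------------------------
```

Reading the table: of 19,311 observable synthetic insurees, 767 (3.97%)
qualify for the HF cohort; 22.3% are newly diagnosed (generator truth:
21.3%, within one binomial SE); 59.7% of first diagnoses are office-based
(truth 63.2%); and 42.0% / 66.3% of NYHA-classed patients meet the strict /
less-strict pattern (truth ≈ 45.2% / 65.0%). Standard errors are binomial.
`results.cohort`, `results.verdicts`, `results.pathway` and
`results.strata` carry the underlying tables;
`results.plot_adherence_by_nyha()` and `results.plot_quarterly_contacts()`
draw the corresponding figures.

The same pipeline runs from the shell:

```bash
hfclaims simulate --out bundle/ --seed 1          # synthetic bundle + truth.csv
hfclaims cohort --in bundle/ --out cohort.csv
hfclaims pathway --cohort cohort.csv --in bundle/ --out pathway/
hfclaims adherence --cohort cohort.csv --in bundle/ --out adherence/
hfclaims run --out report/ --seed 1               # everything + manifest
hfclaims check                                    # published-arithmetic audit
```

Imported real data must match the four documented CSV schemas
(`patients.csv`, `diagnoses.csv`, `dispensations.csv`, `activities.csv`;
ISO-8601 dates, header row); `hfclaims validate --in dir/` reports every
schema violation with file and row.

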