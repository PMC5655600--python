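# Methods

## Study design

The package analyses claims for one *identification year* Y (default 2011)
inside a five-year observability window [1 Jan Y−2, 31 Dec Y+2]. Patients
must be continuously covered over the window, or until death; anyone who
died before 1 Jan Y is excluded. The prevalent HF cohort requires at least
two HF-qualifying diagnoses dated in Y. "At least two" counts events on
distinct dates, or on the same date in different sectors; two same-day,
same-sector rows count once (duplicate billing lines are common in claims;
the deduplication is switchable via `CohortOptions(dedupe_same_day_sector)`
because source conventions differ).

The index quarter is the calendar quarter of the first qualifying
diagnosis. *Incident* means no HF diagnosis of any kind in the four
calendar quarters preceding the index quarter — a quarter-granular reading
of "the year before the index quarter", which matches how German claims are
billed and avoids day-window edge effects.

NYHA class is taken from the last class-specific code (I50.11–I50.14) dated
in Y; same-day ties resolve to the worse class (conservative severity — the
"last documented" rule is silent on ties). Patients without a
class-specific code form the OTHER group and are excluded from
treatment-pattern denominators. Age is computed at 31 Dec of Y and banded
0–49, 50–54, …, 85–89, ≥90. HFrEF/HFpEF cannot be distinguished from
ICD-10-GM codes and is out of scope.

## Code systems

HF-qualifying ICD-10-GM codes (13 codes: I50.0x, I50.1x, I50.9, I11.0,
I13.0, I13.2) ship as a CSV table; dotted and undotted dialects are
accepted and normalized to undotted. ATC classification is longest-prefix
matching on a replaceable rule table: C09A/C09B → ACE inhibitor, C09C/C09D
→ ARB, C07 → β-blocker, C03 → diuretic, with the MRA class restricted to
the spironolactone and eplerenone substance codes (C03DA01, C03DA04).
Fixed-dose combinations (C09BA, C09DA, C07B/C/D) count toward every
constituent class, because the patterns test class exposure, not product
identity. The exact substance list used by the reference study is not
public; these chapter prefixes are the standard operationalization, and the
table is a configuration file precisely so it can be replaced.

## Episode construction and pattern assessment

A dispensation on day d with supply s covers days d … d+s−1. Within a
drug-class track, fills are sorted by date and merged whenever the number
of uncovered days between the previous covered day and the next fill is at
most the gap tolerance g (default 90 days, "three months between
prescriptions"); the result is a set of maximal coverage episodes separated
by more than g uncovered days. ACEI and ARB fills additionally feed a
pooled RAS track so that a mid-stream switch does not break the
"ACE inhibitor or ARB" term. MRA fills feed the diuretic track by default
(an MRA *is* a potassium-sparing diuretic; without this an MRA-treated
patient could paradoxically fail the diuretic term); switchable via
`AdherenceOptions(mra_counts_as_diuretic)`.

A pattern term is met over the window [index, C], C = min(death, index +
730 days), when one episode satisfies both boundary rules, with the gap
rule applied uniformly at the ends:

* initiation — the index date acts as a virtual previously covered day, so
  the episode must start within g days after it;
* termination — the censor date must lie within g days of the last covered
  day. Read literally, "coverage extending to the window end" would fail a
  patient on perfectly regular 90-day refills who is censored mid-gap; the
  symmetric rule is the package's design choice.

Because episodes are separated by more than g days, "no gap > g from index
to censor" reduces to a single episode meeting both conditions; this makes
the monotonicity property (adding a dispensation never breaks adherence)
immediate, and it is tested against a brute-force day-by-day coverage scan.

The reference study reports the overall strict share "in the first quarter
following initial diagnosis" while describing a two-year assessment; the
relationship is ambiguous, so the two-year rule above is the default and a
pure initiation variant (`first_quarter_initiation=True`: any coverage
beginning within 90 days of index) is exposed.

## Pathway outputs

Diagnosing attribution uses each incident patient's earliest qualifying
diagnosis exactly once; same-day multi-sector ties resolve by precedence
hospital-inpatient > ambulatory > hospital-outpatient (an admission on the
diagnosis day is the dominant clinical event; configurable). Quarterly
contact shares run over eight calendar quarters starting at the index
quarter, with alive-at-quarter-start denominators (a patient dying in a
quarter stays in that quarter's denominator). Whether "quarter 1" is the
index quarter or the one after is genuinely ambiguous in the source; the
index quarter is the default (its ~98% office-visit share is only
consistent with the quarter containing the diagnosis) and
`PathwayOptions(followup_origin="next-quarter")` gives the alternative.
Activity attribution counts activity *events* (so Ns exceed the cohort
size) within the same eight-quarter window censored at death, split into
technical diagnostics vs treatment. Echo uptake is the share of incident
patients with ≥ 1 echocardiography event in follow-up.

## Synthetic generator

`SimulationConfig` defaults are the documented study conditions, taken from
the reference study's printed marginals and fixed once:

| parameter | default | source/rationale |
|---|---|---|
| observable_fraction | 0.766 | 3,132,337 / 4,088,854 observable insurees |
| hf_prevalence | 0.0396 | 123,925 / 3,132,337 cohort share |
| incident_fraction | 0.213 | printed incident share |
| nyha_coded_fraction | 0.209 | printed NYHA-coded share |
| nyha_distribution | .136/.425/.311/.128 | printed NYHA mix |
| adherence_prob_strict | I .62, II .56, III .33, IV .211 | class IV printed (21.1%); I–III solved once so the NYHA-weighted mean reproduces the printed overall 45.1% |
| mra_given_eligible | 0.3955 | P(MRA \| less-strict met, III–IV); chosen so the implied overall less-strict share is the printed 65.0% |
| ambulatory_dx_fraction / hospital_outpatient | 0.632 / 0.002 | printed sector split |
| family_practice_dx_fraction | 0.616 | printed specialty share |
| supply_days / gap bounds | 30 / U(0, 60) | monthly packs; refill gaps stay under the 90-day tolerance by construction |
| annual_mortality | 0.06 | implies ~11.6% two-year mortality, consistent with the reported 6.7%/16.2% mortality split |
| hospitalization_prob | 0.64 | reported hospitalized shares ≈ 63–65% |
| echo_prob, office/inpatient/outpatient contact | 0.37, 0.98/0.15/0.045 | printed uptake and contact levels |

Adherence labels are drawn per NYHA class with one nested uniform draw
(strict ⊆ less-strict by construction) and the dispensation streams are
then written **constructively from the label**: adherent classes get refill
chains whose gaps never exceed the tolerance and which reach the censor
date; a non-adherent patient either lacks one required class entirely,
starts it more than the tolerance after index, or carries exactly one
super-threshold gap placed so that neither resulting episode can satisfy
both boundary rules. Index dates are drawn over January–November so a
second same-year diagnosis always exists on a later date, keeping the
diagnosing-sector ground truth exact; pre-index diagnoses of prevalent
patients are placed inside the washout but strictly before the
identification year so the recomputed index equals the generated one.
Deaths (among patients flagged to die) are uniform over [index + 30 d,
index + 730 d]; the 30-day floor guarantees the second diagnosis and first
fill precede death, and no event is ever emitted after death. Background
patients carry non-HF codes, unrelated dispensations, and occasionally a
*single* HF code, so the ≥2-diagnosis filter is genuinely exercised; a
non-observable stratum (late enrolment or pre-identification death)
exercises the observability filter.

What the generator does **not** emulate: comorbidity structure, regional
or insurer heterogeneity, seasonality, dose/strength (DDD) semantics,
adherence–outcome correlation (mortality and hospitalization are drawn
independently of the treatment label), coding errors, or duplicate billing
beyond exact same-day duplicates. Tests passing on synthetic data
therefore establish the *correctness of the algorithms against their
stated rules*, not the clinical validity of any estimate on real claims.

## Numerical and testing choices

Dates are pandas Timestamps; quarters are pandas `Period('Q')`. Shares are
exact rational counts; published percentages are compared after rounding to
their printed precision (that rounding is part of the reproduction
contract). Empty strata report NaN, never zero. Episode construction is
validated against an independent day-by-day coverage oracle on 1,000 random
dispensation histories plus a derandomized property-based sweep; washout
flags against a brute-force event scan; cohort construction against a
whole-year date-translation invariance check. Parameter-recovery tests use
one simulation of 25,000 patients with a fixed seed and assert agreement
with the configured conditions within three binomial standard errors of the
relevant denominator (the cohort of that run holds ~770 HF patients, ~170
of them NYHA-classed); the monotonicity sweep uses five runs of 10,000
patients. These problem sizes are the package's chosen trade-off between
statistical resolution and a test suite that runs in well under a minute.

## Limitations

Supply duration is not recorded in German claims; `supply_days` is a
schema field the importer must provide (default 30 when absent). The ATC
rule table approximates an unpublished substance list. The pipeline cannot
distinguish HFrEF from HFpEF, infer contraindications, or assess dosing
adequacy. Published figure-caption Ns for the stratified adherence
denominators are internally inconsistent with the running text; the
arithmetic audit therefore uses only count/percentage pairs whose numerator
and denominator are both printed.
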