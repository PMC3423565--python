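# alf-triage

Decision support for **acute liver failure (ALF)** as defined by the Japanese
2011 diagnostic criteria: a tested rule-based library plus an `alf-triage`
command line for hepatologists, intensivists and clinical-epidemiology
researchers who need reproducible diagnostic classification, hepatic-coma
grading, transplant triage and outcome prediction over tabular patient data.

## What it implements

**Diagnosis (2011 criteria).** A patient qualifies on the laboratory
criterion when the prothrombin time is ≤ 40 % of the standardized value or
the INR is ≥ 1.5, in a previously normal liver (alcoholic hepatitis is
excluded as acute-on-chronic disease). ALF then splits by hepatic
encephalopathy and by the onset-to-encephalopathy (O-C) interval:

| category | coma grade | window |
| --- | --- | --- |
| ALF without hepatic coma | none / I | labs within 8 weeks of symptom onset |
| ALF with coma, acute type | ≥ II | O-C ≤ 10 days |
| ALF with coma, subacute type | ≥ II | O-C 11–56 days |
| late-onset hepatic failure (LOHF) | ≥ II | O-C 8–24 weeks (57–168 days) |

Patients whose etiology is viral (I), autoimmune (II) or drug-allergy
(III-1) additionally carry the diagnosis **fulminant hepatitis**; drug
toxicity (III-2) and etiologies IV–VIII do not (the indeterminate and
unclassified classes follow a configurable policy).

**Coma grading.** Structured clinical-feature flags map to the ordinal
grades I–V of the adult Inuyama (1972) scale and of the pediatric/infant
(1988) scale; the grader returns the highest grade whose defining criteria
are satisfied.

**Prognostic score (2011).** Six parameters each score 0–2 (liver atrophy
0/1): O-C interval (≤5 / 6–10 / ≥11 d), PT% (>20 / 5–20 / ≤5), total
bilirubin (<10 / 10–15 / ≥15 mg/dL), direct/total bilirubin ratio (≥0.7 /
0.5–0.7 / <0.5), platelets (>10 / 5–10 / ≤5 ×10⁴/µL), atrophy
(absent/present). Total ≥ 5 predicts "death"; totals map to predicted
mortality bands (≥7 → >90 %, 6 → 80–90 %, 5 → 70–80 %, 4 → 50–60 %,
≤3 → <30 %).

**Transplant guideline (1996).** At the onset of grade ≥ II encephalopathy,
meeting ≥ 2 of {age ≥ 45 y, O-C ≥ 11 d, PT < 10 %, TB ≥ 18.0 mg/dL,
D/T < 0.67} lists the patient as a transplant candidate; after 5 days of
intensive therapy (artificial liver support) the call reverts to "alive"
only if the coma improved to grade ≤ I or by ≥ 2 grades *and* the PT rose
above 50 %.

**Cohort analytics & synthetic cohorts.** Stratified counts, shares and
survival rates with the survey's exact denominators and half-up one-decimal
rounding, confusion-matrix metrics for death predictions, a packaged
transcription of the 2010 nationwide-survey strata (220 patients), and a
seeded generator of synthetic cohorts whose stratum structure and outcome
probabilities emulate that survey.

## Worked example

```python
from alf_triage import (ComaGrade, Etiology, EtiologyCode, LabPanel,
                        PatientRecord, classify, total_score,
                        transplant_candidate_initial, reassess_day5)

rec = PatientRecord(
    patient_id="case-01", age_years=52,
    labs=LabPanel(pt_percent=25.0, total_bilirubin=16.0,
                  direct_bilirubin=6.4, platelets=4.5),
    etiology=EtiologyCode(Etiology.II_AUTOIMMUNE),
    coma_grade=ComaGrade.III, onset_to_encephalopathy_days=12,
    onset_to_labs_weeks=2.0, liver_atrophy=True)
rec.validate()

diag = classify(rec)
print(diag.category.value, diag.fulminant_hepatitis)
# ALF_WITH_COMA_SUBACUTE True

score = total_score(rec)
print(score.subscores)
# {'oc_days': 2, 'pt': 0, 'tb': 2, 'dt_ratio': 2, 'plt': 2, 'atrophy': 1}
print(score.total, score.band.label, score.death_call)
# 9 >90% True

triage = transplant_candidate_initial(rec)
print(sorted(triage.criteria_met), triage.candidate)
# ['age', 'dt_ratio', 'interval'] True
after = reassess_day5(triage, ComaGrade.III, ComaGrade.I, 58.0)
print(after.day5.reassessed_alive, after.predicted_death)
# True False
```

Reading the output: encephalopathy at day 12 makes this subacute-type ALF
with coma, and the autoimmune etiology adds the fulminant-hepatitis
diagnosis. The prognostic total of 9 (driven by the long O-C interval, deep
jaundice with a low D/T ratio, thrombocytopenia and atrophy) sits in the
">90 %" predicted-mortality band, so the score calls "death". The guideline
lists the patient for transplantation (3 of 5 criteria); after 5 days the
coma has improved to grade I and the PT to 58 %, so the prognosis is
reassessed as "alive" and the patient leaves the candidate list.

The same flows are available from the shell:

```bash
alf-triage simulate --n 1000 --seed 42 --out cohort.csv
alf-triage classify cohort.csv --out diagnoses.csv
alf-triage score cohort.csv --out scored.csv --skip-ineligible
alf-triage summarize --survey2010 --out summary.md
```

Structured coma-feature flags (for `alf-triage grade` and the record
schema) are supported in the JSON record format; the flat CSV schema
carries the coma grade itself. Threshold overrides live in a YAML config
(see `alf_triage.config`).

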