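# Methods

This note documents the rules the package encodes, the conventions chosen
where the published material leaves room, the synthetic-data model, and the
limits of what the test suite demonstrates.

## Units and record conventions

Prothrombin time is carried as a percentage of a standardized value (the
Japanese laboratory convention; lower is worse) and the INR as a separate
field. No conversion between the two exists in the package: either suffices
for the laboratory criterion, and a record lacking both is rejected at the
schema level. Bilirubin is in mg/dL, platelets in 10⁴/µL. The direct/total
bilirubin (D/T) ratio is always derived, never stored, and is undefined
when total bilirubin is 0.

Intervals are whole days counted inclusively from the calendar day of first
disease symptoms, so "within 10 days" means interval ≤ 10; there is no
day-0 convention. The onset-to-encephalopathy interval is present exactly
when the coma grade is ≥ II — the two facts are one invariant, enforced at
validation. Ages are whole years, and the pediatric flag is explicit: no
age cutoff is published for choosing the pediatric coma scale, so the
package never infers it.

Missing values (empty CSV cell / JSON null) are never imputed. Every
operation that needs an absent value refuses with an error naming the
field; the only relaxation is the explicitly non-standard
`--allow-partial` score mode, which brackets the attainable total instead
of computing one.

## Coma grading

Only the defining psychiatric-disorder items confer grade membership; the
scales' accompanying reference findings overlap across grades and are
treated as illustrative. The grader returns the highest satisfied grade,
evaluated V down to I, and each of grade III's three manifestations
(excitation/delirium; somnolence with eye-opening to stimulation; obeying
only simple orders) suffices alone.

Two conventions deserve note. First, grade V requires complete loss of
consciousness *and* no pain response, grade IV complete loss *with* a
preserved pain response; a record reporting complete loss with the pain
response unassessed is a missing-data error rather than a guess between
the two, and a pain-response flag alone (without the coma flag) does not
raise an adult grade. Second, on the pediatric scale the infant items are
taken literally as printed: "does not laugh aloud" is grade I, "does not
laugh even when being played with" (or loss of maternal eye contact) is
grade II.

## Diagnostic classification

Exclusions are evaluated first — laboratory criterion not met, prior liver
function impaired, habitual alcohol as the cause — then coma-free patients
with qualifying labs within 8 weeks are ALF without coma, and grade ≥ II
patients partition by interval: ≤ 10 days acute, 11–56 subacute, 57–168
LOHF, beyond that outside the entity. The lab boundary is inclusive
(PT ≤ 40 %), following the current wording over the older "less than
40 %". The LOHF window "8–24 weeks" is implemented in days, 57–168
inclusive, so it is exactly continuous with the subacute bound of 56 days;
when day counting and week counting disagree at the 8-week seam, the
day-based rule governs. The chart-history questions behind the inclusion
notes (HBV carriers, autoimmune flares, fatty liver with a non-alcoholic
acute insult) are deliberately collapsed into the single
`prior_liver_function_normal` flag set by the data provider — the package
does not adjudicate clinical history.

The fulminant-hepatitis flag is purely etiologic: classes I, II and III-1
qualify, III-2 and IV–VIII do not. The two residual classes have no
printed rule. Indeterminate-despite-work-up (IX) defaults to
hepatitis-compatible, because the survey tallies indeterminate etiology
inside its hepatitis group; unclassified-for-lack-of-examinations (X)
defaults to not. Both policies are configuration switches. A drug-injury
record with no allergy/toxicity subtype resolves to not-hepatitis
(only III-1 is listed as compatible).

## Prognostic score and transplant guideline

The six subscore cut points are encoded exactly as printed, including
their mixed strictness (PT ≤ 5 scores 2 but TB ≥ 15 scores 2; the D/T
column is closed on the left). The atrophy row prints only two cells
(absent/present), so its subscore is 0/1 and the maximum total 11; because
the table layout leaves the column assignment genuinely ambiguous, the
weight is configurable to 0/2. The death-call threshold (total ≥ 5) and
the mortality-band table are likewise configuration, with the published
values as defaults. Scoring is restricted to grade ≥ II encephalopathy:
the system is defined for fulminant hepatitis and LOHF, and the O-C
interval does not exist for coma-free patients.

The 1996 guideline keeps its own printed inequalities (age ≥ 45,
interval ≥ 11 d, PT < 10 %, TB ≥ 18.0, D/T < 0.67) with no harmonization
against the score's cut points — the two instruments are 15 years apart
and disagree on strictness at several boundaries. Day-5 improvement is a
logical OR (grade ≤ I, or attenuation by ≥ 2 ordinal steps counting
NONE–I–II–III–IV–V as unit steps) AND PT > 50 %; reassessment can only
move a death call toward "alive", never the reverse.

## Survey tables and cohort analytics

The packaged strata table transcribes the 2010 nationwide survey: 220
patients (211 ALF, 9 LOHF), their coma/hepatitis splits, treatment arms
and outcomes. Percentages round half-up to one decimal, which reproduces
every printed figure; survival denominators follow the survey exactly
(medical arm 191, transplant 29, overall 220, hepatitis medical 168). Two
transcription choices: the per-stratum alive/dead split of the 29
transplant recipients is not published (only 18/29 overall), so the
fixture's per-stratum allocation is synthetic and marked as such — golden
tests assert only published aggregates; and the indeterminate-etiology
LOHF fraction is stored as 2/9 (= 22.2 %, the printed percentage), whose
printed denominator "7" is inconsistent with the 9-patient LOHF cohort and
is treated as a typo. The etiology table's `other_hepatitis` column is a
derived remainder (autoimmune + drug-allergy + other), for which no
per-category counts are published.

Empty strata yield an undefined-rate sentinel (`None`), never 0; the same
applies to zero-denominator confusion-matrix ratios.

## Synthetic cohorts

The generator emulates the survey's *structure*: stratum shares,
medical-arm survival probabilities, per-stratum transplant fractions
(whose mixture is exactly the survey's 29/220 — transplantation occurs
only in hepatitis strata, as observed), transplant survival 18/29, and
per-category etiology mixes, all derived at run time from the packaged
tables so the generator and the golden tests share one source of truth.

The laboratory values are *not* survey-derived — no lab distributions are
published — and are drawn from class-conditional truncated log-normals
(D/T from a truncated normal) whose location constants order severity
plausibly across classes (deeper jaundice, lower D/T and more atrophy in
subacute/LOHF disease) and whose truncation keeps every record consistent
with its class: PT within the qualifying range, intervals inside the
category window, direct ≤ total bilirubin. Coma grades II–V are drawn with
fixed probabilities (0.45/0.3/0.15/0.1). One `numpy.random.Generator`
seeded from a single integer drives everything; equal seeds give
byte-identical cohorts.

Passing tests on synthetic cohorts therefore demonstrate rule and
frequency correctness — every generated record classifies into its
assigned stratum, and at n = 10,000 the classified stratum shares and
medical-arm survival frequencies recover their targets within 3 binomial
standard errors — but say nothing about real-world lab correlations,
longitudinal trajectories (only a single day-5 reassessment panel exists),
or treatment selection beyond the survey's marginal rates.

## Numerical and testing choices

Percentage rounding uses decimal half-up (float bankers' rounding would
break several printed values, e.g. 5/11). Score-grid conformance is tested
exhaustively at every cut point ± ε against a hand-coded lookup table;
guideline conformance against a brute-force criterion counter on 10,000
random records; the interval partition by sweeping 0–200 days. Problem
sizes (10,000-record property sweeps, 10,000-patient recovery cohorts)
were chosen to make 3-SE frequency checks meaningful while keeping the
whole suite in the seconds range.

The published external-cohort validation statistics (predictive accuracy
0.80; sensitivity, specificity, PPV, NPV all > 0.70; guideline accuracies
76 %/82 %) rest on patient-level data that were never published; the
package verifies the metric *formulas* against brute-force 2×2 counts and
makes no claim to reproduce those figures.

## Known limitations

* The classifier consumes provider-supplied intervals and flags; it does
  no date arithmetic and no chart review.
* The score refuses coma-free (therefore O-C-less) patients by design; how
  the published system would handle them is unspecified.
* Synthetic lab values are distributional stand-ins, suitable for testing
  rule logic and frequencies, not for training or calibrating models.
* The 2002 fulminant-hepatitis criteria exist here only as the
  etiology-based compatibility flag, not as a separate classifier; King's
  College criteria and MELD are out of scope.
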