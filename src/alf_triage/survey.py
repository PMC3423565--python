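"""Packaged 2010 nationwide-survey stratum tables.

``data/survey2010_strata.csv`` transcribes the survey's outcome strata: one
row per (diagnostic category, hepatitis flag, treatment arm, outcome) cell
with its patient count — 220 patients in all (211 ALF + 9 LOHF; 29
transplanted, 191 managed medically).  The survey prints per-stratum
survival for the medical arm and only the aggregate 18/29 for transplant
recipients; the per-stratum transplant alive/dead split stored here (2/0,
8/5, 7/6, 1/0) is therefore a synthetic allocation that is consistent with
the aggregate, and summaries should only be quoted at the granularity the
survey itself reports.

``data/survey2010_etiology.csv`` holds the etiology-group counts per
category (viral, indeterminate, non-hepatitis — all printed; the
``other_hepatitis`` column is the remainder: autoimmune, drug-allergy and
other hepatitis etiologies, for which the survey prints no per-category
counts).

``expand_strata`` turns the stratum counts back into individual patient
records with representative in-class values, so the whole pipeline
(load -> classify -> summarize) can be exercised on the real cohort
structure.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .classification import Category
from .records import (ComaGrade, Etiology, EtiologyCode, LabPanel, Outcome,
                      PatientRecord, Treatment, ViralSub)

__all__ = ["load_strata", "load_etiology", "expand_strata",
           "etiology_shares", "COHORT_SIZE"]

COHORT_SIZE = 220


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("alf_triage.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(StringIO(text))


def load_strata() -> pd.DataFrame:
    """The (category, hepatitis, treatment, outcome) -> count table."""
    df = _read_packaged("survey2010_strata.csv")
    assert int(df["count"].sum()) == COHORT_SIZE
    return df


def load_etiology() -> pd.DataFrame:
    """The (category, etiology_group) -> count table."""
    return _read_packaged("survey2010_etiology.csv")


# Representative in-class values for expanding count strata into records.
# Labs are identical across strata (well inside the qualifying range); only
# the coma grade and the intervals differ by category.
_CATEGORY_FIELDS: dict[str, dict] = {
    Category.ALF_WITHOUT_COMA.value: dict(
        coma_grade=ComaGrade.NONE, onset_to_encephalopathy_days=None,
        onset_to_labs_weeks=4.0),
    Category.ALF_WITH_COMA_ACUTE.value: dict(
        coma_grade=ComaGrade.III, onset_to_encephalopathy_days=7,
        onset_to_labs_weeks=1.0),
    Category.ALF_WITH_COMA_SUBACUTE.value: dict(
        coma_grade=ComaGrade.III, onset_to_encephalopathy_days=30,
        onset_to_labs_weeks=4.0),
    Category.LOHF.value: dict(
        coma_grade=ComaGrade.III, onset_to_encephalopathy_days=100,
        onset_to_labs_weeks=14.0),
}


def expand_strata(strata: pd.DataFrame | None = None) -> list[PatientRecord]:
    """One validated record per patient, reproducing the stratum counts.

    Hepatitis-group patients get a viral etiology (class I) and the
    non-hepatitis group a circulatory one (class IV), so the fulminant-
    hepatitis flag reproduces the survey's hepatitis split; per-patient
    etiologies beyond that split are not reconstructable from the strata
    table (see :func:`load_etiology` for the group counts).
    """
    if strata is None:
        strata = load_strata()
    records: list[PatientRecord] = []
    idx = 0
    for row in strata.itertuples(index=False):
        fields = _CATEGORY_FIELDS[row.category]
        etiology = (EtiologyCode(Etiology.I_VIRAL, viral_sub=ViralSub.HBV_TRANSIENT)
                    if row.hepatitis else EtiologyCode(Etiology.IV_CIRCULATORY))
        for _ in range(int(row.count)):
            idx += 1
            rec = PatientRecord(
                patient_id=f"S{idx:03d}",
                age_years=50,
                labs=LabPanel(pt_percent=30.0, inr=1.8, total_bilirubin=12.0,
                              direct_bilirubin=7.2, platelets=8.0),
                etiology=etiology,
                liver_atrophy=False,
                prior_liver_function_normal=True,
                habitual_alcohol_as_cause=False,
                treatment=Treatment(row.treatment),
                outcome=Outcome(row.outcome),
                **fields,
            )
            rec.validate()
            records.append(rec)
    return records


def etiology_shares() -> dict[str, dict[str, dict]]:
    """Per-category etiology-group counts and one-decimal shares.

    Denominators are the category sizes (96, 61, 54, 9) plus the pooled
    with-coma column (115).
    """
    from .cohort import pct

    df = load_etiology()
    totals = df.groupby("category")["count"].sum().to_dict()
    coma_cats = [Category.ALF_WITH_COMA_ACUTE.value,
                 Category.ALF_WITH_COMA_SUBACUTE.value]
    out: dict[str, dict[str, dict]] = {}
    for cat, sub in df.groupby("category"):
        out[cat] = {
            row.etiology_group: {
                "n": int(row.count),
                "total": int(totals[cat]),
                "pct": pct(int(row.count), int(totals[cat])),
            }
            for row in sub.itertuples(index=False)
        }
    pooled = (df[df["category"].isin(coma_cats)]
              .groupby("etiology_group")["count"].sum())
    pooled_total = int(pooled.sum())
    out["ALF_WITH_COMA"] = {
        grp: {"n": int(n), "total": pooled_total, "pct": pct(int(n), pooled_total)}
        for grp, n in pooled.items()
    }
    return out
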