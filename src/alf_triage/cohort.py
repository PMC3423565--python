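"""Stratified cohort summarization and prediction-evaluation metrics.

Percentages are rounded half-up to one decimal, the convention used
throughout the nationwide-survey reporting (e.g. 96/211 -> 45.5, 116/220 ->
52.7).  Survival follows the survey's denominators: the medical-treatment
survival rate excludes transplant recipients, the transplant survival rate
is computed among recipients (alive post-transplant counts as survival),
and the overall rate includes everyone.  Undefined ratios (empty strata,
zero-denominator confusion cells) are reported as ``None``, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Any, Callable, Iterable, Mapping, Sequence

import pandas as pd

from .classification import Category, DiagnosisResult
from .errors import AlignmentError
from .records import Etiology, Outcome, PatientRecord, Treatment

__all__ = [
    "pct", "SurvivalRate", "ConfusionMetrics", "CohortSummary",
    "summarize", "survival_rate", "evaluate_predictions", "etiology_group",
]


def pct(numerator: int, denominator: int) -> float | None:
    """100*num/den rounded half-up to one decimal; None when den == 0."""
    if denominator == 0:
        return None
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class SurvivalRate:
    """Survivors / total with the one-decimal percent (None when empty)."""

    survived: int
    total: int

    @property
    def percent(self) -> float | None:
        return pct(self.survived, self.total)

    def __str__(self) -> str:
        p = self.percent
        return (f"{p} % ({self.survived}/{self.total})"
                if p is not None else "undefined (0/0)")


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts with the standard derived proportions.

    Zero-denominator ratios are None (e.g. specificity with no observed
    survivors), not 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)


_ETIOLOGY_GROUPS = {
    Etiology.I_VIRAL: "viral",
    Etiology.II_AUTOIMMUNE: "autoimmune",
    Etiology.III_DRUG: "drug",
    Etiology.IX_INDETERMINATE: "indeterminate",
    Etiology.X_UNCLASSIFIED: "unclassified",
}


def etiology_group(major: Etiology) -> str:
    """Reporting group of an etiology class: viral / autoimmune / drug /
    indeterminate / unclassified / non_hepatitis (classes IV-VIII)."""
    return _ETIOLOGY_GROUPS.get(major, "non_hepatitis")


_COMA_CATEGORIES = (Category.ALF_WITH_COMA_ACUTE, Category.ALF_WITH_COMA_SUBACUTE)


class CohortSummary:
    """Stratified view over (records, diagnoses) pairs.

    Wraps one tidy DataFrame (one row per patient: category, hepatitis
    flag, etiology group, treatment, outcome, survived) and exposes counts,
    shares and survival rates over arbitrary column filters.  A filter value
    may be a scalar or a list/tuple/set of admissible values.
    """

    def __init__(self, records: Sequence[PatientRecord],
                 diagnoses: Sequence[DiagnosisResult]):
        if len(records) != len(diagnoses):
            raise AlignmentError(
                f"{len(records)} records vs {len(diagnoses)} diagnoses")
        self.table = pd.DataFrame({
            "patient_id": [r.patient_id for r in records],
            "category": [d.category.value for d in diagnoses],
            "hepatitis": [d.fulminant_hepatitis for d in diagnoses],
            "etiology_group": [etiology_group(r.etiology.major) for r in records],
            "treatment": [r.treatment.value for r in records],
            "outcome": [r.outcome.value if r.outcome else None for r in records],
            "survived": [r.outcome.alive if r.outcome else None for r in records],
        })

    # -- filtering ---------------------------------------------------------

    def _mask(self, filters: Mapping[str, Any]) -> pd.Series:
        mask = pd.Series(True, index=self.table.index)
        for col, want in filters.items():
            if isinstance(want, (list, tuple, set, frozenset)):
                allowed = [w.value if hasattr(w, "value") else w for w in want]
                mask &= self.table[col].isin(allowed)
            else:
                if hasattr(want, "value"):
                    want = want.value
                mask &= self.table[col] == want
        return mask

    def n(self, **filters: Any) -> int:
        """Number of patients matching the filters."""
        return int(self._mask(filters).sum())

    def share(self, num: Mapping[str, Any], den: Mapping[str, Any]) -> float | None:
        """Percent (half-up, one decimal) of den-patients matching num too."""
        den_mask = self._mask(den)
        num_mask = den_mask & self._mask(num)
        return pct(int(num_mask.sum()), int(den_mask.sum()))

    def survival(self, **filters: Any) -> SurvivalRate:
        """Survival rate in the filtered stratum (outcome must be known)."""
        sub = self.table[self._mask(filters)]
        known = sub[sub["survived"].notna()]
        return SurvivalRate(int(known["survived"].sum()), len(known))

    # -- canonical tables --------------------------------------------------

    def strata_counts(self) -> pd.DataFrame:
        """Counts per (category, hepatitis, treatment, outcome) stratum."""
        if self.table.empty:
            return pd.DataFrame(columns=["category", "hepatitis", "treatment",
                                         "outcome", "count"])
        out = (self.table
               .groupby(["category", "hepatitis", "treatment", "outcome"],
                        dropna=False)
               .size().reset_index(name="count"))
        return out.sort_values(list(out.columns[:-1])).reset_index(drop=True)

    def report(self) -> dict[str, Any]:
        """Survey-style nested summary (counts, shares, survival rates)."""
        alf = [c.value for c in Category if c not in
               (Category.NOT_ALF, Category.LOHF)]
        coma = [c.value for c in _COMA_CATEGORIES]
        entity = alf + [Category.LOHF.value]

        def surv(sr: SurvivalRate) -> dict[str, Any]:
            return {"survived": sr.survived, "total": sr.total,
                    "percent": sr.percent}

        rep: dict[str, Any] = {
            "n_total": self.n(category=entity),
            "n_alf": self.n(category=alf),
            "n_lohf": self.n(category=Category.LOHF),
            "n_not_alf": self.n(category=Category.NOT_ALF),
            "alf_split": {
                "without_coma": {
                    "n": self.n(category=Category.ALF_WITHOUT_COMA),
                    "pct": self.share({"category": Category.ALF_WITHOUT_COMA},
                                      {"category": alf})},
                "with_coma": {
                    "n": self.n(category=coma),
                    "pct": self.share({"category": coma}, {"category": alf})},
                "acute": {
                    "n": self.n(category=Category.ALF_WITH_COMA_ACUTE),
                    "pct": self.share({"category": Category.ALF_WITH_COMA_ACUTE},
                                      {"category": alf})},
                "subacute": {
                    "n": self.n(category=Category.ALF_WITH_COMA_SUBACUTE),
                    "pct": self.share({"category": Category.ALF_WITH_COMA_SUBACUTE},
                                      {"category": alf})},
            },
            "hepatitis_split": {
                "with": {"n": self.n(category=alf, hepatitis=True),
                         "pct": self.share({"hepatitis": True}, {"category": alf})},
                "without": {"n": self.n(category=alf, hepatitis=False),
                            "pct": self.share({"hepatitis": False}, {"category": alf})},
            },
            "treatment": {
                "transplant": {"n": self.n(category=entity, treatment=Treatment.TRANSPLANT),
                               "pct": self.share({"treatment": Treatment.TRANSPLANT},
                                                 {"category": entity})},
                "medical_only": {"n": self.n(category=entity,
                                             treatment=Treatment.MEDICAL_ONLY),
                                 "pct": self.share({"treatment": Treatment.MEDICAL_ONLY},
                                                   {"category": entity})},
            },
            "survival": {
                "medical_overall": surv(self.survival(
                    category=entity, treatment=Treatment.MEDICAL_ONLY)),
                "medical_hepatitis": surv(self.survival(
                    category=entity, hepatitis=True, treatment=Treatment.MEDICAL_ONLY)),
                "medical_non_hepatitis": surv(self.survival(
                    category=entity, hepatitis=False, treatment=Treatment.MEDICAL_ONLY)),
                "transplant": surv(self.survival(
                    category=entity, treatment=Treatment.TRANSPLANT)),
                "overall": surv(self.survival(category=entity)),
            },
            "survival_by_stratum": {},
            "etiology_groups": {},
        }
        for cat in (Category.ALF_WITHOUT_COMA, Category.ALF_WITH_COMA_ACUTE,
                    Category.ALF_WITH_COMA_SUBACUTE, Category.LOHF):
            for hep in (True, False):
                sr = self.survival(category=cat, hepatitis=hep,
                                   treatment=Treatment.MEDICAL_ONLY)
                if sr.total:
                    key = f"{cat.value}|{'hepatitis' if hep else 'non_hepatitis'}"
                    rep["survival_by_stratum"][key] = surv(sr)
        for grp in sorted(self.table.loc[self._mask({"category": entity}),
                                         "etiology_group"].unique()):
            rep["etiology_groups"][grp] = {
                "n": self.n(category=entity, etiology_group=grp),
                "pct": self.share({"etiology_group": grp}, {"category": entity})}
        return rep


def summarize(records: Sequence[PatientRecord],
              diagnoses: Sequence[DiagnosisResult]) -> CohortSummary:
    """Build a :class:`CohortSummary` from aligned records and diagnoses."""
    return CohortSummary(records, diagnoses)


def survival_rate(records: Iterable[PatientRecord],
                  filter: Callable[[PatientRecord], bool] = lambda r: True,
                  ) -> SurvivalRate:
    """Survival rate among records matching a predicate.

    Records with no recorded outcome are left out of the denominator; an
    empty stratum yields ``SurvivalRate(0, 0)`` whose percent is None.
    """
    survived = total = 0
    for rec in records:
        if not filter(rec) or rec.outcome is None:
            continue
        total += 1
        survived += rec.outcome.alive
    return SurvivalRate(survived, total)


def evaluate_predictions(predicted_death: Sequence[bool],
                         observed_death: Sequence[bool]) -> ConfusionMetrics:
    """Confusion-matrix metrics of a death prediction ("death" = positive)."""
    if len(predicted_death) != len(observed_death):
        raise AlignmentError(f"{len(predicted_death)} predictions vs "
                             f"{len(observed_death)} observations")
    if not predicted_death:
        raise AlignmentError("cannot evaluate an empty prediction vector")
    tp = fp = tn = fn = 0
    for p, o in zip(predicted_death, observed_death):
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and o:
            fn += 1
        else:
            tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
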