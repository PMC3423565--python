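"""Outcome prediction for fulminant hepatitis / LOHF.

Two instruments are implemented:

* the 2011 six-parameter prognostic score — each parameter (onset-to-
  encephalopathy interval, PT%, total bilirubin, direct/total bilirubin
  ratio, platelets, liver atrophy) contributes a subscore, the total maps to
  a predicted-mortality band, and a total of 5 or more calls "death";

* the 1996 two-step transplant-candidacy guideline — at the onset of
  grade >= II encephalopathy a patient meeting at least 2 of 5 criteria is
  listed as a transplant candidate, and after 5 days of intensive therapy
  (artificial liver support) the call is revised to "alive" when both the
  encephalopathy (to grade <= I, or attenuation by >= 2 grades) and the PT
  (to over 50 %) have improved.

Subscore cut points::

    score                0         1            2
    O-C interval (d)    <=5       6-10         >=11
    PT (%)              >20       (5, 20]      <=5
    TB (mg/dL)          <10       [10, 15)     >=15
    D/T ratio           >=0.7     [0.5, 0.7)   <0.5
    PLT (10^4/uL)       >10       (5, 10]      <=5
    liver atrophy       absent    present

The atrophy subscore is 0/1 by default (making the maximum total 11); the
printed table is typographically ambiguous about whether "present" is worth
1 or 2 points, so the weight is configurable.  Both instruments are defined
only for patients with grade >= II encephalopathy; missing parameters are
refused, never defaulted (an ``allow_partial`` mode reporting the attainable
score range is offered as an explicitly non-standard extension).

Note the guideline's cut points (PT <10 %, TB >=18.0, D/T <0.67) are
deliberately *not* harmonized with the score's: the two instruments were
published 15 years apart and are kept exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .errors import ConfigError, MissingDataError, PreconditionError
from .records import ComaGrade, PatientRecord

__all__ = [
    "PARAMETERS", "PrognosisConfig", "MortalityBand", "PrognosticScore",
    "GuidelineAssessment", "Day5Reassessment",
    "score_component", "total_score", "partial_score_range",
    "mortality_band", "transplant_candidate_initial", "reassess_day5",
]

PARAMETERS = ("oc_days", "pt", "tb", "dt_ratio", "plt", "atrophy")


@dataclass(frozen=True)
class MortalityBand:
    """Predicted-mortality band for a total score: [lower, upper] percent
    (upper bound open for the top band, lower bound open for the bottom)."""

    lower_percent: float
    upper_percent: float
    label: str


# (min_total, max_total) -> band; the top row covers every attainable
# maximum (11 with the default 0/1 atrophy weight, 12 with 0/2)
_DEFAULT_BANDS: tuple[tuple[int, int, MortalityBand], ...] = (
    (7, 12, MortalityBand(90.0, 100.0, ">90%")),
    (6, 6, MortalityBand(80.0, 90.0, "80-90%")),
    (5, 5, MortalityBand(70.0, 80.0, "70-80%")),
    (4, 4, MortalityBand(50.0, 60.0, "50-60%")),
    (0, 3, MortalityBand(0.0, 30.0, "<30%")),
)


@dataclass(frozen=True)
class PrognosisConfig:
    """Tunables of the scoring system (published values as defaults)."""

    death_threshold: int = 5
    atrophy_max_subscore: int = 1  # 1 per the two printed cells; 2 selectable
    bands: tuple[tuple[int, int, MortalityBand], ...] = _DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.atrophy_max_subscore not in (1, 2):
            raise ConfigError("atrophy_max_subscore must be 1 or 2")
        if not (0 <= self.death_threshold <= self.max_total + 1):
            raise ConfigError(f"death_threshold {self.death_threshold} out of range")
        covered = sorted(t for lo, hi, _ in self.bands for t in range(lo, hi + 1))
        if covered != list(range(0, max(covered) + 1)) or max(covered) < self.max_total:
            raise ConfigError("mortality bands must partition the score range")

    @property
    def max_total(self) -> int:
        return 10 + self.atrophy_max_subscore


DEFAULT_CONFIG = PrognosisConfig()


@dataclass(frozen=True)
class PrognosticScore:
    """Six subscores, their total, the mortality band, and the death call."""

    subscores: Mapping[str, int]
    total: int
    band: MortalityBand
    death_call: bool


@dataclass(frozen=True)
class Day5Reassessment:
    coma_improved: bool
    pt_improved: bool

    @property
    def reassessed_alive(self) -> bool:
        return self.coma_improved and self.pt_improved


@dataclass(frozen=True)
class GuidelineAssessment:
    """First-step guideline result, optionally amended by the day-5 step."""

    criteria_met: frozenset[str]
    candidate: bool
    day5: Day5Reassessment | None = None

    @property
    def n_met(self) -> int:
        return len(self.criteria_met)

    @property
    def predicted_death(self) -> bool:
        """"Death" call: listed as a candidate and not revised to alive."""
        if not self.candidate:
            return False
        return self.day5 is None or not self.day5.reassessed_alive


# ---------------------------------------------------------------------------
# Scoring system
# ---------------------------------------------------------------------------

def score_component(parameter: str, value: float | bool,
                    config: PrognosisConfig = DEFAULT_CONFIG) -> int:
    """Subscore of one parameter (see the cut-point table in the module
    docstring).  ``atrophy`` takes a boolean; all others take numbers."""
    if value is None:
        raise MissingDataError(f"cannot score missing parameter {parameter!r}",
                               missing=[parameter])
    if parameter == "oc_days":
        return 0 if value <= 5 else (1 if value <= 10 else 2)
    if parameter == "pt":
        return 0 if value > 20 else (1 if value > 5 else 2)
    if parameter == "tb":
        return 0 if value < 10 else (1 if value < 15 else 2)
    if parameter == "dt_ratio":
        return 0 if value >= 0.7 else (1 if value >= 0.5 else 2)
    if parameter == "plt":
        return 0 if value > 10 else (1 if value > 5 else 2)
    if parameter == "atrophy":
        return config.atrophy_max_subscore if value else 0
    raise ValueError(f"unknown score parameter {parameter!r}")


def _parameter_values(record: PatientRecord) -> dict[str, float | bool | None]:
    return {
        "oc_days": record.onset_to_encephalopathy_days,
        "pt": record.labs.pt_percent,
        "tb": record.labs.total_bilirubin,
        "dt_ratio": record.labs.dt_ratio,
        "plt": record.labs.platelets,
        "atrophy": record.liver_atrophy,
    }


def _require_coma(record: PatientRecord, what: str) -> ComaGrade:
    grade = record.resolved_coma_grade()
    if grade < ComaGrade.II:
        raise PreconditionError(
            f"{what} is defined only for grade >= II encephalopathy "
            f"(patient {record.patient_id!r} has grade {grade})")
    return grade


def total_score(record: PatientRecord,
                config: PrognosisConfig = DEFAULT_CONFIG) -> PrognosticScore:
    """Total prognostic score for one fulminant-hepatitis/LOHF record.

    Requires grade >= II encephalopathy and all six parameters; any missing
    parameter is refused with a :class:`MissingDataError` naming it.
    """
    _require_coma(record, "the prognostic score")
    values = _parameter_values(record)
    missing = [p for p, v in values.items() if v is None]
    if missing:
        raise MissingDataError("cannot compute the prognostic score",
                               missing=missing, patient_id=record.patient_id)
    subscores = {p: score_component(p, v, config) for p, v in values.items()}
    total = sum(subscores.values())
    return PrognosticScore(
        subscores=subscores,
        total=total,
        band=mortality_band(total, config),
        death_call=total >= config.death_threshold,
    )


def partial_score_range(record: PatientRecord,
                        config: PrognosisConfig = DEFAULT_CONFIG,
                        ) -> tuple[int, int, list[str]]:
    """(min, max) attainable total given the observed parameters, plus the
    names of the missing ones.  Extension beyond the published system: the
    score itself never imputes — this only brackets it."""
    _require_coma(record, "the prognostic score")
    values = _parameter_values(record)
    lo = hi = 0
    missing: list[str] = []
    for p, v in values.items():
        if v is None:
            missing.append(p)
            hi += config.atrophy_max_subscore if p == "atrophy" else 2
        else:
            s = score_component(p, v, config)
            lo += s
            hi += s
    return lo, hi, missing


def mortality_band(total: int, config: PrognosisConfig = DEFAULT_CONFIG) -> MortalityBand:
    """Predicted-mortality band for a total score (0..max_total)."""
    if not (0 <= total <= config.max_total):
        raise ValueError(f"total score {total} outside [0, {config.max_total}]")
    for lo, hi, band in config.bands:
        if lo <= total <= hi:
            return band
    raise AssertionError("bands partition the range")  # unreachable by config check


# ---------------------------------------------------------------------------
# 1996 transplant-candidacy guideline
# ---------------------------------------------------------------------------

def transplant_candidate_initial(record: PatientRecord) -> GuidelineAssessment:
    """First-step assessment at the onset of grade >= II encephalopathy.

    Poor-prognosis criteria: age >= 45 y; onset-to-encephalopathy interval
    >= 11 d; PT < 10 %; total bilirubin >= 18.0 mg/dL; D/T ratio < 0.67.
    Meeting at least 2 lists the patient as a transplant candidate
    (estimated prognosis "death").
    """
    _require_coma(record, "the transplant guideline")
    needed = {
        "interval": record.onset_to_encephalopathy_days,
        "pt": record.labs.pt_percent,
        "bilirubin": record.labs.total_bilirubin,
        "dt_ratio": record.labs.dt_ratio,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise MissingDataError("cannot assess transplant candidacy",
                               missing=missing, patient_id=record.patient_id)
    met = set()
    if record.age_years >= 45:
        met.add("age")
    if needed["interval"] >= 11:
        met.add("interval")
    if needed["pt"] < 10:
        met.add("pt")
    if needed["bilirubin"] >= 18.0:
        met.add("bilirubin")
    if needed["dt_ratio"] < 0.67:
        met.add("dt_ratio")
    return GuidelineAssessment(criteria_met=frozenset(met), candidate=len(met) >= 2)


def reassess_day5(initial: GuidelineAssessment, coma_at_onset: ComaGrade,
                  coma_day5: ComaGrade, pt_day5: float) -> GuidelineAssessment:
    """Second-step reassessment 5 days after encephalopathy onset.

    The prognosis flips to "alive" (and the patient leaves the candidate
    list) only when both hold: the encephalopathy has improved to grade I or
    less or attenuated by 2 or more grades, and the PT has improved to over
    50 % of the standardized value.  A death call can only be revised toward
    alive, never the reverse.
    """
    if not initial.candidate:
        raise PreconditionError(
            "day-5 reassessment applies only to transplant candidates")
    coma_improved = (coma_day5 <= ComaGrade.I
                     or (int(coma_at_onset) - int(coma_day5)) >= 2)
    pt_improved = pt_day5 > 50.0
    return replace(initial, day5=Day5Reassessment(coma_improved, pt_improved))
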