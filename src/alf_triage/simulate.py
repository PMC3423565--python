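"""Seeded synthetic patient cohorts emulating the 2010 survey structure.

The generator draws, per patient, a (category, hepatitis) stratum, then
laboratory values, coma grade, intervals, etiology, treatment arm and
outcome that are *consistent with that stratum by construction*: PT% is
truncated below the qualifying cutoff, the onset-to-encephalopathy interval
falls inside the category's window, and outcomes follow the stratum's
survival probability.  Classifying a generated cohort therefore recovers
the stratum frequencies up to binomial noise.

Defaults are derived from the packaged survey tables (stratum shares,
per-stratum medical survival, per-stratum transplant fractions whose
mixture equals the survey's 29/220, transplant survival 18/29, etiology
mixes).  The lab distributions themselves are synthetic: the survey prints
no laboratory distributions, so class-conditional truncated log-normals
(location/scale constants below) stand in for them.

One integer seed drives a single ``numpy.random.Generator``; no global
state is touched, and equal seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classification import Category
from .errors import ConfigError
from .records import (ComaGrade, DrugSub, Etiology, EtiologyCode, LabPanel,
                      Outcome, PatientRecord, Treatment, ViralSub)
from . import survey

__all__ = ["StratumKey", "LabModel", "GeneratorConfig", "default_config",
           "generate"]

# stratum key: (category value, hepatitis flag)
StratumKey = tuple[str, bool]


@dataclass(frozen=True)
class LabModel:
    """Class-conditional sampling model for one diagnostic category.

    Log-normal parameters are (mu, sigma) of the underlying normal;
    ``*_range`` bounds are enforced by rejection (resampling).  All values
    are synthetic constants — see the module docstring.
    """

    pt_lognorm: tuple[float, float] = (3.0, 0.45)     # percent; worse = lower
    pt_range: tuple[float, float] = (2.0, 40.0)
    inr_lognorm: tuple[float, float] = (0.75, 0.35)
    inr_range: tuple[float, float] = (1.5, 12.0)
    tb_lognorm: tuple[float, float] = (2.2, 0.6)      # mg/dL
    tb_range: tuple[float, float] = (0.5, 45.0)
    dt_mean_sd: tuple[float, float] = (0.62, 0.12)    # truncated normal
    dt_range: tuple[float, float] = (0.1, 0.92)
    plt_lognorm: tuple[float, float] = (2.2, 0.5)     # 10^4/uL
    plt_range: tuple[float, float] = (1.0, 40.0)
    atrophy_prevalence: float = 0.2
    interval_days: tuple[int, int] = (0, 10)          # O-C window (coma classes)
    labs_weeks: tuple[float, float] = (0.5, 8.0)      # qualifying-lab time (no coma)
    coma_grade_probs: tuple[float, ...] = (0.45, 0.3, 0.15, 0.1)  # II..V

    def validate(self, category: str) -> None:
        for name in ("pt_range", "inr_range", "tb_range", "dt_range",
                     "plt_range", "labs_weeks"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{category}: {name} ({lo}, {hi}) is empty")
        if self.pt_range[0] < 0 or self.pt_range[1] > 150:
            raise ConfigError(f"{category}: pt_range outside [0, 150]")
        if not (0 <= self.atrophy_prevalence <= 1):
            raise ConfigError(f"{category}: atrophy_prevalence outside [0, 1]")
        lo, hi = self.interval_days
        if lo > hi or lo < 0:
            raise ConfigError(f"{category}: interval_days ({lo}, {hi}) is empty")
        if abs(sum(self.coma_grade_probs) - 1) > 1e-9:
            raise ConfigError(f"{category}: coma_grade_probs must sum to 1")


def _default_lab_models() -> dict[str, LabModel]:
    # Severity ordering across classes: subacute/LOHF run deeper jaundice,
    # lower D/T ratios and more atrophy than the acute type; coma-free
    # patients sit nearer the qualifying cutoffs.
    return {
        Category.ALF_WITHOUT_COMA.value: LabModel(
            pt_lognorm=(3.4, 0.3), tb_lognorm=(1.8, 0.6),
            dt_mean_sd=(0.68, 0.1), atrophy_prevalence=0.05,
            coma_grade_probs=(0.45, 0.3, 0.15, 0.1)),
        Category.ALF_WITH_COMA_ACUTE.value: LabModel(
            pt_lognorm=(2.7, 0.5), tb_lognorm=(2.1, 0.6),
            dt_mean_sd=(0.66, 0.11), atrophy_prevalence=0.25,
            interval_days=(0, 10)),
        Category.ALF_WITH_COMA_SUBACUTE.value: LabModel(
            pt_lognorm=(2.9, 0.45), tb_lognorm=(2.7, 0.45),
            dt_mean_sd=(0.55, 0.13), atrophy_prevalence=0.45,
            interval_days=(11, 56)),
        Category.LOHF.value: LabModel(
            pt_lognorm=(2.9, 0.45), tb_lognorm=(2.8, 0.45),
            dt_mean_sd=(0.52, 0.13), atrophy_prevalence=0.5,
            interval_days=(57, 168)),
    }


# etiology mixes: hepatitis strata per category (viral / indeterminate /
# autoimmune / drug-allergy), non-hepatitis pooled (survey-reported counts)
_NON_HEPATITIS_ETIOLOGIES: tuple[tuple[Etiology, float], ...] = (
    (Etiology.IV_CIRCULATORY, 6 / 23),
    (Etiology.V_MALIGNANT_INFILTRATION, 5 / 23),
    (Etiology.VII_POST_RESECTION_TRANSPLANT, 4 / 23),
    (Etiology.VI_METABOLIC, 3 / 23),
    (Etiology.VIII_MISCELLANEOUS, 3 / 23),
    (Etiology.III_DRUG, 2 / 23),  # toxicity subtype
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator configuration; defaults come from the survey tables
    (see :func:`default_config`)."""

    n_patients: int
    seed: int
    stratum_probs: Mapping[StratumKey, float]
    survival_probs: Mapping[StratumKey, float]          # medical arm
    transplant_probs: Mapping[StratumKey, float]
    transplant_survival_prob: float
    lab_models: Mapping[str, LabModel] = field(default_factory=_default_lab_models)
    hepatitis_etiology_mix: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict)  # (viral, indeterminate, autoimmune, drug_allergy)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        total = sum(self.stratum_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"stratum_probs sum to {total}, expected 1")
        for name, mapping in (("stratum_probs", self.stratum_probs),
                              ("survival_probs", self.survival_probs),
                              ("transplant_probs", self.transplant_probs)):
            for key, p in mapping.items():
                if not (0 <= p <= 1):
                    raise ConfigError(f"{name}[{key}] = {p} outside [0, 1]")
        if not (0 <= self.transplant_survival_prob <= 1):
            raise ConfigError("transplant_survival_prob outside [0, 1]")
        for key in self.stratum_probs:
            cat = key[0]
            if cat not in self.lab_models:
                raise ConfigError(f"no lab model for category {cat}")
            if key not in self.survival_probs:
                raise ConfigError(f"no survival probability for stratum {key}")
        for cat, model in self.lab_models.items():
            model.validate(cat)
        for cat, mix in self.hepatitis_etiology_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError(f"hepatitis_etiology_mix[{cat}] must sum to 1")


def default_config(n_patients: int = 220, seed: int = 0) -> GeneratorConfig:
    """Configuration whose targets are the packaged survey tables.

    Stratum shares, medical-arm survival and per-stratum transplant
    fractions are read off the strata fixture, so the generator and the
    golden summary tests share one source of truth.
    """
    strata = survey.load_strata()
    total = int(strata["count"].sum())
    by_stratum = strata.groupby(["category", "hepatitis"])
    stratum_probs: dict[StratumKey, float] = {}
    survival_probs: dict[StratumKey, float] = {}
    transplant_probs: dict[StratumKey, float] = {}
    for (cat, hep), sub in by_stratum:
        key = (cat, bool(hep))
        n_str = int(sub["count"].sum())
        stratum_probs[key] = n_str / total
        med = sub[sub["treatment"] == "medical_only"]
        n_med = int(med["count"].sum())
        n_med_alive = int(med.loc[med["outcome"] == "survived", "count"].sum())
        survival_probs[key] = n_med_alive / n_med if n_med else 0.0
        n_tx = int(sub.loc[sub["treatment"] == "transplant", "count"].sum())
        transplant_probs[key] = n_tx / n_str if n_str else 0.0
    tx = strata[strata["treatment"] == "transplant"]
    n_tx_total = int(tx["count"].sum())
    n_tx_alive = int(tx.loc[tx["outcome"] == "transplanted_alive", "count"].sum())

    etio = survey.load_etiology()
    mix: dict[str, tuple[float, float, float, float]] = {}
    for cat, sub in etio.groupby("category"):
        counts = dict(zip(sub["etiology_group"], sub["count"]))
        hep_total = sum(v for k, v in counts.items() if k != "non_hepatitis")
        other = counts.get("other_hepatitis", 0)
        # the "other hepatitis" remainder splits evenly between autoimmune
        # and drug allergy (no per-category counts are reported for them)
        mix[cat] = (counts.get("viral", 0) / hep_total,
                    counts.get("indeterminate", 0) / hep_total,
                    other / 2 / hep_total, other / 2 / hep_total)

    cfg = GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        stratum_probs=stratum_probs,
        survival_probs=survival_probs,
        transplant_probs=transplant_probs,
        transplant_survival_prob=n_tx_alive / n_tx_total,
        hepatitis_etiology_mix=mix,
    )
    cfg.validate()
    return cfg


def _trunc_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                     lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.lognormal(mu, sigma)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(rng.lognormal(mu, sigma), lo), hi))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(rng.normal(mean, sd), lo), hi))


def _sample_etiology(rng: np.random.Generator, category: str, hepatitis: bool,
                     config: GeneratorConfig) -> EtiologyCode:
    if not hepatitis:
        probs = np.array([p for _, p in _NON_HEPATITIS_ETIOLOGIES])
        i = int(rng.choice(len(_NON_HEPATITIS_ETIOLOGIES), p=probs / probs.sum()))
        major = _NON_HEPATITIS_ETIOLOGIES[i][0]
        if major is Etiology.III_DRUG:
            return EtiologyCode(major, drug_sub=DrugSub.TOXICITY)
        return EtiologyCode(major)
    mix = config.hepatitis_etiology_mix.get(category, (0.45, 0.35, 0.1, 0.1))
    i = int(rng.choice(4, p=np.asarray(mix) / sum(mix)))
    if i == 0:
        viral_sub = ViralSub(rng.choice([ViralSub.HBV_TRANSIENT.value,
                                         ViralSub.HBV_CARRIER_INACTIVE.value,
                                         ViralSub.HAV.value,
                                         ViralSub.OTHER.value],
                                        p=[0.5, 0.25, 0.15, 0.1]))
        return EtiologyCode(Etiology.I_VIRAL, viral_sub=viral_sub)
    if i == 1:
        return EtiologyCode(Etiology.IX_INDETERMINATE)
    if i == 2:
        return EtiologyCode(Etiology.II_AUTOIMMUNE)
    return EtiologyCode(Etiology.III_DRUG, drug_sub=DrugSub.ALLERGY)


def generate(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate a validated synthetic cohort (deterministic given the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    keys = sorted(config.stratum_probs)           # deterministic order
    probs = np.array([config.stratum_probs[k] for k in keys])
    records: list[PatientRecord] = []
    if config.n_patients == 0:
        return records
    draws = rng.choice(len(keys), size=config.n_patients, p=probs)
    for idx, ki in enumerate(draws, start=1):
        category, hepatitis = keys[int(ki)]
        model = config.lab_models[category]
        pt = _trunc_lognormal(rng, *model.pt_lognorm, *model.pt_range)
        inr = _trunc_lognormal(rng, *model.inr_lognorm, *model.inr_range)
        tb = _trunc_lognormal(rng, *model.tb_lognorm, *model.tb_range)
        dt = _trunc_normal(rng, *model.dt_mean_sd, *model.dt_range)
        plt = _trunc_lognormal(rng, *model.plt_lognorm, *model.plt_range)
        atrophy = bool(rng.random() < model.atrophy_prevalence)

        if category == Category.ALF_WITHOUT_COMA.value:
            grade = ComaGrade.NONE if rng.random() < 0.5 else ComaGrade.I
            oc_days = None
            weeks = float(rng.uniform(*model.labs_weeks))
        else:
            grade = ComaGrade(int(rng.choice([2, 3, 4, 5],
                                             p=model.coma_grade_probs)))
            lo, hi = model.interval_days
            oc_days = int(rng.integers(lo, hi + 1))
            weeks = round(oc_days / 7.0, 2)

        stratum = (category, hepatitis)
        if rng.random() < config.transplant_probs.get(stratum, 0.0):
            treatment = Treatment.TRANSPLANT
            alive = rng.random() < config.transplant_survival_prob
            outcome = Outcome.TRANSPLANTED_ALIVE if alive else Outcome.TRANSPLANTED_DEAD
        else:
            treatment = Treatment.MEDICAL_ONLY
            alive = rng.random() < config.survival_probs[stratum]
            outcome = Outcome.SURVIVED if alive else Outcome.DIED

        age = int(np.clip(rng.normal(55, 18), 16, 92))
        rec = PatientRecord(
            patient_id=f"G{idx:05d}",
            age_years=age,
            labs=LabPanel(pt_percent=round(pt, 1), inr=round(inr, 2),
                          total_bilirubin=round(tb, 1),
                          # rounding the total down must not push direct past it
                          direct_bilirubin=min(round(tb * dt, 2), round(tb, 1)),
                          platelets=round(plt, 1)),
            etiology=_sample_etiology(rng, category, hepatitis, config),
            onset_to_encephalopathy_days=oc_days,
            onset_to_labs_weeks=weeks,
            liver_atrophy=atrophy,
            coma_grade=grade,
            prior_liver_function_normal=True,
            habitual_alcohol_as_cause=False,
            treatment=treatment,
            outcome=outcome,
        )
        rec.validate()
        records.append(rec)
    return records
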