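"""Hepatic-encephalopathy grading from structured clinical-feature flags.

Adults are graded on the Inuyama 1972 coma scale (grades I-V); children and
infants on the 5th Workshop on Pediatric Liver Diseases (1988) scale.  Both
graders return the *highest* grade whose defining criteria are satisfied,
evaluating V down to I; a patient with no positive feature has no
encephalopathy (grade NONE).

Only the defining psychiatric-disorder items confer grade membership; the
accompanying reference findings (e.g. flapping tremor being *observable* in
grade III) overlap across grades and are treated as illustrative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MissingDataError, ValidationError
from .records import ComaGrade

__all__ = ["ClinicalFeatures", "PediatricFeatures",
           "grade_coma", "grade_coma_pediatric"]


@dataclass(frozen=True)
class ClinicalFeatures:
    """Adult coma-scale feature flags, one per defining criterion.

    ``responds_to_pain`` and ``no_response_to_pain`` are mutually exclusive;
    with complete loss of consciousness exactly one of them must be set to
    separate grade IV (pain response preserved) from grade V (deep coma).
    """

    # grade I
    sleep_inversion: bool = False
    euphoria_or_depression: bool = False
    shortened_attention: bool = False
    # grade II
    disorientation_time_place: bool = False
    inappropriate_behavior: bool = False
    somnolent_but_responds: bool = False
    flapping_tremor: bool = False
    # grade III
    excitation_or_delirium: bool = False
    sleeps_mostly_opens_eyes_to_stimulus: bool = False
    follows_only_simple_orders: bool = False
    # grades IV / V
    complete_loss_of_consciousness: bool = False
    responds_to_pain: bool = False
    no_response_to_pain: bool = False


@dataclass(frozen=True)
class PediatricFeatures:
    """Pediatric/infant coma-scale feature flags.

    Grades I and II carry parallel items for children (lethargy;
    obedient-somnolent attitude or disorientation) and for infants (does not
    laugh aloud; does not laugh when played with / no maternal eye contact).
    Grades III-V are shared: eye opening only to a loud voice; no waking to
    pain but grimacing or brushing away the stimulus; no response to pain.
    """

    # grade I
    lethargic_low_spirited: bool = False
    does_not_laugh_aloud: bool = False
    # grade II
    obedient_somnolent_or_disoriented: bool = False
    no_laugh_when_played_or_no_eye_contact: bool = False
    # grades III-V
    opens_eyes_to_loud_voice: bool = False
    no_wake_to_pain_but_grimaces: bool = False
    no_response_to_pain: bool = False


def grade_coma(features: ClinicalFeatures) -> ComaGrade:
    """Grade adult hepatic encephalopathy from feature flags.

    Raises
    ------
    ValidationError
        If both pain-response flags are set.
    MissingDataError
        If consciousness is completely lost but the pain response was not
        assessed (neither pain flag set): grades IV and V cannot be told
        apart without it.
    """
    f = features
    if f.responds_to_pain and f.no_response_to_pain:
        raise ValidationError(
            "responds_to_pain and no_response_to_pain are mutually exclusive",
            field="responds_to_pain")
    if f.complete_loss_of_consciousness:
        if f.no_response_to_pain:
            return ComaGrade.V
        if f.responds_to_pain:
            return ComaGrade.IV
        raise MissingDataError(
            "complete loss of consciousness requires a pain-response "
            "assessment to separate grade IV from grade V",
            missing=["responds_to_pain", "no_response_to_pain"])
    if (f.excitation_or_delirium or f.sleeps_mostly_opens_eyes_to_stimulus
            or f.follows_only_simple_orders):
        return ComaGrade.III
    if (f.disorientation_time_place or f.inappropriate_behavior
            or f.somnolent_but_responds or f.flapping_tremor):
        return ComaGrade.II
    if f.sleep_inversion or f.euphoria_or_depression or f.shortened_attention:
        return ComaGrade.I
    return ComaGrade.NONE


def grade_coma_pediatric(features: PediatricFeatures) -> ComaGrade:
    """Grade pediatric/infant hepatic encephalopathy from feature flags."""
    f = features
    if f.no_response_to_pain and f.no_wake_to_pain_but_grimaces:
        raise ValidationError(
            "no_response_to_pain contradicts no_wake_to_pain_but_grimaces "
            "(grimacing is a pain response)", field="no_response_to_pain")
    if f.no_response_to_pain:
        return ComaGrade.V
    if f.no_wake_to_pain_but_grimaces:
        return ComaGrade.IV
    if f.opens_eyes_to_loud_voice:
        return ComaGrade.III
    if f.obedient_somnolent_or_disoriented or f.no_laugh_when_played_or_no_eye_contact:
        return ComaGrade.II
    if f.lethargic_low_spirited or f.does_not_laugh_aloud:
        return ComaGrade.I
    return ComaGrade.NONE


def _feature_grade_map(cls: type) -> dict[str, ComaGrade]:
    """Map each feature flag to the grade it defines (test/introspection aid)."""
    if cls is ClinicalFeatures:
        return {
            "sleep_inversion": ComaGrade.I,
            "euphoria_or_depression": ComaGrade.I,
            "shortened_attention": ComaGrade.I,
            "disorientation_time_place": ComaGrade.II,
            "inappropriate_behavior": ComaGrade.II,
            "somnolent_but_responds": ComaGrade.II,
            "flapping_tremor": ComaGrade.II,
            "excitation_or_delirium": ComaGrade.III,
            "sleeps_mostly_opens_eyes_to_stimulus": ComaGrade.III,
            "follows_only_simple_orders": ComaGrade.III,
        }
    if cls is PediatricFeatures:
        return {
            "lethargic_low_spirited": ComaGrade.I,
            "does_not_laugh_aloud": ComaGrade.I,
            "obedient_somnolent_or_disoriented": ComaGrade.II,
            "no_laugh_when_played_or_no_eye_contact": ComaGrade.II,
            "opens_eyes_to_loud_voice": ComaGrade.III,
            "no_wake_to_pain_but_grimaces": ComaGrade.IV,
            "no_response_to_pain": ComaGrade.V,
        }
    raise TypeError(cls)
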