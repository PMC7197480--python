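"""Ordinal health scoring and improvement classification.

Mecp2-null (Mecp2/Y) male mice are assessed weekly for five subjective
health parameters — hindlimb clasping, tremor, activity, general body
condition, and muscle tone — each scored 0 (equivalent to wild type),
1 (intermediate), or 2 (severe).  Body weight is scored on the same 0–2
scale from fixed gram anchors, and the six components sum to a composite
health score out of 12.  Founders and backcross (N3) offspring are then
classified *improved* or not from the composite score and/or longevity,
with separate longevity thresholds for the two screens (the colonies had
different life spans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

ORDINAL_LEVELS = (0, 1, 2)

SUBJECTIVE_PARAMETERS = (
    "clasping",
    "tremor",
    "activity",
    "body_condition",
    "muscle_tone",
)


class InvalidInputError(ValueError):
    """Raised when a score, weight, or classification input is out of range."""


def _check_ordinal(name: str, value: int) -> int:
    if value not in ORDINAL_LEVELS:
        raise InvalidInputError(
            f"{name} must be one of {ORDINAL_LEVELS}, got {value!r}"
        )
    return int(value)


@dataclass(frozen=True)
class HealthAssessment:
    """One animal-week of health observations.

    ``imputed_parameters`` flags subjective parameters that were not
    actually assessed and were entered as 0 (screen 1 initially scored
    four parameters; muscle tone was added later).  All five are scored
    through a single code path; the flag preserves provenance.
    """

    animal_id: str
    age_days: int
    clasping: int
    tremor: int
    activity: int
    body_condition: int
    muscle_tone: int
    body_weight_g: float
    imputed_parameters: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise InvalidInputError(f"age_days must be >= 0, got {self.age_days}")
        for name in SUBJECTIVE_PARAMETERS:
            _check_ordinal(name, getattr(self, name))
        if not math.isfinite(self.body_weight_g) or self.body_weight_g <= 0:
            raise InvalidInputError(
                f"body_weight_g must be positive and finite, got {self.body_weight_g!r}"
            )
        unknown = set(self.imputed_parameters) - set(SUBJECTIVE_PARAMETERS)
        if unknown:
            raise InvalidInputError(f"unknown imputed parameters: {sorted(unknown)}")

    @property
    def subjective_scores(self) -> Tuple[int, ...]:
        return tuple(getattr(self, name) for name in SUBJECTIVE_PARAMETERS)


@dataclass(frozen=True)
class HealthScore:
    """Composite score: five subjective parameters plus the weight score."""

    subjective_subtotal: int
    weight_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.subjective_subtotal <= 10:
            raise InvalidInputError(
                f"subjective_subtotal out of range: {self.subjective_subtotal}"
            )
        _check_ordinal("weight_score", self.weight_score)

    @property
    def total(self) -> int:
        return self.subjective_subtotal + self.weight_score


@dataclass(frozen=True)
class ImprovementRules:
    """Thresholds used to classify animals as improved.

    The composite-score threshold is strict (< 8 at 8 wk).  Longevity
    thresholds are 14 wk for screen 1 and 10 wk for screen 2.
    """

    founder_score_threshold: int = 8
    founder_assessment_age_weeks: int = 8
    screen1_longevity_days: int = 98
    screen2_longevity_days: int = 70

    def __post_init__(self) -> None:
        for name in (
            "founder_score_threshold",
            "founder_assessment_age_weeks",
            "screen1_longevity_days",
            "screen2_longevity_days",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")


DEFAULT_RULES = ImprovementRules()


def score_body_weight(weight_g: float) -> int:
    """Score body weight on the 0–2 severity scale.

    Anchors: 0 if <29 g, 1 if 30–34 g, 2 if >35 g.  The printed anchors
    leave [29, 30) and (34, 35] undefined, so the weight is first rounded
    half-up to the nearest gram and then scored 0 for <=29, 1 for 30–34,
    2 for >=35, which preserves the integer anchors exactly.
    """
    if not isinstance(weight_g, (int, float)) or isinstance(weight_g, bool):
        raise InvalidInputError(f"weight must be numeric, got {weight_g!r}")
    if not math.isfinite(weight_g) or weight_g <= 0:
        raise InvalidInputError(f"weight must be positive and finite, got {weight_g!r}")
    grams = math.floor(weight_g + 0.5)  # half-up rounding
    if grams <= 29:
        return 0
    if grams <= 34:
        return 1
    return 2


def total_health_score(assessment: HealthAssessment) -> HealthScore:
    """Sum the five subjective parameters and the weight score (max 12)."""
    subtotal = sum(assessment.subjective_scores)
    return HealthScore(
        subjective_subtotal=subtotal,
        weight_score=score_body_weight(assessment.body_weight_g),
    )


def classify_founder_improved(
    score_at_8wk: int, rules: ImprovementRules = DEFAULT_RULES
) -> bool:
    """Founder classification: improved iff the 8-wk composite score is < 8."""
    if not 0 <= score_at_8wk <= 12:
        raise InvalidInputError(f"score must be in 0..12, got {score_at_8wk}")
    return score_at_8wk < rules.founder_score_threshold


def classify_offspring_improved(
    screen: int,
    survival_days: int,
    censored: bool = False,
    score_at_8wk: Optional[int] = None,
    rules: ImprovementRules = DEFAULT_RULES,
) -> bool:
    """Classify an Mecp2/Y N3 animal as improved.

    Screen 1: improved iff it lived >= 14 wk (98 d).  Screen 2: improved
    iff it lived >= 10 wk (70 d) *and* had an improved composite score
    (< 8) at 8 wk.  An animal censored (sacrificed healthy) at or after
    the longevity threshold counts toward the threshold; censoring before
    it does not.
    """
    if screen not in (1, 2):
        raise InvalidInputError(f"screen must be 1 or 2, got {screen!r}")
    if survival_days < 0:
        raise InvalidInputError(f"survival_days must be >= 0, got {survival_days}")
    if screen == 1:
        return survival_days >= rules.screen1_longevity_days
    if score_at_8wk is None:
        raise InvalidInputError("screen 2 classification requires score_at_8wk")
    if not 0 <= score_at_8wk <= 12:
        raise InvalidInputError(f"score must be in 0..12, got {score_at_8wk}")
    return (
        survival_days >= rules.screen2_longevity_days
        and score_at_8wk < rules.founder_score_threshold
    )


def assessment_nearest_age(
    assessments: Sequence[HealthAssessment], age_days: int
) -> Optional[HealthAssessment]:
    """The assessment closest in age to ``age_days`` (ties -> earlier week)."""
    if not assessments:
        return None
    return min(assessments, key=lambda a: (abs(a.age_days - age_days), a.age_days))
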