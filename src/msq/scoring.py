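"""MSQ raw score, percent score and section/subscale subtotals.

The raw score is the plain sum of the 30 item points (0-314).  For reporting
it is expressed as a percentage, ``100 * raw / 314``, displayed as a
round-half-up integer; higher values mean better shoulder function.

Two policies are configurable:

* ``weight_policy`` — how the strength bag-lift weight maps to points.  The
  default ``per_kg`` awards 2 points per kilogram (24 points at the 12 kg
  maximum).  ``literal_500g`` awards 2 points per 500 g step and therefore
  saturates at the 24-point cap from 6 kg upward.
* ``missing_policy`` — ``strict`` (default) refuses to score incomplete
  questionnaires, mirroring their exclusion from analysis; ``prorate`` scales
  the answered subtotal by the ratio of full to answered maximum and flags
  the report as prorated.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel

from .errors import RangeError, ScoringError
from .instrument import (
    InstrumentDefinition,
    MSQResponse,
    Section,
    Subscale,
    MAX_LIFT_KG,
    LIFT_STEP_KG,
    validate_response,
)

WeightPolicy = Literal["per_kg", "literal_500g"]
MissingPolicy = Literal["strict", "prorate"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounded up."""
    return int(math.floor(x + 0.5))


class ScoreReport(BaseModel):
    """Scored MSQ for one respondent."""

    respondent_id: str
    raw: int
    percent: float
    percent_display: int
    objective_subtotal: int
    subjective_subtotal: int
    subscale_subtotals: dict[Subscale, int]
    complete: bool
    prorated: bool = False
    instrument_version: str = ""


def weight_to_points(
    lifted_weight_kg: float, policy: WeightPolicy = "per_kg"
) -> int:
    """Convert the bag-lift weight to strength-item points.

    ``per_kg`` (default): 2 points per kilogram, capped at 24.
    ``literal_500g``: 2 points per 500 g step, capped at 24 (saturates at 6 kg).
    """
    if not (0.0 <= lifted_weight_kg <= MAX_LIFT_KG):
        raise RangeError(
            f"lifted weight {lifted_weight_kg} kg outside [0, {MAX_LIFT_KG}]"
        )
    steps = lifted_weight_kg / LIFT_STEP_KG
    if abs(steps - round(steps)) > 1e-9:
        raise RangeError("lifted weight must be a multiple of 0.5 kg")
    if policy == "per_kg":
        pts = round_half_up(2.0 * lifted_weight_kg)
    elif policy == "literal_500g":
        pts = round_half_up(2.0 * steps)
    else:
        raise ValueError(f"unknown weight policy {policy!r}")
    return min(pts, 24)


def points_to_weight(points: int, policy: WeightPolicy = "per_kg") -> float:
    """Inverse of :func:`weight_to_points` (ambiguous above the cap; returns
    the smallest weight producing ``points``)."""
    if not 0 <= points <= 24:
        raise RangeError(f"strength points {points} outside [0, 24]")
    kg = points / 2.0 if policy == "per_kg" else points / 4.0
    return min(kg, MAX_LIFT_KG)


def effective_answers(
    response: MSQResponse,
    instrument: InstrumentDefinition,
    weight_policy: WeightPolicy = "per_kg",
) -> dict[int, int]:
    """Item answers with the strength item resolved from weight if needed."""
    answers = dict(response.answers)
    sid = instrument.strength_item.item_id
    if sid not in answers and response.lifted_weight_kg is not None:
        answers[sid] = weight_to_points(response.lifted_weight_kg, weight_policy)
    return answers


def raw_to_percent(raw: float, raw_max: int = 314) -> float:
    """Percent score: ``100 * raw / raw_max`` (full precision)."""
    if not (0 <= raw <= raw_max):
        raise RangeError(f"raw score {raw} outside [0, {raw_max}]")
    return 100.0 * raw / raw_max


def compute_raw_score(
    response: MSQResponse,
    instrument: InstrumentDefinition,
    missing_policy: MissingPolicy = "strict",
    weight_policy: WeightPolicy = "per_kg",
) -> int:
    """Sum of item points (strength converted from weight when needed)."""
    return section_subtotals(
        response, instrument, missing_policy=missing_policy,
        weight_policy=weight_policy,
    ).raw


def section_subtotals(
    response: MSQResponse,
    instrument: InstrumentDefinition,
    missing_policy: MissingPolicy = "strict",
    weight_policy: WeightPolicy = "per_kg",
) -> ScoreReport:
    """Full score report: raw, percent and per-section/subscale subtotals."""
    check = validate_response(response, instrument)
    if check.issues:
        raise ScoringError(
            f"{check.respondent_id}: invalid answers: {'; '.join(check.issues)}"
        )
    if not check.complete and missing_policy == "strict":
        raise ScoringError(
            f"{check.respondent_id}: incomplete questionnaire, "
            f"missing items {check.missing_items}"
        )

    answers = effective_answers(response, instrument, weight_policy)
    sub: dict[Subscale, int] = {s: 0 for s in Subscale}
    answered_max = 0
    for it in instrument.items:
        if it.item_id in answers:
            sub[it.subscale] += answers[it.item_id]
            answered_max += it.max_points

    prorated = False
    if not check.complete:  # missing_policy == "prorate"
        if answered_max == 0:
            raise ScoringError(
                f"{check.respondent_id}: no answers present, cannot prorate"
            )
        # scale each subscale against its own answered maximum
        for s in Subscale:
            s_answered = sum(
                it.max_points
                for it in instrument.items_in(s)
                if it.item_id in answers
            )
            if 0 < s_answered < instrument.subscale_max(s):
                sub[s] = round_half_up(sub[s] * instrument.subscale_max(s) / s_answered)
        prorated = True

    objective = sum(sub[s] for s in (Subscale.rom, Subscale.strength))
    subjective = sum(
        sub[s]
        for s in (
            Subscale.pain,
            Subscale.work_daily,
            Subscale.sport_recreation,
            Subscale.quality_of_life,
        )
    )
    raw = objective + subjective
    percent = raw_to_percent(raw, instrument.raw_max)
    return ScoreReport(
        respondent_id=response.demographics.respondent_id,
        raw=raw,
        percent=percent,
        percent_display=round_half_up(percent),
        objective_subtotal=objective,
        subjective_subtotal=subjective,
        subscale_subtotals=sub,
        complete=check.complete,
        prorated=prorated,
        instrument_version=instrument.version,
    )


def subscale_weights(instrument: InstrumentDefinition) -> dict[Subscale, int]:
    """Percent of the total score carried by each subscale (round half up)."""
    return {
        s: round_half_up(100.0 * instrument.subscale_max(s) / instrument.raw_max)
        for s in Subscale
    }


def section_weights(instrument: InstrumentDefinition) -> dict[Section, int]:
    """Percent of the total score carried by each section (round half up)."""
    return {
        sec: round_half_up(100.0 * instrument.section_max(sec) / instrument.raw_max)
        for sec in Section
    }
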