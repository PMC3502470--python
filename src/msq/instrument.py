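"""Machine-readable definition of the Munich Shoulder Questionnaire item bank.

The MSQ is a 30-item shoulder self-assessment instrument.  Five range-of-motion
items and one strength item (a standardised bag lift, up to 12 kg in 0.5 kg
steps, 2 points per kilogram for a 24-point maximum) form the objective
section; six pain, nine work/daily-activity, six sport/recreation and three
quality-of-life items form the subjective section.  Every other item scores
0-10 points, so the raw score spans 0-314 with higher values indicating better
function.

This module holds the declarative item bank (:class:`InstrumentDefinition`),
typed respondent records (:class:`MSQResponse`) and completeness validation.
Scoring itself lives in :mod:`msq.scoring`.
"""

from __future__ import annotations

import datetime as _dt
import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import pydantic
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import DefinitionError, ResponseError, StructuralError

MAX_LIFT_KG = 12.0
LIFT_STEP_KG = 0.5

_DEFAULT_DOCUMENT = "msq_instrument_v1.json"

#: Required number of items per subscale for a valid MSQ definition.
SUBSCALE_CARDINALITY = {
    "rom": 5,
    "strength": 1,
    "pain": 6,
    "work_daily": 9,
    "sport_recreation": 6,
    "quality_of_life": 3,
}


class Section(str, Enum):
    objective = "objective"
    subjective = "subjective"


class Subscale(str, Enum):
    rom = "rom"
    strength = "strength"
    pain = "pain"
    work_daily = "work_daily"
    sport_recreation = "sport_recreation"
    quality_of_life = "quality_of_life"


class ItemDefinition(BaseModel):
    """One question of the item bank with its point range."""

    model_config = ConfigDict(frozen=True)

    item_id: int = Field(ge=1, le=30)
    label: str
    section: Section
    subscale: Subscale
    min_points: int = 0
    max_points: int
    response_step: int = 1

    @field_validator("min_points")
    @classmethod
    def _min_is_zero(cls, v: int) -> int:
        if v != 0:
            raise ValueError("min_points must be 0")
        return v

    @field_validator("max_points")
    @classmethod
    def _max_allowed(cls, v: int) -> int:
        if v not in (10, 24):
            raise ValueError("max_points must be 10 (or 24 for the strength item)")
        return v

    def allowed(self, value: int) -> bool:
        """Whether ``value`` is a permitted integer answer for this item."""
        return (
            isinstance(value, int)
            and self.min_points <= value <= self.max_points
            and (value - self.min_points) % self.response_step == 0
        )


class InstrumentDefinition(BaseModel):
    """The complete, validated 30-item bank."""

    model_config = ConfigDict(frozen=True)

    version: str
    items: tuple[ItemDefinition, ...]
    raw_max: int = 314

    @pydantic.model_validator(mode="after")
    def _structure(self) -> "InstrumentDefinition":
        if len(self.items) != 30:
            raise StructuralError(f"expected 30 items, got {len(self.items)}")
        ids = [it.item_id for it in self.items]
        if sorted(ids) != list(range(1, 31)):
            raise StructuralError("item_ids must be exactly 1..30")
        counts: dict[str, int] = {}
        for it in self.items:
            counts[it.subscale.value] = counts.get(it.subscale.value, 0) + 1
        if counts != SUBSCALE_CARDINALITY:
            raise StructuralError(
                f"subscale cardinalities {counts} != required {SUBSCALE_CARDINALITY}"
            )
        for it in self.items:
            obj = it.subscale in (Subscale.rom, Subscale.strength)
            if obj != (it.section is Section.objective):
                raise StructuralError(
                    f"item {it.item_id}: section/subscale mismatch"
                )
            if it.subscale is Subscale.strength and it.max_points != 24:
                raise StructuralError("strength item must score 0-24")
            if it.subscale is not Subscale.strength and it.max_points != 10:
                raise StructuralError(f"item {it.item_id} must score 0-10")
        total = sum(it.max_points for it in self.items)
        if total != self.raw_max:
            raise StructuralError(
                f"raw_max {self.raw_max} != sum of item maxima {total}"
            )
        return self

    # -- convenience accessors -------------------------------------------------

    def item(self, item_id: int) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise ResponseError(f"unknown item_id {item_id}")

    def items_in(self, subscale: Subscale) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.subscale is subscale)

    def items_in_section(self, section: Section) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.section is section)

    def subscale_max(self, subscale: Subscale) -> int:
        return sum(it.max_points for it in self.items_in(subscale))

    def section_max(self, section: Section) -> int:
        return sum(it.max_points for it in self.items_in_section(section))

    @property
    def strength_item(self) -> ItemDefinition:
        return self.items_in(Subscale.strength)[0]

    def to_document(self) -> dict:
        """Serialise back to the JSON document layout."""
        return {
            "version": self.version,
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "section": it.section.value,
                    "subscale": it.subscale.value,
                    "min_points": it.min_points,
                    "max_points": it.max_points,
                    "response_step": it.response_step,
                }
                for it in self.items
            ],
        }


class Sex(str, Enum):
    male = "male"
    female = "female"


class SideLR(str, Enum):
    left = "left"
    right = "right"


class AffectedSide(str, Enum):
    left = "left"
    right = "right"
    bilateral = "bilateral"


class Demographics(BaseModel):
    """Cover-sheet data collected alongside the item answers."""

    respondent_id: str
    age: float = Field(ge=0)
    sex: Sex
    affected_side: AffectedSide
    hand_dominance: SideLR
    employment: str = ""
    pain_medication: str = ""
    assessed_side: SideLR
    completion_date: Optional[_dt.date] = None
    diagnosis: Optional[str] = None


class MSQResponse(BaseModel):
    """One respondent's demographics plus item answers.

    The strength item may be given either directly as points or as the raw
    lifted weight in kilograms (``lifted_weight_kg``), which scoring converts.
    """

    demographics: Demographics
    answers: dict[int, int] = Field(default_factory=dict)
    lifted_weight_kg: Optional[float] = None

    @field_validator("lifted_weight_kg")
    @classmethod
    def _weight_grid(cls, v: Optional[float]) -> Optional[float]:
        if v is None:
            return v
        if not (0.0 <= v <= MAX_LIFT_KG):
            raise ValueError(f"lifted_weight_kg must lie in [0, {MAX_LIFT_KG}]")
        if abs(v / LIFT_STEP_KG - round(v / LIFT_STEP_KG)) > 1e-9:
            raise ValueError("lifted_weight_kg must be a multiple of 0.5 kg")
        return v


class ResponseValidation(BaseModel):
    """Outcome of checking a response against the instrument."""

    respondent_id: str
    complete: bool
    missing_items: list[int] = Field(default_factory=list)
    issues: list[str] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.complete and not self.issues


def load_instrument(
    document: Union[None, str, Path, Mapping] = None,
) -> InstrumentDefinition:
    """Load an instrument definition.

    With no argument the built-in MSQ item bank is returned.  ``document`` may
    be a path to a JSON file or an already-parsed mapping.

    Raises
    ------
    DefinitionError
        If an item entry is malformed (the message names the item).
    StructuralError
        If item counts or subscale cardinalities are wrong.
    """
    if document is None:
        with resources.files("msq.data").joinpath(_DEFAULT_DOCUMENT).open(
            "r", encoding="utf-8"
        ) as fh:
            doc = json.load(fh)
    elif isinstance(document, (str, Path)):
        with open(document, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = dict(document)

    if not isinstance(doc, dict) or "items" not in doc:
        raise DefinitionError("instrument document must contain an 'items' list")

    items = []
    for raw in doc["items"]:
        try:
            items.append(ItemDefinition(**raw))
        except pydantic.ValidationError as exc:
            ident = raw.get("item_id", "?") if isinstance(raw, dict) else "?"
            raise DefinitionError(f"item {ident}: {exc.errors()[0]['msg']}") from exc
    try:
        return InstrumentDefinition(
            version=doc.get("version", "unversioned"),
            items=tuple(items),
            raw_max=doc.get("raw_max", sum(i.max_points for i in items)),
        )
    except pydantic.ValidationError as exc:
        # pydantic wraps errors raised inside model validators
        cause = exc.errors()[0]["msg"]
        raise StructuralError(cause) from exc


def validate_response(
    response: MSQResponse, instrument: InstrumentDefinition
) -> ResponseValidation:
    """Annotate a response as complete/incomplete and list range issues.

    Out-of-range answers are reported as issues, never clamped.  The strength
    item counts as answered if either its points or ``lifted_weight_kg`` is
    present.  Incomplete questionnaires are flagged here; whether they are
    scored is a policy decision made in :mod:`msq.scoring`.

    Raises
    ------
    ResponseError
        If the response answers an item_id the instrument does not define.
    """
    known = {it.item_id for it in instrument.items}
    unknown = sorted(set(response.answers) - known)
    if unknown:
        raise ResponseError(f"unknown item_id(s) {unknown}")

    issues: list[str] = []
    missing: list[int] = []
    strength_id = instrument.strength_item.item_id
    for it in instrument.items:
        if it.item_id in response.answers:
            val = response.answers[it.item_id]
            if not it.allowed(val):
                issues.append(
                    f"item {it.item_id}: answer {val} outside "
                    f"[{it.min_points}, {it.max_points}]"
                )
        elif it.item_id == strength_id and response.lifted_weight_kg is not None:
            pass  # strength supplied as raw weight
        else:
            missing.append(it.item_id)

    return ResponseValidation(
        respondent_id=response.demographics.respondent_id,
        complete=not missing,
        missing_items=missing,
        issues=issues,
    )
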