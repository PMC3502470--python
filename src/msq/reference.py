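"""Reference engines for the three established shoulder scores.

* SPADI — Shoulder Pain and Disability Index: 5 pain and 8 disability items,
  each on a 0-10 numeric scale here.  Each subscale is its item mean times 10;
  the total is the mean of the two subscales.  Conventionally higher = worse
  ("standard" orientation); the "inverted" orientation reports ``100 - standard``
  so that higher = better, matching the MSQ and CMS.
* DASH — Disabilities of the Arm, Shoulder and Hand: 30 items scored 1-5; up
  to 3 may be missing.  Score = ((mean of answered - 1) / 4) * 100, higher =
  worse function (the scale runs inversely relative to the others).
* CMS — Constant-Murley Score: pain (0-15), activities of daily living
  (0-20), range of motion (0-40) and strength (0-25) components summing to
  0-100, higher = better.  The strength component is fed from the
  self-assessed bag lift: 1 point per pound lifted, capped at 25.

Item values are accepted as reals so that crosswalk-calculated pseudo
responses (subscale means mapped back onto item scales) score exactly.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import RangeError, ScoringError
from .scoring import round_half_up

KG_TO_LB = 2.2046

SpadiOrientation = Literal["standard", "inverted"]

SPADI_N_PAIN = 5
SPADI_N_DISABILITY = 8
DASH_N_ITEMS = 30
DASH_MAX_MISSING = 3


class SpadiResponse(BaseModel):
    """13 items (5 pain, 8 disability), each 0-10; ``None`` marks missing."""

    model_config = ConfigDict(frozen=True)

    pain: tuple[Optional[float], ...]
    disability: tuple[Optional[float], ...]

    @model_validator(mode="after")
    def _shape(self) -> "SpadiResponse":
        if len(self.pain) != SPADI_N_PAIN:
            raise ValueError(f"SPADI needs {SPADI_N_PAIN} pain items")
        if len(self.disability) != SPADI_N_DISABILITY:
            raise ValueError(f"SPADI needs {SPADI_N_DISABILITY} disability items")
        for v in (*self.pain, *self.disability):
            if v is not None and not (0.0 <= v <= 10.0):
                raise ValueError(f"SPADI item value {v} outside [0, 10]")
        return self


class DashResponse(BaseModel):
    """30 items, each 1-5; ``None`` marks missing (at most 3 tolerated)."""

    model_config = ConfigDict(frozen=True)

    items: tuple[Optional[float], ...]

    @model_validator(mode="after")
    def _shape(self) -> "DashResponse":
        if len(self.items) != DASH_N_ITEMS:
            raise ValueError(f"DASH needs {DASH_N_ITEMS} items")
        for v in self.items:
            if v is not None and not (1.0 <= v <= 5.0):
                raise ValueError(f"DASH item value {v} outside [1, 5]")
        return self


class CmsComponents(BaseModel):
    """Constant-Murley components on their native point ranges."""

    model_config = ConfigDict(frozen=True)

    pain: float = Field(ge=0, le=15)
    adl: float = Field(ge=0, le=20)
    rom: float = Field(ge=0, le=40)
    strength: float = Field(ge=0, le=25)


def score_spadi(
    response: SpadiResponse, orientation: SpadiOrientation = "standard"
) -> float:
    """SPADI total on 0-100.

    Each subscale is ``mean(items) * 10``; the total is the mean of the two
    subscales.  No prorating: any missing item is a scoring error.
    """
    if any(v is None for v in (*response.pain, *response.disability)):
        raise ScoringError("SPADI does not prorate: all 13 items are required")
    pain = sum(response.pain) / SPADI_N_PAIN * 10.0
    disability = sum(response.disability) / SPADI_N_DISABILITY * 10.0
    total = (pain + disability) / 2.0
    if orientation == "inverted":
        return 100.0 - total
    if orientation == "standard":
        return total
    raise ValueError(f"unknown orientation {orientation!r}")


def score_dash(response: DashResponse) -> float:
    """DASH score on 0-100, higher = worse: ``((mean - 1) / 4) * 100``.

    Up to 3 missing items are tolerated (the mean is over answered items);
    more is a scoring error.
    """
    answered = [v for v in response.items if v is not None]
    n_missing = DASH_N_ITEMS - len(answered)
    if n_missing > DASH_MAX_MISSING:
        raise ScoringError(
            f"{n_missing} DASH items missing; at most {DASH_MAX_MISSING} allowed"
        )
    mean = sum(answered) / len(answered)
    return (mean - 1.0) / 4.0 * 100.0


def score_cms(components: CmsComponents) -> float:
    """Constant-Murley total: plain sum of the four components (0-100)."""
    return components.pain + components.adl + components.rom + components.strength


def invert_scale(score: float) -> float:
    """Flip a 0-100 score's orientation: ``100 - score``."""
    if not (0.0 <= score <= 100.0):
        raise RangeError(f"score {score} outside [0, 100]")
    return 100.0 - score


def strength_kg_to_cms_points(weight_kg: float) -> int:
    """Map a lifted weight to the CMS strength component.

    One point per pound (1 kg = 2.2046 lb), rounded half up, capped at 25;
    the 12 kg bag-lift maximum therefore saturates the component.
    """
    if weight_kg < 0:
        raise RangeError(f"weight {weight_kg} kg is negative")
    if weight_kg > 12.0:
        raise RangeError(f"weight {weight_kg} kg exceeds the 12 kg protocol maximum")
    return min(round_half_up(weight_kg * KG_TO_LB), 25)
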