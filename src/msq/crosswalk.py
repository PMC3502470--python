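"""Derive SPADI, DASH and Constant-Murley scores from a single MSQ response.

The mapping is declarative: each :class:`CrosswalkEntry` names the MSQ items
feeding one component of a target instrument and the transform that places
their subtotal on the component's range.  Because the original item-to-item
correspondence is not published in machine-readable form, the shipped default
(``crosswalk-1.0``) is a documented reconstruction from the instrument's
structure:

* MSQ ROM items -> CMS range-of-motion component (linear rescale 0-50 -> 0-40);
* the bag lift -> CMS strength via the pound-per-point rule;
* pain subscale -> CMS pain, SPADI pain subscale, DASH symptom block;
* work/daily + sport subscales -> CMS ADL, SPADI disability, DASH function
  block;
* quality-of-life subscale -> DASH social/emotional block.

Orientation flips (MSQ higher = better vs. SPADI/DASH higher = worse) are
explicit ``invert_then_rescale`` transforms, never sign conventions hidden in
weights.  Component values are fed to the engines in :mod:`msq.reference`, so
a calculated score obeys exactly the same formula as a directly administered
one.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Union

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .errors import CrosswalkError, DefinitionError, ScoringError
from .instrument import InstrumentDefinition, MSQResponse, validate_response
from .reference import (
    CmsComponents,
    DashResponse,
    SpadiResponse,
    score_cms,
    score_dash,
    score_spadi,
    strength_kg_to_cms_points,
)
from .scoring import WeightPolicy, effective_answers, points_to_weight

_DEFAULT_DOCUMENT = "msq_crosswalk_v1.json"

Transform = Literal["linear_rescale", "invert_then_rescale", "weight_to_cms_points"]
TargetInstrument = Literal["spadi", "dash", "cms"]

#: Components each target instrument requires for a complete crosswalk.
REQUIRED_COMPONENTS: dict[str, set[str]] = {
    "spadi": {"pain", "disability"},
    "cms": {"pain", "adl", "rom", "strength"},
}

#: Component ranges the reference engines accept.
_ENGINE_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("cms", "pain"): (0, 15),
    ("cms", "adl"): (0, 20),
    ("cms", "rom"): (0, 40),
    ("cms", "strength"): (0, 25),
}


class CrosswalkEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    target_instrument: TargetInstrument
    target_component: str
    source_item_ids: tuple[int, ...] = Field(min_length=1)
    transform: Transform
    target_range: tuple[float, float]
    #: number of target-instrument items this component stands for (used to
    #: weight DASH blocks in the 30-item mean; 1 elsewhere).
    target_items: int = 1


class Crosswalk(BaseModel):
    model_config = ConfigDict(frozen=True)

    version: str
    entries: tuple[CrosswalkEntry, ...]

    def for_instrument(self, name: str) -> tuple[CrosswalkEntry, ...]:
        return tuple(e for e in self.entries if e.target_instrument == name)


class DerivedScores(BaseModel):
    """Calculated (c-) scores for one respondent, all on 0-100."""

    respondent_id: str
    cspadi_standard: float
    cspadi_inverted: float
    cdash: float
    cdash_inverted: float
    ccms: float
    crosswalk_version: str


def load_crosswalk(
    document: Union[None, str, Path, Mapping] = None,
) -> Crosswalk:
    """Load a crosswalk definition (the shipped default when ``document`` is
    None; otherwise a JSON path or parsed mapping)."""
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
    try:
        return Crosswalk(
            version=doc.get("version", "unversioned"),
            entries=tuple(CrosswalkEntry(**e) for e in doc.get("entries", [])),
        )
    except pydantic.ValidationError as exc:
        raise DefinitionError(f"malformed crosswalk: {exc.errors()[0]['msg']}") from exc


def validate_crosswalk(
    crosswalk: Crosswalk, instrument: InstrumentDefinition
) -> list[str]:
    """Diagnostic check: returns a list of issues (empty when consistent).

    Reports dangling item references, uncovered required components, CMS
    component ranges that disagree with the engine, and DASH blocks whose
    ``target_items`` do not sum to the 30-item form.
    """
    issues: list[str] = []
    known = {it.item_id for it in instrument.items}
    for e in crosswalk.entries:
        dangling = sorted(set(e.source_item_ids) - known)
        if dangling:
            issues.append(
                f"{e.target_instrument}/{e.target_component}: "
                f"references unknown item(s) {dangling}"
            )
        lo, hi = e.target_range
        if hi <= lo:
            issues.append(
                f"{e.target_instrument}/{e.target_component}: empty range {e.target_range}"
            )
        engine_range = _ENGINE_RANGES.get((e.target_instrument, e.target_component))
        if engine_range is not None and tuple(e.target_range) != engine_range:
            issues.append(
                f"{e.target_instrument}/{e.target_component}: range "
                f"{tuple(e.target_range)} != engine range {engine_range}"
            )
    for inst, required in REQUIRED_COMPONENTS.items():
        mapped = {e.target_component for e in crosswalk.for_instrument(inst)}
        for comp in sorted(required - mapped):
            issues.append(f"{inst}: component '{comp}' not covered")
    dash_items = sum(e.target_items for e in crosswalk.for_instrument("dash"))
    if crosswalk.for_instrument("dash") and dash_items != 30:
        issues.append(f"dash: target_items sum to {dash_items}, expected 30")
    elif not crosswalk.for_instrument("dash"):
        issues.append("dash: no components mapped")
    return issues


def _component_value(
    entry: CrosswalkEntry,
    answers: Mapping[int, int],
    response: MSQResponse,
    instrument: InstrumentDefinition,
    weight_policy: WeightPolicy,
) -> float:
    lo, hi = entry.target_range
    if entry.transform == "weight_to_cms_points":
        kg = response.lifted_weight_kg
        if kg is None:
            sid = entry.source_item_ids[0]
            kg = points_to_weight(answers[sid], weight_policy)
        return float(min(max(strength_kg_to_cms_points(kg), lo), hi))
    subtotal = sum(answers[i] for i in entry.source_item_ids)
    src_max = sum(instrument.item(i).max_points for i in entry.source_item_ids)
    t = subtotal / src_max
    if entry.transform == "linear_rescale":
        return lo + t * (hi - lo)
    if entry.transform == "invert_then_rescale":
        return hi - t * (hi - lo)
    raise CrosswalkError(f"unknown transform {entry.transform!r}")


def derive_scores(
    response: MSQResponse,
    instrument: InstrumentDefinition | None = None,
    crosswalk: Crosswalk | None = None,
    weight_policy: WeightPolicy = "per_kg",
) -> DerivedScores:
    """Compute cSPADI, cDASH and cCMS from one complete MSQ response.

    Each target component is the transform of its source-item subtotal placed
    on the component range; components are then scored by the matching
    reference engine.  SPADI is reported in both orientations and DASH both
    natively (higher = worse) and inverted.
    """
    instrument = instrument or _default_instrument()
    crosswalk = crosswalk or _default_crosswalk()

    issues = validate_crosswalk(crosswalk, instrument)
    if issues:
        raise CrosswalkError("; ".join(issues))
    check = validate_response(response, instrument)
    if not check.ok:
        raise ScoringError(
            f"{check.respondent_id}: crosswalk requires a complete valid response "
            f"(missing {check.missing_items}, issues {check.issues})"
        )

    answers = effective_answers(response, instrument, weight_policy)
    values: dict[tuple[str, str], tuple[float, int]] = {}
    for e in crosswalk.entries:
        values[(e.target_instrument, e.target_component)] = (
            _component_value(e, answers, response, instrument, weight_policy),
            e.target_items,
        )

    # CMS: component values feed the sum engine directly.
    cms = CmsComponents(
        pain=values[("cms", "pain")][0],
        adl=values[("cms", "adl")][0],
        rom=values[("cms", "rom")][0],
        strength=values[("cms", "strength")][0],
    )
    ccms = score_cms(cms)

    # SPADI: subscale values (0-100, higher = worse) are spread uniformly over
    # the subscale's items so the engine's mean reproduces them exactly.
    pain_sub = values[("spadi", "pain")][0]
    dis_sub = values[("spadi", "disability")][0]
    spadi = SpadiResponse(
        pain=(pain_sub / 10.0,) * 5, disability=(dis_sub / 10.0,) * 8
    )
    cspadi_standard = score_spadi(spadi, "standard")
    cspadi_inverted = score_spadi(spadi, "inverted")

    # DASH: each block value (1-5) is repeated for the items it stands for.
    dash_items: list[float] = []
    for e in crosswalk.for_instrument("dash"):
        val, n = values[(e.target_instrument, e.target_component)]
        dash_items.extend([val] * n)
    cdash = score_dash(DashResponse(items=tuple(dash_items)))

    return DerivedScores(
        respondent_id=response.demographics.respondent_id,
        cspadi_standard=cspadi_standard,
        cspadi_inverted=cspadi_inverted,
        cdash=cdash,
        cdash_inverted=100.0 - cdash,
        ccms=ccms,
        crosswalk_version=crosswalk.version,
    )


def _default_instrument() -> InstrumentDefinition:
    from .instrument import load_instrument

    return load_instrument()


def _default_crosswalk() -> Crosswalk:
    return load_crosswalk()
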