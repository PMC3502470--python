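"""Synthetic shoulder-clinic cohorts with paired questionnaire responses.

The validation design needs the same patients answering four instruments at
once, with controllable agreement between them.  Independent per-item
sampling cannot produce that, so each simulated patient carries a single
latent function level ``theta`` in [0, 1] (0 = worst, 1 = best shoulder
function).  For every instrument the patient answers, a perturbed copy
``theta_i = clip(theta + cross_instrument_noise, 0, 1)`` drives all of that
instrument's items, each further jittered by item-level noise, oriented per
instrument (SPADI/DASH items run higher = worse) and clamped and rounded to
the item's response grid.

Each item additionally carries a fixed difficulty offset (a deterministic
ladder spread over one response step within its averaging group), the graded-
response-model feature that keeps a patient from answering every item of a
subscale identically and lets item means vary smoothly with the trait.

Defaults emulate a mixed surgical shoulder-clinic population of 51 patients:
``theta ~ Beta(4, 3)`` reproduces the observed MSQ percent distribution
(mean ~58, sd ~17.5), and item noise 0.08 of the item range with
cross-instrument noise 0.04 on the latent scale places concurrent validity
between paired instruments at r ~ 0.91-0.94, the agreement level reported
for the clinic cohort.  All randomness flows from one seeded generator, so a
cohort is fully reproducible from its seed.

:func:`make_fixture_cohort` additionally pins the demographic and diagnosis
margins (sex 36/15, handedness 41/10, 34 dominant-side affected, the
14-diagnosis case mix) to the published clinic counts, as an exact fixture.
"""

from __future__ import annotations

import datetime as _dt
from typing import Literal, Optional, Sequence

import numpy as np
import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError
from .instrument import (
    AffectedSide,
    Demographics,
    InstrumentDefinition,
    MSQResponse,
    Sex,
    SideLR,
    Subscale,
    load_instrument,
)
from .reference import CmsComponents, DashResponse, SpadiResponse, strength_kg_to_cms_points
from .scoring import weight_to_points

#: Published case mix of the 51-patient clinic cohort (diagnosis, count).
FIXTURE_DIAGNOSES: tuple[tuple[str, int], ...] = (
    ("Dislocation of the AC-joint", 4),
    ("Osteoarthritis of the shoulder", 4),
    ("Dislocation of the shoulder", 4),
    ("Shoulder pain of unknown origin", 2),
    ("Rotator cuff tear", 3),
    ("Impingement", 14),
    ("Humeral bone cyst", 1),
    ("Contusion of the shoulder", 1),
    ("Fracture of the clavicle", 1),
    ("Fracture of the scapula", 1),
    ("Fracture of the humerus", 13),
    ("Damage of the brachial plexus", 1),
    ("Biceps tendon tear", 1),
    ("Shoulder arthroplasty", 1),
)

FIXTURE_N = 51
FIXTURE_N_MALE = 36
FIXTURE_N_RIGHT_HANDED = 41
FIXTURE_N_DOMINANT_AFFECTED = 34
#: age-band counts: 20-39, 40-59, 60-80 years
FIXTURE_AGE_BANDS: tuple[tuple[int, int, int], ...] = (
    (20, 39, 12),
    (40, 59, 26),
    (60, 80, 13),
)
FIXTURE_EMPLOYMENT: tuple[tuple[str, int], ...] = (
    ("paid work", 33),
    ("housework", 3),
    ("retired", 14),
    ("unemployed", 1),
)


class LatentDistribution(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["beta", "truncnorm"] = "beta"
    a: float = Field(default=4.0, gt=0)
    b: float = Field(default=3.0, gt=0)
    mu: float = Field(default=0.5, ge=0, le=1)
    sigma: float = Field(default=0.25, gt=0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=n)
        # truncated normal on [0, 1] by rejection (cheap at these scales)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mu, self.sigma, size=2 * (n - filled) + 8)
            keep = draw[(draw >= 0.0) & (draw <= 1.0)][: n - filled]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out


class SimConfig(BaseModel):
    """Cohort simulator configuration (defaults are the study conditions)."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=51, ge=2)
    latent: LatentDistribution = LatentDistribution()
    item_noise_sd: float = Field(default=0.08, ge=0)
    cross_instrument_noise_sd: float = Field(default=0.04, ge=0)
    missing_rate: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0


class SimulatedPatient(BaseModel):
    """One patient's latent function and their four paired responses."""

    latent_function: float = Field(ge=0, le=1)
    msq_response: MSQResponse
    spadi_response: SpadiResponse
    dash_response: DashResponse
    cms_components: CmsComponents


def _grid(x: float, lo: float, hi: float, step: float = 1.0) -> float:
    """Clamp to [lo, hi] and round onto the response grid."""
    snapped = round(x / step) * step
    return float(min(max(snapped, lo), hi))


def _difficulty(pos: int, m: int) -> float:
    """Fixed item-difficulty offset, in units of one response step.

    Items within an averaging group get offsets spread uniformly over one
    quantization step, centred on zero.  This is the deterministic analogue of
    item difficulties in a graded-response model: patients do not answer every
    item of a subscale identically, and the group mean becomes an almost
    linear function of the latent trait instead of a coarse staircase.
    """
    return (pos + 0.5) / m - 0.5


def _sample_demographics(rng: np.random.Generator, idx: int) -> Demographics:
    sex = Sex.male if rng.random() < FIXTURE_N_MALE / FIXTURE_N else Sex.female
    dominance = (
        SideLR.right
        if rng.random() < FIXTURE_N_RIGHT_HANDED / FIXTURE_N
        else SideLR.left
    )
    if rng.random() < FIXTURE_N_DOMINANT_AFFECTED / FIXTURE_N:
        affected = AffectedSide(dominance.value)
    else:
        affected = AffectedSide("left" if dominance is SideLR.right else "right")
    age = float(np.clip(np.round(rng.normal(51.0, 15.0)), 20, 80))
    diagnoses, counts = zip(*FIXTURE_DIAGNOSES)
    diagnosis = str(rng.choice(diagnoses, p=np.asarray(counts) / FIXTURE_N))
    jobs, jcounts = zip(*FIXTURE_EMPLOYMENT)
    employment = str(rng.choice(jobs, p=np.asarray(jcounts) / FIXTURE_N))
    return Demographics(
        respondent_id=f"sim-{idx + 1:03d}",
        age=age,
        sex=sex,
        affected_side=affected,
        hand_dominance=dominance,
        employment=employment,
        pain_medication="no",
        assessed_side=SideLR(affected.value),
        completion_date=_dt.date(2009, 8, 1),
        diagnosis=diagnosis,
    )


def _simulate_patient(
    theta: float,
    rng: np.random.Generator,
    config: SimConfig,
    instrument: InstrumentDefinition,
    demographics: Demographics,
) -> SimulatedPatient:
    cross = config.cross_instrument_noise_sd
    noise = config.item_noise_sd

    def inst_theta() -> float:
        return float(np.clip(theta + cross * rng.normal(), 0.0, 1.0))

    # --- MSQ ---------------------------------------------------------------
    th = inst_theta()
    answers: dict[int, int] = {}
    lifted: Optional[float] = None
    sub_pos: dict[Subscale, int] = {}
    for it in instrument.items:
        if it.subscale is Subscale.strength:
            kg = _grid(th * 12.0 + noise * 12.0 * rng.normal(), 0.0, 12.0, 0.5)
            lifted = kg
            answers[it.item_id] = weight_to_points(kg)
        else:
            pos = sub_pos.get(it.subscale, 0)
            sub_pos[it.subscale] = pos + 1
            m = len(instrument.items_in(it.subscale))
            answers[it.item_id] = int(
                _grid(
                    th * it.max_points
                    + _difficulty(pos, m)
                    + noise * it.max_points * rng.normal(),
                    it.min_points,
                    it.max_points,
                )
            )
    if config.missing_rate > 0:
        drop = rng.random(30) < config.missing_rate
        for pos, it in enumerate(instrument.items):
            if drop[pos]:
                answers.pop(it.item_id, None)
                if it.subscale is Subscale.strength:
                    lifted = None
    msq = MSQResponse(demographics=demographics, answers=answers, lifted_weight_kg=lifted)

    # --- SPADI (items higher = worse) --------------------------------------
    th = inst_theta()
    spadi = SpadiResponse(
        pain=tuple(
            _grid(
                (1.0 - th) * 10.0 + _difficulty(j, 5) + noise * 10.0 * rng.normal(),
                0.0, 10.0,
            )
            for j in range(5)
        ),
        disability=tuple(
            _grid(
                (1.0 - th) * 10.0 + _difficulty(j, 8) + noise * 10.0 * rng.normal(),
                0.0, 10.0,
            )
            for j in range(8)
        ),
    )

    # --- DASH (items 1-5, higher = worse) ----------------------------------
    th = inst_theta()
    dash = DashResponse(
        items=tuple(
            _grid(
                1.0 + (1.0 - th) * 4.0 + _difficulty(j, 30) + noise * 4.0 * rng.normal(),
                1.0, 5.0,
            )
            for j in range(30)
        )
    )

    # --- CMS ----------------------------------------------------------------
    th = inst_theta()
    kg = _grid(th * 12.0 + noise * 12.0 * rng.normal(), 0.0, 12.0, 0.5)
    cms = CmsComponents(
        pain=_grid(th * 15.0 + noise * 15.0 * rng.normal(), 0.0, 15.0),
        adl=_grid(th * 20.0 + noise * 20.0 * rng.normal(), 0.0, 20.0),
        rom=_grid(th * 40.0 + noise * 40.0 * rng.normal(), 0.0, 40.0),
        strength=float(strength_kg_to_cms_points(kg)),
    )

    return SimulatedPatient(
        latent_function=float(theta),
        msq_response=msq,
        spadi_response=spadi,
        dash_response=dash,
        cms_components=cms,
    )


def simulate_cohort(
    config: SimConfig | dict | None = None,
    instrument: InstrumentDefinition | None = None,
) -> list[SimulatedPatient]:
    """Draw a cohort of paired responses; reproducible from ``config.seed``."""
    if config is None:
        config = SimConfig()
    elif isinstance(config, dict):
        try:
            config = SimConfig(**config)
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from exc
    instrument = instrument or load_instrument()
    rng = np.random.default_rng(config.seed)
    thetas = config.latent.sample(config.n_patients, rng)
    return [
        _simulate_patient(
            float(th), rng, config, instrument, _sample_demographics(rng, i)
        )
        for i, th in enumerate(thetas)
    ]


def make_fixture_cohort(
    seed: int = 7,
    config: SimConfig | None = None,
    out_dir=None,
) -> list[SimulatedPatient]:
    """A 51-patient cohort whose demographic margins match the clinic cohort
    exactly (sex 36/15, handedness 41/10, 34 dominant-side affected, age bands
    12/26/13 over 20-80 years, employment 33/3/14/1, the 14-diagnosis mix).

    Responses are simulated under ``config`` (default study conditions); only
    the demographics are replaced by the exact-count assignment.  When
    ``out_dir`` is given, one CSV per instrument plus a manifest are written
    there (see :func:`msq.io.write_cohort`).
    """
    base = config or SimConfig(seed=seed)
    if base.n_patients != FIXTURE_N:
        raise ConfigError(f"fixture cohort is defined for n={FIXTURE_N}")
    patients = simulate_cohort(base.model_copy(update={"seed": seed}))

    rng = np.random.default_rng(seed + 1)
    sexes = [Sex.male] * FIXTURE_N_MALE + [Sex.female] * (FIXTURE_N - FIXTURE_N_MALE)
    dominance = [SideLR.right] * FIXTURE_N_RIGHT_HANDED + [SideLR.left] * (
        FIXTURE_N - FIXTURE_N_RIGHT_HANDED
    )
    ages: list[int] = []
    for lo, hi, count in FIXTURE_AGE_BANDS:
        ages.extend(int(a) for a in rng.integers(lo, hi + 1, size=count))
    ages[0], ages[-1] = 20, 80  # pin the published range
    employment = [job for job, c in FIXTURE_EMPLOYMENT for _ in range(c)]
    diagnoses = [d for d, c in FIXTURE_DIAGNOSES for _ in range(c)]
    for lst in (sexes, dominance, ages, employment, diagnoses):
        rng.shuffle(lst)
    dominant_affected = np.zeros(FIXTURE_N, dtype=bool)
    dominant_affected[
        rng.choice(FIXTURE_N, size=FIXTURE_N_DOMINANT_AFFECTED, replace=False)
    ] = True

    out: list[SimulatedPatient] = []
    for i, p in enumerate(patients):
        dom = dominance[i]
        if dominant_affected[i]:
            affected = AffectedSide(dom.value)
        else:
            affected = AffectedSide("left" if dom is SideLR.right else "right")
        demo = Demographics(
            respondent_id=f"pat-{i + 1:03d}",
            age=float(ages[i]),
            sex=sexes[i],
            affected_side=affected,
            hand_dominance=dom,
            employment=employment[i],
            pain_medication="no",
            assessed_side=SideLR(affected.value),
            completion_date=_dt.date(2009, 8, 1),
            diagnosis=diagnoses[i],
        )
        out.append(
            p.model_copy(
                update={
                    "msq_response": p.msq_response.model_copy(
                        update={"demographics": demo}
                    )
                }
            )
        )

    if out_dir is not None:
        from .io import write_cohort

        write_cohort(out, out_dir)
    return out


def cohort_score_frames(
    patients: Sequence[SimulatedPatient],
    instrument: InstrumentDefinition | None = None,
    crosswalk=None,
):
    """Original and MSQ-calculated score frames for a simulated cohort.

    Returns ``(original, calculated)`` pandas frames indexed by respondent id.
    Original columns carry each instrument's study orientation: ``spadi``
    (higher = better), ``dash`` (native, higher = worse), ``cms``.  All
    calculated columns, including ``dash``, inherit the MSQ's higher = better
    orientation (plus ``msq_percent``), so the DASH pair correlates
    negatively, as its inverse scale dictates.
    """
    import pandas as pd

    from .crosswalk import derive_scores, load_crosswalk
    from .reference import score_cms, score_dash, score_spadi
    from .scoring import section_subtotals

    instrument = instrument or load_instrument()
    crosswalk = crosswalk or load_crosswalk()

    orig_rows, calc_rows = [], []
    for p in patients:
        rid = p.msq_response.demographics.respondent_id
        orig_rows.append(
            {
                "respondent_id": rid,
                "spadi": score_spadi(p.spadi_response, "inverted"),
                "dash": score_dash(p.dash_response),
                "cms": score_cms(p.cms_components),
            }
        )
        report = section_subtotals(p.msq_response, instrument)
        d = derive_scores(p.msq_response, instrument, crosswalk)
        calc_rows.append(
            {
                "respondent_id": rid,
                "msq_percent": report.percent,
                "spadi": d.cspadi_inverted,
                "dash": d.cdash_inverted,
                "cms": d.ccms,
            }
        )
    original = pd.DataFrame(orig_rows).set_index("respondent_id")
    calculated = pd.DataFrame(calc_rows).set_index("respondent_id")
    return original, calculated
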