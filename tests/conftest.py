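import numpy as np
import pytest

from msq.instrument import Demographics, MSQResponse, load_instrument
from msq.crosswalk import load_crosswalk


@pytest.fixture(scope="session")
def instrument():
    return load_instrument()


@pytest.fixture(scope="session")
def crosswalk():
    return load_crosswalk()


@pytest.fixture(scope="session")
def fixture_patients():
    from msq.simulate import make_fixture_cohort

    return make_fixture_cohort(seed=7)


def make_demographics(rid: str = "t-001") -> Demographics:
    return Demographics(
        respondent_id=rid,
        age=51,
        sex="male",
        affected_side="right",
        hand_dominance="right",
        employment="paid work",
        pain_medication="no",
        assessed_side="right",
    )


def make_response(answers: dict[int, int], rid: str = "t-001", **kw) -> MSQResponse:
    return MSQResponse(demographics=make_demographics(rid), answers=answers, **kw)


def full_response(value_graded: int = 10, strength: int = 24, rid: str = "t-001") -> MSQResponse:
    answers = {i: value_graded for i in range(1, 31)}
    answers[6] = strength
    return make_response(answers, rid=rid)


def random_response(rng: np.random.Generator, instrument, rid: str = "t-rand") -> MSQResponse:
    answers = {
        it.item_id: int(rng.integers(it.min_points, it.max_points + 1))
        for it in instrument.items
    }
    return make_response(answers, rid=rid)
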