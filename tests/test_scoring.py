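"""Raw score, percent conversion, subtotals and scoring policies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msq.errors import RangeError, ScoringError
from msq.instrument import Subscale
from msq.scoring import (
    compute_raw_score,
    raw_to_percent,
    round_half_up,
    section_subtotals,
    subscale_weights,
    weight_to_points,
)

from .conftest import full_response, make_response, random_response


class TestWeightToPoints:
    @pytest.mark.parametrize(
        "kg, expected", [(12.0, 24), (0.0, 0), (6.0, 12), (0.5, 1), (11.5, 23)]
    )
    def test_default_two_points_per_kg(self, kg, expected):
        assert weight_to_points(kg) == expected

    def test_default_policy_full_grid(self):
        """Every 0.5 kg step: 2 pts/kg, never above the 24-point cap."""
        for step in range(25):
            kg = step * 0.5
            assert weight_to_points(kg) == min(round(2 * kg), 24)

    def test_literal_policy_saturates_at_6kg(self):
        for step in range(25):
            kg = step * 0.5
            assert weight_to_points(kg, "literal_500g") == min(2 * step, 24)
        assert weight_to_points(6.0, "literal_500g") == 24
        assert weight_to_points(12.0, "literal_500g") == 24

    @pytest.mark.parametrize("kg", [-0.5, 12.5])
    def test_out_of_range(self, kg):
        with pytest.raises(RangeError):
            weight_to_points(kg)


class TestRawScore:
    def test_all_max_gives_314(self, instrument):
        assert compute_raw_score(full_response(), instrument) == 314

    def test_all_zero_gives_0(self, instrument):
        assert compute_raw_score(full_response(0, 0), instrument) == 0

    def test_rom_only_gives_50(self, instrument):
        answers = {i: 0 for i in range(1, 31)}
        answers.update({i: 10 for i in range(1, 6)})
        assert compute_raw_score(make_response(answers), instrument) == 50

    def test_strength_from_weight(self, instrument):
        answers = {i: 0 for i in range(1, 31) if i != 6}
        resp = make_response(answers, lifted_weight_kg=9.0)
        assert compute_raw_score(resp, instrument) == 18

    def test_strict_policy_refuses_incomplete(self, instrument):
        answers = {i: 5 for i in range(1, 29)}  # items 29, 30 missing
        with pytest.raises(ScoringError, match=r"29.*30|\[29, 30\]"):
            compute_raw_score(make_response(answers), instrument)

    def test_prorate_policy_scales_and_flags(self, instrument):
        # pain subscale: 5 of 6 items answered at 8 -> prorated to 48
        answers = {i: 0 for i in range(1, 31)}
        answers.update({i: 8 for i in range(7, 12)})
        del answers[12]
        report = section_subtotals(
            make_response(answers), instrument, missing_policy="prorate"
        )
        assert report.prorated and not report.complete
        assert report.subscale_subtotals[Subscale.pain] == 48

    def test_invalid_answer_rejected_not_clamped(self, instrument):
        answers = {i: 5 for i in range(1, 31)}
        answers[3] = 12
        with pytest.raises(ScoringError, match="item 3"):
            compute_raw_score(make_response(answers), instrument)


class TestPercent:
    @pytest.mark.parametrize(
        "raw, display",
        [(182, 58), (88, 28), (314, 100), (0, 0), (310, 99)],
    )
    def test_display_rounding(self, raw, display):
        assert round_half_up(raw_to_percent(raw)) == display

    def test_exact_value(self):
        assert raw_to_percent(157) == pytest.approx(50.0)
        assert raw_to_percent(314) == 100.0

    @pytest.mark.parametrize("raw", [-1, 315])
    def test_out_of_range(self, raw):
        with pytest.raises(RangeError):
            raw_to_percent(raw)


class TestSubtotals:
    def test_all_max_sections(self, instrument):
        report = section_subtotals(full_response(), instrument)
        assert report.objective_subtotal == 74
        assert report.subjective_subtotal == 240
        assert report.raw == 314

    def test_all_zero(self, instrument):
        report = section_subtotals(full_response(0, 0), instrument)
        assert report.raw == 0
        assert all(v == 0 for v in report.subscale_subtotals.values())

    def test_pain_only(self, instrument):
        answers = {i: 0 for i in range(1, 31)}
        answers.update({i: 10 for i in range(7, 13)})
        report = section_subtotals(make_response(answers), instrument)
        assert report.subscale_subtotals[Subscale.pain] == 60
        assert report.raw == 60

    def test_sections_add_to_raw_on_random_responses(self, instrument):
        rng = np.random.default_rng(11)
        for _ in range(200):
            report = section_subtotals(random_response(rng, instrument), instrument)
            assert report.raw == report.objective_subtotal + report.subjective_subtotal
            assert report.raw == sum(report.subscale_subtotals.values())

    def test_oracle_equivalence_brute_force(self, instrument):
        """Raw score equals an independent sum over the item bank."""
        rng = np.random.default_rng(23)
        item_max = {it.item_id: it.max_points for it in instrument.items}
        for _ in range(1000):
            resp = random_response(rng, instrument)
            oracle = sum(resp.answers[i] for i in sorted(item_max))
            assert compute_raw_score(resp, instrument) == oracle


class TestSubscaleWeights:
    def test_printed_weights(self, instrument):
        weights = {s.value: w for s, w in subscale_weights(instrument).items()}
        assert weights == {
            "rom": 16,
            "strength": 8,
            "pain": 19,
            "work_daily": 29,
            "sport_recreation": 19,
            "quality_of_life": 10,
        }

    def test_weights_sum_within_rounding_slack(self, instrument):
        assert abs(sum(subscale_weights(instrument).values()) - 100) <= 1


class TestMonotonicity:
    @settings(max_examples=60, deadline=None)
    @given(
        data=st.data(),
        item_id=st.integers(min_value=1, max_value=30),
    )
    def test_increasing_one_answer_never_decreases_scores(
        self, data, item_id, instrument
    ):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        resp = random_response(rng, instrument)
        item = instrument.item(item_id)
        if resp.answers[item_id] >= item.max_points:
            return
        bumped_answers = dict(resp.answers)
        bumped_answers[item_id] += 1
        bumped = make_response(bumped_answers)
        before = section_subtotals(resp, instrument)
        after = section_subtotals(bumped, instrument)
        assert after.raw >= before.raw
        assert after.percent >= before.percent
        assert (
            after.subscale_subtotals[item.subscale]
            >= before.subscale_subtotals[item.subscale]
        )
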