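"""Pearson/regression/descriptives/box summaries and their oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msq.errors import AlignmentError, DegenerateFitError, StatsError
from msq.stats import (
    descriptives,
    ols_fit,
    pearson_r,
    summary_table,
    tukey_box_summary,
    validate_pairs,
)


def naive_pearson(x, y):
    """Two-pass textbook formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_exact_anticorrelation(self):
        x = np.arange(5.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_p_value_from_t_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = pearson_r(x, y)
        from scipy import stats as sps

        t = r * np.sqrt(28 / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 28), rel=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(StatsError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            pearson_r([1, 2, 3], [1, 2])

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            r, _ = pearson_r(x, y)
            assert r == pytest.approx(naive_pearson(x, y), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(min_value=-5, max_value=5, allow_nan=False),
        b=st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    def test_affine_invariance(self, seed, a, b):
        if abs(a) < 1e-3:
            return
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r(a * x + b, y)
        assert r1 == pytest.approx(np.sign(a) * r0, abs=1e-9)


class TestOls:
    def test_exact_line(self):
        x = np.arange(6.0)
        slope, intercept = ols_fit(x, 3 * x - 2)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(-2.0)

    def test_constant_response(self):
        slope, intercept = ols_fit([0, 1, 2], [4, 4, 4])
        assert slope == 0.0
        assert intercept == 4.0

    def test_normal_equations_by_hand(self):
        slope, intercept = ols_fit([0, 1, 2], [0, 0, 3])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-0.5)

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateFitError):
            ols_fit([2, 2, 2], [1, 2, 3])


class TestDescriptives:
    def test_degenerate_series(self):
        d = descriptives([2, 2, 2])
        assert (d.mean, d.sd, d.range) == (2.0, 0.0, 0.0)

    def test_closed_form_two_points(self):
        d = descriptives([0, 10])
        assert d.mean == 5.0
        assert d.sd == pytest.approx(np.sqrt(50.0))
        assert d.range == 10.0

    def test_range_is_max_minus_min(self):
        rng = np.random.default_rng(2)
        x = rng.integers(12, 98, size=51)
        d = descriptives(x)
        assert d.range == d.max - d.min
        # mirrors the printed summary convention, e.g. 97 - 12 = 85
        assert descriptives([97, 12]).range == 85

    def test_empty_error(self):
        with pytest.raises(StatsError):
            descriptives([])

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 20, size=200)
        d = descriptives(x)
        mean = sum(x) / len(x)
        sd = np.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
        assert d.mean == pytest.approx(mean, abs=1e-12)
        assert d.sd == pytest.approx(sd, abs=1e-12)


class TestTukeyBox:
    def test_one_to_nine(self):
        box = tukey_box_summary(range(1, 10))
        assert (box.median, box.q1, box.q3) == (5.0, 3.0, 7.0)
        assert box.outliers == ()
        assert (box.whisker_lo, box.whisker_hi) == (1.0, 9.0)

    def test_degenerate_box(self):
        box = tukey_box_summary([4] * 8)
        assert box.median == box.q1 == box.q3 == 4.0
        assert box.outliers == ()

    def test_extreme_point_flagged(self):
        box = tukey_box_summary(list(range(1, 10)) + [100])
        assert 100.0 in box.outliers
        assert box.whisker_hi < 100.0

    def test_too_few_points(self):
        with pytest.raises(StatsError):
            tukey_box_summary([1, 2, 3, 4])


class TestValidatePairs:
    def _frames(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n)]
        orig = pd.DataFrame(
            {
                "spadi": rng.uniform(0, 100, n),
                "dash": rng.uniform(0, 100, n),
                "cms": rng.uniform(0, 100, n),
            },
            index=idx,
        )
        return orig

    def test_identical_series_give_r_one(self):
        orig = self._frames()
        calc = orig.copy()
        results = {r.pair_label: r for r in validate_pairs(orig, calc)}
        assert results["spadi original vs calculated"].r == pytest.approx(1.0)
        assert results["cms original vs calculated"].r == pytest.approx(1.0)

    def test_dash_inverted_flips_sign_only(self):
        orig = self._frames(3)
        calc = orig.copy()
        calc["dash"] = 100 - orig["dash"] + np.random.default_rng(4).normal(0, 3, len(orig))
        calc["dash"] = calc["dash"].clip(0, 100)
        results = {r.pair_label: r for r in validate_pairs(orig, calc)}
        native = results["dash original vs calculated"].r
        inverted = results["dash (inverted) original vs calculated"].r
        assert native == pytest.approx(-inverted, abs=1e-12)
        assert native < 0 < inverted

    def test_id_mismatch_raises(self):
        orig = self._frames()
        calc = orig.copy()
        calc.index = [f"q{i}" for i in range(len(calc))]
        with pytest.raises(AlignmentError):
            validate_pairs(orig, calc)

    def test_summary_table_columns(self):
        orig = self._frames(7)
        results = validate_pairs(orig, orig.copy())
        table = summary_table(results)
        assert list(table.columns) == ["Mean", "SD", "Max", "Min", "Range"]
        assert "spadi original" in table.index
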