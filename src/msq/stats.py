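"""Concurrent-validity statistics for original-vs-calculated score pairs.

For each instrument pair (SPADI, DASH, CMS original vs. calculated from the
MSQ) this module reports Pearson's r with its two-sided p-value from the
t-transform on n-2 degrees of freedom, the least-squares regression line,
per-series descriptives (sample sd, n-1 denominator) and Tukey box-plot
summaries (quartiles by linear interpolation, whiskers at the most extreme
observations within 1.5 x IQR, points beyond flagged as outliers).

The DASH pair is reported in both orientations: on the native scale (higher =
worse) its correlation with the other instruments is negative, and inverting
the scale flips only the sign of r.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats as _sps

from .errors import AlignmentError, DegenerateFitError, StatsError


class Descriptives(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int
    mean: float
    sd: float
    min: float
    max: float
    range: float


class BoxSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


class ValidationResult(BaseModel):
    """One original-vs-calculated pair's full comparison."""

    model_config = ConfigDict(frozen=True)

    pair_label: str
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    descriptives: dict[str, Descriptives]
    boxplots: dict[str, BoxSummary]


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise StatsError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise StatsError(f"{name} contains missing values")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value.

    The p-value comes from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees
    of freedom (equivalent to the simple-regression slope test).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise StatsError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise StatsError("pearson_r needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise StatsError("correlation undefined for a zero-variance series")
    res = _sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise StatsError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise StatsError("ols_fit needs n >= 2")
    if np.ptp(xa) == 0:
        raise DegenerateFitError("x is constant; slope undefined")
    if np.ptp(ya) == 0:
        return 0.0, float(ya[0])  # scipy.linregress leaves r undefined here
    res = _sps.linregress(xa, ya)
    return float(res.slope), float(res.intercept)


def descriptives(series: Sequence[float]) -> Descriptives:
    """Mean, sample sd (n-1), min, max and range of a series."""
    arr = _as_array(series, "series")
    if arr.size == 0:
        raise StatsError("descriptives of an empty series")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return Descriptives(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        range=float(arr.max() - arr.min()),
    )


def tukey_box_summary(series: Sequence[float]) -> BoxSummary:
    """Five-number box summary with 1.5 x IQR whiskers and outliers."""
    arr = _as_array(series, "series")
    if arr.size < 5:
        raise StatsError("tukey_box_summary needs n >= 5")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = np.sort(arr[(arr < lo_fence) | (arr > hi_fence)])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


def _compare(label: str, orig: np.ndarray, calc: np.ndarray) -> ValidationResult:
    r, p = pearson_r(orig, calc)
    slope, intercept = ols_fit(orig, calc)
    return ValidationResult(
        pair_label=label,
        r=r,
        p_value=p,
        slope=slope,
        intercept=intercept,
        n=int(orig.size),
        descriptives={
            "original": descriptives(orig),
            "calculated": descriptives(calc),
        },
        boxplots={
            "original": tukey_box_summary(orig),
            "calculated": tukey_box_summary(calc),
        },
    )


def validate_pairs(
    original: pd.DataFrame, calculated: pd.DataFrame
) -> list[ValidationResult]:
    """Compare original and calculated scores instrument by instrument.

    Both frames are indexed by respondent id with one column per instrument
    (``spadi``, ``dash``, ``cms``, ...).  The DASH pair is additionally
    reported on the inverted scale (where its r flips sign).

    Raises
    ------
    AlignmentError
        If the two frames do not cover the same respondents.
    """
    if set(original.index) != set(calculated.index):
        missing = set(original.index) ^ set(calculated.index)
        raise AlignmentError(f"respondent ids differ between frames: {sorted(missing)!r}")
    calculated = calculated.loc[original.index]

    results: list[ValidationResult] = []
    for col in original.columns:
        if col not in calculated.columns:
            continue
        orig = _as_array(original[col], f"original.{col}")
        calc = _as_array(calculated[col], f"calculated.{col}")
        results.append(_compare(f"{col} original vs calculated", orig, calc))
        if col == "dash":
            # The calculated DASH column carries the MSQ's higher = better
            # orientation while the original runs inversely, so the native
            # pair correlates negatively; inverting the original flips the
            # sign of r and nothing else.
            results.append(
                _compare("dash (inverted) original vs calculated",
                         100.0 - orig, calc)
            )
    return results


def summary_table(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """Descriptives of every series, one row per score (Mean/SD/Max/Min/Range)."""
    rows = []
    for res in results:
        for which, d in res.descriptives.items():
            rows.append(
                {
                    "score": res.pair_label.replace(" original vs calculated", "")
                    + f" {which}",
                    "Mean": d.mean,
                    "SD": d.sd,
                    "Max": d.max,
                    "Min": d.min,
                    "Range": d.range,
                }
            )
    return pd.DataFrame(rows).set_index("score")


def correlation_table(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """r, p, regression line and n for every pair."""
    return pd.DataFrame(
        [
            {
                "pair": res.pair_label,
                "r": res.r,
                "p_value": res.p_value,
                "slope": res.slope,
                "intercept": res.intercept,
                "n": res.n,
            }
            for res in results
        ]
    ).set_index("pair")
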