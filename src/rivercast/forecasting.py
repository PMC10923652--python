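"""Lagged regressions of fishery CPUE on dam counts and the in-season
convergence forecast.

The workhorse is ordinary least squares with an intercept: weekly CPUE x at
the test fishery is paired with the dam count y observed ``lag`` weeks later.
In-season, the regression is refit as each weekly data point arrives; once
the slope has converged (relative tolerance against the final-season slope),
the current fit predicts up to three future weekly dam counts from the next
CPUE readings, and the cumulative prediction is scored by absolute
percentage error (APE) against the observed cumulative count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ForecastRow, ValidationError

__all__ = [
    "RegressionResult",
    "lagged_regression",
    "regression_suite",
    "incremental_slopes",
    "detect_convergence",
    "forecast_weeks",
    "ape",
    "mape",
    "in_season_table",
]


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit: dam counts per unit CPUE."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


SeriesLike = Union[pd.Series, Mapping[int, float]]


def _as_series(series: SeriesLike) -> pd.Series:
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) \
        else series.astype(float)
    return s.sort_index()


def _aligned_pairs(
    cpue: SeriesLike, dam: SeriesLike, lag_weeks: int
) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Pair CPUE at week w with the dam count at week w + lag; weeks with a
    missing value on either side are dropped, not imputed."""
    c = _as_series(cpue).dropna()
    d = _as_series(dam).dropna()
    weeks = [int(w) for w in c.index if w + lag_weeks in d.index]
    x = c.loc[weeks].to_numpy()
    y = d.loc[[w + lag_weeks for w in weeks]].to_numpy()
    return x, y, weeks


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 2:
        raise ValidationError(
            f"need >= 2 paired weeks for a regression, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in CPUE; slope undefined")
    if np.ptp(y) == 0:
        # constant response: flat line fits exactly but explains nothing
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                n=len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r2=float(fit.rvalue) ** 2, n=len(x))


def lagged_regression(
    cpue: SeriesLike, dam: SeriesLike, lag_weeks: int
) -> RegressionResult:
    """OLS of dam counts at week w+lag on CPUE at week w, with intercept."""
    x, y, _ = _aligned_pairs(cpue, dam, lag_weeks)
    return _ols(x, y)


def regression_suite(
    cpue_by_key: Mapping, target_series: Union[SeriesLike, Mapping],
    lag_weeks: int,
) -> pd.DataFrame:
    """One lagged regression per stock unit.

    ``cpue_by_key`` maps a key (e.g. ``(year, clip)`` or
    ``(year, clip, genstock)``) to a weekly CPUE series.  ``target_series``
    is either a single weekly count series shared by all keys, or a mapping
    from the same keys to per-unit series (dam counts per GenStock,
    Willamette Falls counts for the lower stock, ...).  Keys whose pairing
    leaves fewer than two weeks are reported with NaN fit fields.
    """
    # a mapping of series means per-unit targets; a Series (or a flat
    # week -> value mapping) is shared by all keys
    per_key = (
        isinstance(target_series, Mapping)
        and not isinstance(target_series, pd.Series)
        and bool(target_series)
        and all(isinstance(v, (pd.Series, Mapping))
                for v in target_series.values())
    )
    rows = []
    for key, series in cpue_by_key.items():
        if per_key:
            if key not in target_series:
                raise ValidationError(f"no target series for {key!r}")
            target = target_series[key]
        else:
            target = target_series
        key_tuple = key if isinstance(key, tuple) else (key,)
        try:
            res = lagged_regression(series, target, lag_weeks)
            rows.append(key_tuple + (res.slope, res.intercept, res.r2, res.n))
        except ValidationError:
            rows.append(key_tuple + (np.nan, np.nan, np.nan, 0))
    width = max(len(r) for r in rows) - 4 if rows else 1
    key_cols = [f"key_{i}" for i in range(width)]
    return pd.DataFrame(rows, columns=key_cols + ["slope", "intercept",
                                                  "r2", "n"])


def incremental_slopes(
    cpue: SeriesLike, dam: SeriesLike, lag_weeks: int, start_n: int = 3
) -> List[RegressionResult]:
    """Refit the regression on nested prefixes of the paired weekly data:
    first ``start_n`` pairs, then one more pair per step."""
    x, y, _ = _aligned_pairs(cpue, dam, lag_weeks)
    if len(x) < start_n:
        raise ValidationError(
            f"only {len(x)} paired weeks; need at least {start_n}")
    return [_ols(x[:n], y[:n]) for n in range(start_n, len(x) + 1)]


def detect_convergence(
    slopes: Sequence[float], rel_tol: float = 0.20, start_n: int = 3
) -> Optional[int]:
    """Number of data points at which the slope sequence converges.

    ``slopes[i]`` is the slope after ``start_n + i`` data points.  The
    convergence point is the smallest n whose slope — and every later
    slope — is within ``rel_tol`` (relative) of the final slope.  The final
    point alone cannot establish convergence (it is trivially within
    tolerance of itself); when no earlier point qualifies the sequence never
    converged and ``None`` is returned.
    """
    if len(slopes) < 2:
        raise ValidationError("need at least 2 slopes")
    final = slopes[-1]
    if final == 0:
        raise ValidationError("final slope is zero; relative tolerance undefined")
    ok = [abs(s - final) / abs(final) <= rel_tol for s in slopes]
    for i in range(len(slopes) - 1):
        if all(ok[i:]):
            return start_n + i
    return None


def forecast_weeks(
    reg: RegressionResult, future_cpue: Sequence[float]
) -> Tuple[List[float], float]:
    """Predict up to three future weekly dam counts from upcoming CPUE
    readings; returns (per-week predictions, cumulative).  Predictions are
    not clamped at zero."""
    preds = [reg.predict(x) for x in future_cpue[:3]]
    return preds, float(sum(preds))


def ape(predicted_cum: float, observed_cum: float) -> float:
    """Absolute percentage error |observed - predicted| / observed x 100."""
    if observed_cum <= 0:
        raise ValidationError(
            f"observed cumulative must be positive, got {observed_cum}")
    return abs(observed_cum - predicted_cum) / observed_cum * 100.0


def mape(apes: Sequence[float]) -> float:
    """Arithmetic mean of APEs."""
    if len(apes) == 0:
        raise ValidationError("empty APE list")
    return float(sum(apes)) / len(apes)


def in_season_table(
    cpue: SeriesLike,
    dam: SeriesLike,
    lag_weeks: int = 2,
    start_n: int = 3,
    predict_from: int = 5,
    horizon: int = 3,
    year: int = 0,
) -> List[ForecastRow]:
    """The full in-season procedure for one year.

    For each n (number of openings used) the regression is refit; from
    ``predict_from`` points onward the fit predicts up to ``horizon`` future
    weekly dam counts from the next CPUE readings, and the cumulative
    prediction is scored by APE against the observed counts of those weeks.
    """
    x, y, _ = _aligned_pairs(cpue, dam, lag_weeks)
    rows: List[ForecastRow] = []
    for i, reg in enumerate(incremental_slopes(cpue, dam, lag_weeks, start_n)):
        n = start_n + i
        future_x = x[n:n + horizon]
        future_y = y[n:n + horizon]
        if n >= predict_from and len(future_x) > 0:
            preds, pred_cum = forecast_weeks(reg, list(future_x))
            obs_cum = float(np.sum(future_y))
            rows.append(ForecastRow(
                year=year, n_points=n, slope=reg.slope,
                intercept=reg.intercept, r2=reg.r2,
                predictions=tuple(preds), pred_cumulative=pred_cum,
                observed=tuple(float(v) for v in future_y),
                obs_cumulative=obs_cum, ape=ape(pred_cum, obs_cum)))
        else:
            rows.append(ForecastRow(
                year=year, n_points=n, slope=reg.slope,
                intercept=reg.intercept, r2=reg.r2))
    return rows
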