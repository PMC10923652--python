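"""Travel-time estimation and CPUE-to-dam-count lag selection.

Estuary-tagged spring Chinook are re-detected at Bonneville dam; pooling the
PIT records across years gives a mean travel time per statistical week of
capture.  Travel speeds up as the season progresses, which is why a fixed
2-week lag fits most years but an early-timed year needs a longer one.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Tuple, Union

import pandas as pd

from .datamodel import TravelRecord, ValidationError

__all__ = [
    "BONNEVILLE_RKM",
    "FISHERY_LOWER_BOUNDARY_RKM",
    "TRAVEL_DISTANCE_RKM",
    "weekly_mean_travel",
    "travel_rate",
    "initial_peak",
    "select_lag",
]

#: River kilometres upstream of the Columbia mouth.
BONNEVILLE_RKM = 235.0
#: Downstream boundary of the test-fishery reach.
FISHERY_LOWER_BOUNDARY_RKM = 34.0
#: Distance a fish travels from the fishery reach to Bonneville dam.
TRAVEL_DISTANCE_RKM = BONNEVILLE_RKM - FISHERY_LOWER_BOUNDARY_RKM


def weekly_mean_travel(
    records: Iterable[TravelRecord], min_n: int = 6
) -> Dict[int, Tuple[float, int]]:
    """Mean travel days per capture week, pooled across years.

    Weeks with fewer than ``min_n`` fish are dropped.  Returns
    ``{capture_week: (mean_days, n)}`` ordered by week.
    """
    by_week: Dict[int, list] = {}
    for rec in records:
        by_week.setdefault(rec.capture_week, []).append(rec.travel_days)
    out: Dict[int, Tuple[float, int]] = {}
    for week in sorted(by_week):
        days = by_week[week]
        if len(days) >= min_n:
            out[week] = (sum(days) / len(days), len(days))
    return out


def travel_rate(distance_rkm: float, mean_days: float) -> float:
    """Migration rate in Rkm/day, reported to one decimal."""
    if mean_days <= 0:
        raise ValidationError(f"mean_days must be positive, got {mean_days}")
    if distance_rkm == 0:
        return 0.0
    return round(distance_rkm / mean_days, 1)


def _as_series(series: Union[pd.Series, Mapping[int, float]]) -> pd.Series:
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) \
        else series.astype(float)
    return s.sort_index()


def initial_peak(
    series: Union[pd.Series, Mapping[int, float]], frac: float = 0.5
) -> int:
    """Week of the first local maximum exceeding ``frac`` of the series max.

    The run can show an early shoulder before its highest week; the initial
    peak (not the highest) is what lines up between the fishery and the dam.
    Endpoints count as local maxima.
    """
    s = _as_series(series)
    if s.empty or s.max() <= 0:
        raise ValidationError("no peak detectable in all-zero/empty series")
    threshold = frac * s.max()
    values = s.to_numpy()
    weeks = s.index.to_numpy()
    for i, v in enumerate(values):
        left = values[i - 1] if i > 0 else float("-inf")
        right = values[i + 1] if i < len(values) - 1 else float("-inf")
        if v >= left and v >= right and v >= threshold:
            return int(weeks[i])
    raise ValidationError("no peak detectable")


def select_lag(
    cpue_series: Union[pd.Series, Mapping[int, float]],
    dam_series: Union[pd.Series, Mapping[int, float]],
    candidates: Iterable[int] = range(1, 6),
    mode: str = "peak",
    peak_frac: float = 0.5,
) -> int:
    """Lag (whole statistical weeks) between fishery CPUE and dam counts.

    ``peak`` mode (default): difference between the initial-peak weeks of the
    two series.  ``r2`` mode: the candidate lag maximising the R^2 of the
    lagged regression, ties broken toward the smaller lag.
    """
    cpue = _as_series(cpue_series)
    dam = _as_series(dam_series)
    if mode == "peak":
        return initial_peak(dam, peak_frac) - initial_peak(cpue, peak_frac)
    if mode == "r2":
        from .forecasting import lagged_regression

        best_lag, best_r2 = None, -1.0
        for lag in sorted(candidates):
            weeks = [w for w in cpue.index if w + lag in dam.index]
            if len(weeks) < 4:
                continue
            res = lagged_regression(cpue, dam, lag)
            if res.r2 > best_r2 + 1e-12:
                best_lag, best_r2 = lag, res.r2
        if best_lag is None:
            raise ValidationError(
                "no candidate lag has >= 4 overlapping weeks")
        return best_lag
    raise ValueError(f"unknown mode {mode!r}")
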