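"""Weekly catch accounting and CPUE estimation.

From one weekly drift-net opening we know, per fin clip, how many fish were
visually stock-identified (VSI) as lower vs. upriver, plus a pool of adult
Chinook that were never VSI'd (fish taken out of the net by sea lions, and a
few early-year unidentified fish).  Estimation proceeds in two stages:

1. a recorded sea-lion take is split into AD/AI by the sampled fin-clip
   proportions of that week (both stocks combined);
2. within each clip, the no-VSI fish are apportioned to lower/upriver by the
   sampled VSI proportions of that clip, giving estimated category totals;

CPUE is the estimated total divided by the number of drifts.  Totals are
conserved within each clip at every stage.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .datamodel import (
    CLIPS,
    STOCKS,
    CategoryEstimate,
    DriftWeekRecord,
    ValidationError,
)

__all__ = [
    "apportion_sealion_by_clip",
    "resolve_novsi",
    "estimate_category_totals",
    "compute_cpue",
    "estimate_week",
    "estimate_table",
]


def apportion_sealion_by_clip(record: DriftWeekRecord) -> Tuple[float, float]:
    """Split a sea-lion take into (AD, AI) no-VSI fish.

    The split is proportional to the sampled AD:AI ratio of the week, both
    stocks combined, because sea-lion-taken fish were never examined.
    """
    if record.sealion_take is None:
        raise ValidationError(
            f"{record.year} wk{record.stat_week}: no sea-lion take recorded")
    take = float(record.sealion_take)
    if take == 0.0:
        return (0.0, 0.0)
    ad = record.sampled_clip_total("AD")
    ai = record.sampled_clip_total("AI")
    if ad + ai == 0:
        raise ValidationError(
            f"{record.year} wk{record.stat_week}: sea-lion take {take:g} "
            "with zero sampled fish; no basis for apportionment")
    return (take * ad / (ad + ai), take * ai / (ad + ai))


def resolve_novsi(record: DriftWeekRecord) -> Tuple[float, float]:
    """No-VSI (AD, AI) fish for a week.

    When a sea-lion take was recorded the split is recomputed from the take;
    otherwise the recorded no-VSI counts are used as printed.
    """
    if record.sealion_take is not None:
        return apportion_sealion_by_clip(record)
    return (record.novsi_ad, record.novsi_ai)


def estimate_category_totals(
    record: DriftWeekRecord,
    novsi: Tuple[float, float],
) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """Estimated (proportion, total) per (stock, clip) cell.

    Within each clip the sampled VSI proportion p_stock|clip apportions the
    whole clip total (sampled + no-VSI) to the two stocks, so per-clip totals
    are conserved.  A clip with no VSI'd fish but a positive no-VSI count has
    no basis for apportionment and raises.
    """
    novsi_by_clip = dict(zip(CLIPS, novsi))
    out: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for clip in CLIPS:
        sampled = {s: record.sampled(s, clip) for s in STOCKS}
        denom = sum(sampled.values())
        extra = novsi_by_clip[clip]
        if extra < 0:
            raise ValidationError("negative no-VSI count")
        if denom == 0:
            if extra > 0:
                raise ValidationError(
                    f"{record.year} wk{record.stat_week}: {extra:g} no-VSI "
                    f"{clip} fish but no VSI'd {clip} fish to apportion by")
            for s in STOCKS:
                out[(s, clip)] = (0.0, 0.0)
            continue
        for s in STOCKS:
            p = sampled[s] / denom
            out[(s, clip)] = (p, p * (denom + extra))
    return out


def compute_cpue(
    est_totals: Dict[Tuple[str, str], Tuple[float, float]],
    n_drifts: int,
    year: int = 0,
    stat_week: int = 0,
) -> List[CategoryEstimate]:
    """Estimated fish per drift for each (stock, clip) cell plus per-stock
    totals (clip label ``"total"``)."""
    if n_drifts < 1:
        raise ValidationError(f"n_drifts must be >= 1, got {n_drifts}")
    out = []
    for stock in STOCKS:
        stock_total = 0.0
        for clip in CLIPS:
            p, est = est_totals[(stock, clip)]
            stock_total += est
            out.append(CategoryEstimate(
                year=year, stat_week=stat_week, vsi_stock=stock, clip=clip,
                proportion=p, est_total=est, cpue=est / n_drifts))
        out.append(CategoryEstimate(
            year=year, stat_week=stat_week, vsi_stock=stock, clip="total",
            proportion=1.0, est_total=stock_total,
            cpue=stock_total / n_drifts))
    return out


def estimate_week(record: DriftWeekRecord) -> List[CategoryEstimate]:
    """Full per-week pipeline: no-VSI resolution, apportionment, CPUE."""
    novsi = resolve_novsi(record)
    totals = estimate_category_totals(record, novsi)
    return compute_cpue(totals, record.n_drifts,
                        year=record.year, stat_week=record.stat_week)


def estimate_table(records: Iterable[DriftWeekRecord]) -> pd.DataFrame:
    """Run the estimator over many weeks, one row per (year, week).

    Column layout mirrors the published CPUE table: per stock, the AD and AI
    proportion / estimated total / CPUE plus the stock's total CPUE.
    """
    rows = []
    for rec in records:
        estimates = {(e.vsi_stock, e.clip): e for e in estimate_week(rec)}
        row: Dict[str, float] = {"year": rec.year, "stat_week": rec.stat_week}
        for stock in STOCKS:
            for clip in CLIPS:
                e = estimates[(stock, clip)]
                row[f"{stock}_{clip.lower()}_pct"] = e.proportion
                row[f"{stock}_{clip.lower()}_est"] = e.est_total
                row[f"{stock}_{clip.lower()}_cpue"] = e.cpue
            row[f"{stock}_total_cpue"] = estimates[(stock, "total")].cpue
        rows.append(row)
    return pd.DataFrame(rows)
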