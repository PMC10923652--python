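"""CSV readers and writers for the tabular inputs of the pipeline.

All files are UTF-8 CSV with a header row and one record per row.  The
``schema`` tag selects the expected layout:

``table1``
    Weekly drift-level catch: ``year, stat_week, month, day, n_drifts,
    lower_ad, lower_ai, lower_unk, upriver_ad, upriver_ai, upriver_unk,
    novsi_ad, novsi_ai, sealion_take, total_chinook`` (the last five may be
    blank; a blank ``sealion_take`` means removals were not recorded that
    year, which is distinct from zero).
``samples``
    Per-fish records: ``sample_id, year, stat_week, origin_site,
    fork_length_mm, vsi_stock, fin_clip, genstock_obs, pbt_broodstock,
    genstock_exp`` (the last two blank for PBT-unassigned fish).
``tag_rates``
    ``broodstock, tag_rate`` with rates in (0, 1].
``dam``
    Dam passage counts: ``year, week_lo, week_hi, ad_count, ai_count``
    (plus optional ``stratum``); weekly series have ``week_lo == week_hi``.
``travel``
    PIT travel times: ``year, capture_week, travel_days``.

Validation failures raise :class:`~rivercast.datamodel.ValidationError`
naming the offending column and 1-based data row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

from .datamodel import (
    DamCount,
    DriftWeekRecord,
    FishSample,
    TagRateTable,
    TravelRecord,
    ValidationError,
)

__all__ = ["read_table", "write_table", "SCHEMAS"]

SCHEMAS = ("table1", "samples", "tag_rates", "dam", "travel")

_REQUIRED_COLUMNS = {
    "table1": ["year", "stat_week", "n_drifts", "lower_ad", "lower_ai",
               "upriver_ad", "upriver_ai"],
    "samples": ["sample_id", "year", "stat_week", "vsi_stock", "fin_clip",
                "genstock_obs"],
    "tag_rates": ["broodstock", "tag_rate"],
    "dam": ["year", "week_lo", "week_hi", "ad_count", "ai_count"],
    "travel": ["year", "capture_week", "travel_days"],
}


def _require_columns(df: pd.DataFrame, schema: str, path) -> None:
    missing = [c for c in _REQUIRED_COLUMNS[schema] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing} for schema {schema!r}")


def _cell(row, name, default=None):
    if name not in row or pd.isna(row[name]):
        return default
    return row[name]


def read_table(path: Union[str, Path], schema: str):
    """Read and validate one CSV file, returning typed records.

    Returns a list of records for ``table1``/``samples``/``dam``/``travel``
    and a :class:`TagRateTable` for ``tag_rates``.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"day": str, "month": str}
                     if schema == "table1" else None)
    _require_columns(df, schema, path)
    reader = {
        "table1": _read_table1,
        "samples": _read_samples,
        "tag_rates": _read_tag_rates,
        "dam": _read_dam,
        "travel": _read_travel,
    }[schema]
    return reader(df)


def _read_table1(df: pd.DataFrame) -> List[DriftWeekRecord]:
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        take = _cell(row, "sealion_take")
        rec = DriftWeekRecord(
            year=int(row["year"]),
            stat_week=int(row["stat_week"]),
            n_drifts=int(row["n_drifts"]),
            lower_ad=int(row["lower_ad"]),
            lower_ai=int(row["lower_ai"]),
            lower_unk=int(_cell(row, "lower_unk", 0)),
            upriver_ad=int(row["upriver_ad"]),
            upriver_ai=int(row["upriver_ai"]),
            upriver_unk=int(_cell(row, "upriver_unk", 0)),
            novsi_ad=float(_cell(row, "novsi_ad", 0.0)),
            novsi_ai=float(_cell(row, "novsi_ai", 0.0)),
            sealion_take=None if take is None else int(take),
            total_chinook=_cell(row, "total_chinook"),
            month=str(_cell(row, "month", "")),
            day=str(_cell(row, "day", "")),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def _read_samples(df: pd.DataFrame) -> List[FishSample]:
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        brood = _cell(row, "pbt_broodstock")
        exp = _cell(row, "genstock_exp")
        rec = FishSample(
            sample_id=str(row["sample_id"]),
            year=int(row["year"]),
            stat_week=int(row["stat_week"]),
            origin_site=str(_cell(row, "origin_site", "SCTF")),
            fork_length_mm=float(_cell(row, "fork_length_mm", 700.0)),
            vsi_stock=str(row["vsi_stock"]),
            fin_clip=str(row["fin_clip"]),
            genstock_obs=str(row["genstock_obs"]),
            pbt_broodstock=None if brood is None else str(brood),
            genstock_exp=None if exp is None else str(exp),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def _read_tag_rates(df: pd.DataFrame) -> TagRateTable:
    rates = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        rate = float(row["tag_rate"])
        if not (0.0 < rate <= 1.0) or math.isnan(rate):
            raise ValidationError(
                f"tag_rate out of (0, 1] at row {i}: {rate}")
        rates[str(row["broodstock"])] = rate
    return TagRateTable(rates)


def _read_dam(df: pd.DataFrame) -> List[DamCount]:
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        stratum = _cell(row, "stratum")
        rec = DamCount(
            year=int(row["year"]),
            week_lo=int(row["week_lo"]),
            week_hi=int(row["week_hi"]),
            ad_count=float(row["ad_count"]),
            ai_count=float(row["ai_count"]),
            stratum=None if stratum is None else int(stratum),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def _read_travel(df: pd.DataFrame) -> List[TravelRecord]:
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rec = TravelRecord(
            year=int(row["year"]),
            capture_week=int(row["capture_week"]),
            travel_days=float(row["travel_days"]),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_table(records: Sequence, path: Union[str, Path], schema: str) -> None:
    """Write typed records back to CSV in the schema's column layout."""
    path = Path(path)
    if schema == "table1":
        df = pd.DataFrame([
            {
                "year": r.year, "stat_week": r.stat_week, "month": r.month,
                "day": r.day, "n_drifts": r.n_drifts,
                "lower_ad": r.lower_ad, "lower_ai": r.lower_ai,
                "lower_unk": r.lower_unk, "upriver_ad": r.upriver_ad,
                "upriver_ai": r.upriver_ai, "upriver_unk": r.upriver_unk,
                "novsi_ad": round(r.novsi_ad, 2),
                "novsi_ai": round(r.novsi_ai, 2),
                "sealion_take": r.sealion_take,
                "total_chinook": r.total_chinook,
            }
            for r in records
        ])
    elif schema == "samples":
        df = pd.DataFrame([
            {
                "sample_id": r.sample_id, "year": r.year,
                "stat_week": r.stat_week, "origin_site": r.origin_site,
                "fork_length_mm": r.fork_length_mm,
                "vsi_stock": r.vsi_stock, "fin_clip": r.fin_clip,
                "genstock_obs": r.genstock_obs,
                "pbt_broodstock": r.pbt_broodstock,
                "genstock_exp": r.genstock_exp,
            }
            for r in records
        ])
    elif schema == "tag_rates":
        df = pd.DataFrame(
            [{"broodstock": b, "tag_rate": t} for b, t in records.items()])
    elif schema == "dam":
        df = pd.DataFrame([
            {
                "year": r.year, "week_lo": r.week_lo, "week_hi": r.week_hi,
                "ad_count": r.ad_count, "ai_count": r.ai_count,
                "stratum": r.stratum,
            }
            for r in records
        ])
    elif schema == "travel":
        df = pd.DataFrame([
            {"year": r.year, "capture_week": r.capture_week,
             "travel_days": r.travel_days}
            for r in records
        ])
    else:
        raise ValueError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)
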