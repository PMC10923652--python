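"""Packaged transcriptions of the published study tables.

The fixtures are small CSVs shipped inside the package:

* ``table1`` — weekly drift-level catch (returns ``list[DriftWeekRecord]``)
* ``table2`` — Bonneville dam strata with AD/AI counts and adult-fish-facility
  sample sizes (``list[DamCount]``; AFF sizes on the DataFrame via
  :func:`fixture_frame`)
* ``table3`` — test-fishery stratification sample sizes (``DataFrame``)
* ``table4`` — published CPUE estimates, used as reference values
  (``DataFrame``)
* ``table5`` — per-fish VSI x GenStock x category counts (``DataFrame``;
  :func:`table5_samples` expands it to ``FishSample`` records)
* ``table6`` — dam-passage abundance by GenStock and category (``DataFrame``)
* ``table7`` — in-season regression states and forecasts (``DataFrame``)

File checksums are pinned so a silently edited fixture fails loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import List

import pandas as pd

from ..datamodel import DamCount, DriftWeekRecord, FishSample, ValidationError
from .. import io as _io

__all__ = ["fixture", "fixture_frame", "fixture_path", "table5_samples",
           "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5", "table6",
                 "table7")

_CHECKSUMS = {
    "table1": "d87c1a97570eb2a63b941a07227380d51b85932f62ff6576b1c47b8e5e10e053",
    "table2": "3d8db261ce494c9c06d75ce7b905d1ec35999fe18b38e453aacb29277b3310ed",
    "table3": "b10808d38bb296008742ceebf95b218374a82bde98530c4f0c701eb4de938898",
    "table4": "1d7ae5747de9e3bfc6d46c9d7d0ba997b9f050b1d34c745abd0fdda0ad705917",
    "table5": "ab52589dacf8794891b125fce3c4756d30617ff23bafc2f06a91ae0c11fad55b",
    "table6": "7fe298963a51e37053c672ce8179bce236b6a74c729b3aad31deb0202e6d4dda",
    "table7": "37adac0dddc30b2c649b16d2b9a841a0abab6a6292070c3e9b8c7c9c9856ac9c",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture CSV (context-free resource)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected {FIXTURE_NAMES}")
    return resources.files(__name__).joinpath(f"{name}.csv")

def _verified_bytes(name: str) -> bytes:
    data = fixture_path(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[name]
    if expected and digest != expected:
        raise ValidationError(
            f"fixture {name!r} checksum mismatch: {digest}")
    return data


def fixture_frame(name: str) -> pd.DataFrame:
    """The raw fixture as a DataFrame, checksum-verified."""
    import io as _stdio

    return pd.read_csv(_stdio.BytesIO(_verified_bytes(name)))


def fixture(name: str):
    """Load a fixture in its natural typed form (see module docstring)."""
    if name == "table1":
        return _table1_records()
    if name == "table2":
        return _table2_records()
    return fixture_frame(name)


def _table1_records() -> List[DriftWeekRecord]:
    import io as _stdio

    df = pd.read_csv(_stdio.BytesIO(_verified_bytes("table1")),
                     dtype={"day": str, "month": str})
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        take = row.get("sealion_take")
        take = None if pd.isna(take) else int(take)
        rec = DriftWeekRecord(
            year=int(row["year"]), stat_week=int(row["stat_week"]),
            n_drifts=int(row["n_drifts"]),
            lower_ad=int(row["lower_ad"]), lower_ai=int(row["lower_ai"]),
            lower_unk=int(row["lower_unk"]),
            upriver_ad=int(row["upriver_ad"]),
            upriver_ai=int(row["upriver_ai"]),
            upriver_unk=int(row["upriver_unk"]),
            novsi_ad=float(row["novsi_ad"]), novsi_ai=float(row["novsi_ai"]),
            sealion_take=take, total_chinook=float(row["total_chinook"]),
            month=row["month"], day=row["day"],
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def _table2_records() -> List[DamCount]:
    df = fixture_frame("table2")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rec = DamCount(
            year=int(row["year"]), week_lo=int(row["week_lo"]),
            week_hi=int(row["week_hi"]), ad_count=float(row["ad_count"]),
            ai_count=float(row["ai_count"]), stratum=int(row["stratum"]),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def table5_samples(years=None) -> List[FishSample]:
    """Expand the table5 count cells into individual ``FishSample`` records.

    Each counted fish gets a synthetic id, an adult fork length, and —
    for HNC fish — a placeholder broodstock named after its reporting
    group (the published table does not identify broodstocks).
    """
    df = fixture_frame("table5")
    if years is not None:
        df = df[df["year"].isin(list(years))]
    samples: List[FishSample] = []
    n = 0
    for row in df.to_dict("records"):
        year = int(row["year"])
        code = str(row["genstock"])
        vsi = str(row["vsi_stock"])
        category = str(row["category"])
        for _ in range(int(row["count"])):
            n += 1
            clip = "AD" if category == "H" else "AI"
            pbt = f"{code}-BY{year - 4}" if category == "HNC" else None
            samples.append(FishSample(
                sample_id=f"T5-{year}-{n:04d}", year=year, stat_week=15,
                origin_site="SCTF", fork_length_mm=700.0, vsi_stock=vsi,
                fin_clip=clip, genstock_obs=code, pbt_broodstock=pbt,
                genstock_exp=code if pbt else None,
            ))
    return samples
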