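"""Agreement between visual (VSI) and genetic (GSI) stock identification.

A fish is concordant when the geographic side of its genetic reporting
group (lower vs. upriver of Bonneville dam) matches its visual call.  Fish
whose reporting group is outside the spring management window still count in
the denominators — and as discordant when on the wrong side — matching how
the published subtotals are tallied.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .datamodel import DEFAULT_CATALOG, FishSample, GenStockCatalog

__all__ = ["classify_lower_upriver", "concordance_table"]


def classify_lower_upriver(
    genstock: str, catalog: GenStockCatalog = DEFAULT_CATALOG
) -> str:
    """Spring-management classification of a reporting group:
    ``lower``, ``upriver`` or ``excluded`` (run timing outside the spring
    period)."""
    return catalog.classify(genstock)


def concordance_table(
    samples: Iterable[FishSample],
    catalog: GenStockCatalog = DEFAULT_CATALOG,
    adults_only: bool = True,
) -> pd.DataFrame:
    """Per-year and pooled VSI/GSI concordance percentages.

    ``lower_pct`` is the share of VSI-lower fish whose genetic side is also
    lower; ``upriver_pct`` analogously; ``total_pct`` pools numerators and
    denominators, so it always lies between the two.  Undefined cells (zero
    denominator) are NaN.  Percentages are on the 0-100 scale at full
    precision; round to one decimal for presentation.
    """
    rows = []
    for s in samples:
        if adults_only and not s.is_adult:
            continue
        if s.vsi_stock not in ("lower", "upriver"):
            continue
        rows.append({
            "year": s.year,
            "vsi": s.vsi_stock,
            "gsi_side": catalog.side(s.genstock),
        })
    df = pd.DataFrame(rows, columns=["year", "vsi", "gsi_side"])

    def _one(group: pd.DataFrame) -> dict:
        out = {}
        num_pool = den_pool = 0
        for stock in ("lower", "upriver"):
            sub = group[group["vsi"] == stock]
            den = len(sub)
            num = int((sub["gsi_side"] == stock).sum())
            out[f"{stock}_pct"] = 100.0 * num / den if den else float("nan")
            num_pool += num
            den_pool += den
        out["total_pct"] = (
            100.0 * num_pool / den_pool if den_pool else float("nan"))
        out["n"] = den_pool
        return out

    results = []
    for year in sorted(df["year"].unique()):
        row = {"year": int(year)}
        row.update(_one(df[df["year"] == year]))
        results.append(row)
    pooled = {"year": "pooled"}
    pooled.update(_one(df))
    results.append(pooled)
    return pd.DataFrame(
        results,
        columns=["year", "lower_pct", "upriver_pct", "total_pct", "n"])
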