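"""Stock-composition estimation with tag-rate-balanced PBT expansion.

Genotyped fish from a stratum are decomposed into origin categories and
genetic stocks, and the stratum's abundance (CPUE units at the test fishery,
dam-count units at Bonneville) is apportioned by the resulting proportions.

PBT-assigned fish undercount their hatchery cohort because only a fraction
(the *tag rate*) of each broodstock's parents were genotyped.  Each
assignment is therefore expanded by 1/tag-rate, and — to avoid
double-counting natural-origin fish — the surplus is subtracted from the
PBT-*unassigned* fish of the same observed reporting group, proportionally
(the balancing rule).  When the unassigned pool is too small the subtraction
is clamped at zero, the broodstock keeps only what the pool could supply,
and a warning records the discarded surplus; group totals are conserved in
every case.

Uncertainty comes from a stratified bootstrap: fish are resampled with
replacement within (stratum x VSI stock x fin clip) cells, the whole
estimator is re-run, and percentile intervals are taken; abundance inputs
are held fixed, so the intervals express composition uncertainty only.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    DamCount,
    FishSample,
    StratumDef,
    TagRateTable,
    ValidationError,
)

__all__ = [
    "StratumComposition",
    "build_strata",
    "build_dam_strata",
    "spibetr_expand",
    "estimate_composition_cpue",
    "estimate_dam_composition",
    "bootstrap_ci",
]

GroupKey = Tuple[str, str]  # (vsi_stock or "all", fin clip)
CellKey = Tuple[str, str, str, Optional[str], Optional[str]]
# (vsi_stock, clip, category, genstock, broodstock)


def _default_group(sample: FishSample) -> GroupKey:
    return (sample.vsi_stock, sample.fin_clip)


@dataclass
class StratumComposition:
    """Composition of one stratum: expanded counts and apportioned abundance.

    ``cells`` has one row per (vsi_stock, clip, category, genstock,
    broodstock) with the balanced count and the abundance value; broodstock
    is NA for PBT-unassigned cells.
    """

    stratum: StratumDef
    units: str
    cells: pd.DataFrame
    warnings: List[str] = field(default_factory=list)

    def total(self, vsi_stock: str, clip: str) -> float:
        sel = ((self.cells["vsi_stock"] == vsi_stock)
               & (self.cells["clip"] == clip))
        return float(self.cells.loc[sel, "value"].sum())

    def by_genstock(self, vsi_stock: Optional[str] = None) -> pd.Series:
        """Abundance summed to the reporting-group level."""
        df = self.cells
        if vsi_stock is not None:
            df = df[df["vsi_stock"] == vsi_stock]
        return df.groupby("genstock")["value"].sum()

    def by_category(self) -> pd.Series:
        """Abundance in the six stock/origin categories (L-H ... U-W)."""
        df = self.cells.copy()
        prefix = df["vsi_stock"].map({"lower": "L", "upriver": "U"})
        label = prefix.fillna("") + "-" + df["category"]
        label = label.str.lstrip("-")
        return df.groupby(label)["value"].sum()

    def cell_series(self) -> pd.Series:
        """Values keyed by full cell tuple, for bootstrap bookkeeping."""
        idx = pd.MultiIndex.from_frame(
            self.cells[["vsi_stock", "clip", "category", "genstock",
                        "broodstock"]].fillna(""))
        return pd.Series(self.cells["value"].to_numpy(), index=idx)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def _week_counts(samples: Iterable[FishSample]) -> pd.DataFrame:
    rows = [{"week": s.stat_week, "vsi": s.vsi_stock, "clip": s.fin_clip}
            for s in samples]
    return pd.DataFrame(rows, columns=["week", "vsi", "clip"])


def build_strata(
    samples: List[FishSample], min_vsi: int = 20, min_ai: int = 2
) -> List[StratumDef]:
    """Pool weeks into as many strata as possible subject to sample minima.

    Guidelines: the same strata serve both VSI stocks; each stratum holds at
    least ``min_vsi`` fish of each VSI stock and at least ``min_ai`` AI fish
    of each; and the number of strata is maximal.  A greedy left-to-right
    sweep (close a stratum as soon as the minima are met; fold a deficient
    tail into the last stratum) achieves the maximum because feasibility is
    monotone under adding weeks.  If the whole year cannot meet the minima a
    single stratum flagged ``deficient`` is returned with a warning.
    """
    if not samples:
        raise ValidationError("no samples to stratify")
    years = {s.year for s in samples}
    if len(years) > 1:
        raise ValidationError(f"samples span multiple years: {sorted(years)}")
    year = years.pop()
    df = _week_counts(samples)
    weeks = sorted(df["week"].unique())

    def satisfied(tally: Dict[str, int]) -> bool:
        return (tally["lower"] >= min_vsi and tally["upriver"] >= min_vsi
                and tally["lower_ai"] >= min_ai
                and tally["upriver_ai"] >= min_ai)

    strata: List[Tuple[int, int]] = []
    tally = {"lower": 0, "upriver": 0, "lower_ai": 0, "upriver_ai": 0}
    start = weeks[0]
    for week in weeks:
        sub = df[df["week"] == week]
        for vsi in ("lower", "upriver"):
            tally[vsi] += int((sub["vsi"] == vsi).sum())
            tally[f"{vsi}_ai"] += int(
                ((sub["vsi"] == vsi) & (sub["clip"] == "AI")).sum())
        if satisfied(tally):
            strata.append((start, week))
            tally = {k: 0 for k in tally}
            start = week + 1
    leftover = any(v > 0 for v in tally.values()) or start <= weeks[-1]
    if strata and leftover:
        # fold the deficient tail into the last complete stratum
        lo, _ = strata[-1]
        strata[-1] = (lo, weeks[-1])
    if not strata:
        _warnings.warn(
            f"year {year}: sample minima unattainable; using one deficient "
            "stratum", stacklevel=2)
        return [StratumDef(year=year, label="1", week_lo=weeks[0],
                           week_hi=weeks[-1], deficient=True)]
    return [StratumDef(year=year, label=str(i + 1), week_lo=lo, week_hi=hi)
            for i, (lo, hi) in enumerate(strata)]


def build_dam_strata(
    samples: List[FishSample], min_total: int = 100
) -> List[StratumDef]:
    """Pool dam (adult-fish-facility) sample weeks to ~``min_total`` fish per
    stratum, as many strata as possible, deficient tail folded backwards."""
    if not samples:
        raise ValidationError("no samples to stratify")
    years = {s.year for s in samples}
    if len(years) > 1:
        raise ValidationError(f"samples span multiple years: {sorted(years)}")
    year = years.pop()
    counts = pd.Series([s.stat_week for s in samples]).value_counts()
    weeks = sorted(counts.index)
    strata: List[Tuple[int, int]] = []
    start, running = weeks[0], 0
    for week in weeks:
        running += int(counts[week])
        if running >= min_total:
            strata.append((start, week))
            start, running = week + 1, 0
    if strata and running > 0:
        lo, _ = strata[-1]
        strata[-1] = (lo, weeks[-1])
    if not strata:
        _warnings.warn(
            f"year {year}: fewer than {min_total} samples in total; one "
            "deficient stratum", stacklevel=2)
        return [StratumDef(year=year, label="1", week_lo=weeks[0],
                           week_hi=weeks[-1], deficient=True)]
    return [StratumDef(year=year, label=str(i + 1), week_lo=lo, week_hi=hi)
            for i, (lo, hi) in enumerate(strata)]


# ---------------------------------------------------------------------------
# Tag-rate-balanced expansion
# ---------------------------------------------------------------------------


def spibetr_expand(
    samples: List[FishSample],
    tag_rates: TagRateTable,
    abundance: Mapping[GroupKey, float],
    stratum: Optional[StratumDef] = None,
    units: str = "cpue",
    group_of: Callable[[FishSample], GroupKey] = _default_group,
) -> StratumComposition:
    """Balanced composition of one stratum.

    Within each (VSI stock, clip) group: PBT-assigned counts are expanded by
    1/tag-rate; the surplus is taken from PBT-unassigned fish whose observed
    reporting group matches the broodstock's expected one, proportionally
    across broodstocks competing for the same pool and clamped at an empty
    pool (discarded surplus is logged).  Counts are then normalised and
    multiplied by the group's abundance.
    """
    tag_rates.require(
        s.pbt_broodstock for s in samples if s.pbt_broodstock)
    groups: Dict[GroupKey, List[FishSample]] = {}
    for s in samples:
        groups.setdefault(group_of(s), []).append(s)

    warn_log: List[str] = []
    rows = []
    for key, abund in abundance.items():
        members = groups.get(key, [])
        if not members:
            if abund > 0:
                raise ValidationError(
                    f"abundance {abund:g} for group {key} but no samples")
            continue
        vsi, clip = key
        n_total = len(members)

        assigned: Dict[str, int] = {}       # broodstock -> count
        brood_gen: Dict[str, str] = {}      # broodstock -> expected genstock
        unassigned: Dict[str, float] = {}   # observed genstock -> count
        for s in members:
            if s.is_pbt_assigned:
                assigned[s.pbt_broodstock] = assigned.get(
                    s.pbt_broodstock, 0) + 1
                brood_gen[s.pbt_broodstock] = s.genstock_exp
            else:
                unassigned[s.genstock_obs] = unassigned.get(
                    s.genstock_obs, 0.0) + 1.0

        # surplus demanded per expected genstock, then proportional draw
        demand: Dict[str, float] = {}
        surplus: Dict[str, float] = {}
        for b, n_b in assigned.items():
            s_b = n_b * (1.0 / tag_rates[b] - 1.0)
            surplus[b] = s_b
            g = brood_gen[b]
            demand[g] = demand.get(g, 0.0) + s_b
        scale: Dict[str, float] = {}
        for g, s_g in demand.items():
            avail = unassigned.get(g, 0.0)
            taken = min(s_g, avail)
            scale[g] = taken / s_g if s_g > 0 else 0.0
            if s_g > taken + 1e-12:
                msg = (f"group {key}: surplus {s_g - taken:.3f} for "
                       f"genstock {g} exceeds unassigned pool; clamped")
                warn_log.append(msg)
                _warnings.warn(msg, stacklevel=2)
            unassigned[g] = avail - taken

        counts: Dict[CellKey, float] = {}
        for b, n_b in assigned.items():
            g = brood_gen[b]
            category = "H" if clip == "AD" else "HNC"
            counts[(vsi, clip, category, g, b)] = (
                n_b + surplus[b] * scale[g])
        for g, u_g in unassigned.items():
            if u_g <= 0:
                continue
            category = "H" if clip == "AD" else "W"
            counts[(vsi, clip, category, g, None)] = counts.get(
                (vsi, clip, category, g, None), 0.0) + u_g

        for (v, c, category, g, b), count in counts.items():
            rows.append({
                "vsi_stock": v, "clip": c, "category": category,
                "genstock": g, "broodstock": b,
                "count": count, "value": count / n_total * abund,
            })

    cells = pd.DataFrame(
        rows, columns=["vsi_stock", "clip", "category", "genstock",
                       "broodstock", "count", "value"])
    if stratum is None:
        year = samples[0].year if samples else 0
        stratum = StratumDef(year=year, label="1", week_lo=0, week_hi=0)
    return StratumComposition(stratum=stratum, units=units, cells=cells,
                              warnings=warn_log)


# ---------------------------------------------------------------------------
# Stratified estimators
# ---------------------------------------------------------------------------


def _stratum_samples(samples: Iterable[FishSample],
                     stratum: StratumDef) -> List[FishSample]:
    return [s for s in samples
            if s.year == stratum.year and stratum.contains(s.stat_week)]


def estimate_composition_cpue(
    samples: List[FishSample],
    tag_rates: TagRateTable,
    cpue: pd.DataFrame,
    strata: List[StratumDef],
) -> List[StratumComposition]:
    """Decompose weekly CPUE into genetic-stock composition per stratum.

    ``cpue`` is the weekly estimate table (one row per year x week with
    ``{stock}_{clip}_cpue`` columns).  Weekly CPUE is summed within each
    stratum per (VSI stock, clip) and apportioned by that stratum's balanced
    sample composition; the GenStock-level sums therefore conserve the CPUE
    input.  A week with positive CPUE not covered by any stratum is an
    error.
    """
    out: List[StratumComposition] = []
    cpue = cpue.copy()
    covered = set()
    for stratum in strata:
        mask = ((cpue["year"] == stratum.year)
                & (cpue["stat_week"] >= stratum.week_lo)
                & (cpue["stat_week"] <= stratum.week_hi))
        sub = cpue[mask]
        covered.update(zip(sub["year"], sub["stat_week"]))
        abundance = {
            (stock, clip): float(sub[f"{stock}_{clip.lower()}_cpue"].sum())
            for stock in ("lower", "upriver") for clip in ("AD", "AI")
        }
        out.append(spibetr_expand(
            _stratum_samples(samples, stratum), tag_rates, abundance,
            stratum=stratum, units="cpue"))
    years = {st.year for st in strata}
    for _, row in cpue[cpue["year"].isin(years)].iterrows():
        key = (row["year"], row["stat_week"])
        total = sum(row[f"{stock}_{clip}_cpue"]
                    for stock in ("lower", "upriver") for clip in ("ad", "ai"))
        if key not in covered and total > 0:
            raise ValidationError(
                f"week {key} has CPUE > 0 but no covering stratum")
    return out


def estimate_dam_composition(
    aff_samples: List[FishSample],
    tag_rates: TagRateTable,
    dam_counts: List[DamCount],
    strata: Optional[List[StratumDef]] = None,
    min_total: int = 100,
) -> List[StratumComposition]:
    """Apply the composition engine to dam passage counts.

    Abundance inputs are the AD and AI adult-sized counts per stratum.  When
    published pooled strata are provided (``dam_counts`` with week ranges)
    they are used as-is; otherwise strata are built from the samples with
    the ~``min_total``-fish guideline and a weekly dam series is summed into
    them.  Dam samples carry no VSI call, so groups are keyed by clip only
    (``vsi_stock = "all"``).
    """
    group_of = lambda s: ("all", s.fin_clip)  # noqa: E731
    out: List[StratumComposition] = []
    if strata is None and all(not d.is_weekly for d in dam_counts):
        strata = [StratumDef(year=d.year, label=str(d.stratum or i + 1),
                             week_lo=d.week_lo, week_hi=d.week_hi)
                  for i, d in enumerate(dam_counts)]
    elif strata is None:
        strata = build_dam_strata(aff_samples, min_total=min_total)
    for stratum in strata:
        in_stratum = [d for d in dam_counts
                      if d.year == stratum.year
                      and d.week_lo >= stratum.week_lo
                      and d.week_hi <= stratum.week_hi]
        abundance = {
            ("all", "AD"): float(sum(d.ad_count for d in in_stratum)),
            ("all", "AI"): float(sum(d.ai_count for d in in_stratum)),
        }
        out.append(spibetr_expand(
            _stratum_samples(aff_samples, stratum), tag_rates, abundance,
            stratum=stratum, units="dam_count", group_of=group_of))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    estimator: Callable[[List[FishSample]], Mapping],
    samples: List[FishSample],
    B: int = 1000,
    alpha: float = 0.10,
    seed: Optional[int] = None,
    group_of: Callable[[FishSample], Tuple] = _default_group,
) -> Dict:
    """Stratified-bootstrap percentile intervals for a composition estimator.

    Fish are resampled with replacement within ``group_of`` cells (default:
    VSI stock x fin clip), the estimator is re-run, and per-cell
    ``(ci_lo, ci_hi)`` percentile intervals at ``alpha/2``, ``1 - alpha/2``
    are returned.  Cells absent from a replicate contribute zero.
    Deterministic for a given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    groups: Dict[Tuple, List[FishSample]] = {}
    for s in samples:
        groups.setdefault(group_of(s), []).append(s)
    group_lists = list(groups.values())

    draws: Dict[object, np.ndarray] = {}
    for rep in range(B):
        resampled: List[FishSample] = []
        for members in group_lists:
            idx = rng.integers(0, len(members), size=len(members))
            resampled.extend(members[i] for i in idx)
        result = estimator(resampled)
        items = result.items() if hasattr(result, "items") else result
        for cell, value in items:
            if cell not in draws:
                draws[cell] = np.zeros(B)
            draws[cell][rep] = value

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {cell: (float(np.percentile(vals, lo_q)),
                   float(np.percentile(vals, hi_q)))
            for cell, vals in draws.items()}
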