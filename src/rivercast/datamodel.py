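"""Domain types for the spring Chinook test-fishery analysis.

The test fishery intercepts a mixture of "lower river" and "upriver" spring
Chinook stocks near the Columbia River mouth.  Each fish encountered carries
up to three layers of identity:

* **VSI** (visual stock identification): lower vs. upriver, judged in the
  boat from coloration.
* **fin clip**: AD (adipose-clipped, hatchery-marked) vs. AI (adipose
  intact, putatively natural origin).
* **genetics**: a GSI reporting-group assignment (``genstock_obs``) for every
  genotyped fish, and for a subset a parentage-based-tagging (PBT) assignment
  to a hatchery broodstock, which implies an expected reporting group
  (``genstock_exp``).

These types are deliberately thin records; all estimation lives in the
sibling modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "ADULT_FORK_LENGTH_MM",
    "STOCKS",
    "CLIPS",
    "CATEGORIES",
    "SIX_CATEGORIES",
    "ValidationError",
    "DriftWeekRecord",
    "FishSample",
    "GenStockCatalog",
    "DEFAULT_CATALOG",
    "TagRateTable",
    "DamCount",
    "StratumDef",
    "TravelRecord",
    "CategoryEstimate",
    "CompositionEstimate",
    "ForecastRow",
]

#: Fork-length threshold separating adult-sized fish from jacks (mm).
#: Adults (>560 mm) proxy age classes 4+; jacks are excluded from analyses.
ADULT_FORK_LENGTH_MM = 560.0

STOCKS = ("lower", "upriver")
CLIPS = ("AD", "AI")
#: Origin categories: H = hatchery clipped (AD), HNC = hatchery no-clip
#: (AI but PBT-assigned), W = natural origin (AI, PBT-unassigned).
CATEGORIES = ("H", "HNC", "W")
SIX_CATEGORIES = ("L-H", "L-HNC", "L-W", "U-H", "U-HNC", "U-W")


class ValidationError(ValueError):
    """Raised when an input record violates a schema or invariant."""


# ---------------------------------------------------------------------------
# Catch records
# ---------------------------------------------------------------------------


@dataclass
class DriftWeekRecord:
    """One weekly opening of the test fishery (one Table-1-style row).

    ``novsi_ad``/``novsi_ai`` hold adult Chinook that were never visually
    stock-identified (fractional after apportioning a sea-lion take by fin
    clip).  ``sealion_take`` is ``None`` for years before removals were
    recorded, which is distinct from an observed zero.
    """

    year: int
    stat_week: int
    n_drifts: int
    lower_ad: int = 0
    lower_ai: int = 0
    lower_unk: int = 0
    upriver_ad: int = 0
    upriver_ai: int = 0
    upriver_unk: int = 0
    novsi_ad: float = 0.0
    novsi_ai: float = 0.0
    sealion_take: Optional[int] = None
    total_chinook: Optional[float] = None
    month: str = ""
    day: str = ""

    def sampled(self, stock: str, clip: str) -> int:
        if stock not in STOCKS or clip not in CLIPS:
            raise KeyError((stock, clip))
        return getattr(self, f"{stock}_{clip.lower()}")

    def sampled_clip_total(self, clip: str) -> int:
        """VSI'd fish of one fin clip summed over both stocks."""
        return self.sampled("lower", clip) + self.sampled("upriver", clip)

    @property
    def sampled_total(self) -> int:
        return sum(self.sampled(s, c) for s in STOCKS for c in CLIPS)

    @property
    def novsi_total(self) -> float:
        return self.novsi_ad + self.novsi_ai

    def validate(self, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.n_drifts < 1:
            raise ValidationError(
                f"n_drifts must be >= 1, got {self.n_drifts}{where}")
        for name in ("lower_ad", "lower_ai", "lower_unk", "upriver_ad",
                     "upriver_ai", "upriver_unk", "novsi_ad", "novsi_ai"):
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(
                    f"negative count {name}={value}{where}")
        if self.sealion_take is not None and self.sealion_take < 0:
            raise ValidationError(
                f"negative sealion_take={self.sealion_take}{where}")
        if self.total_chinook is not None:
            accounted = self.sampled_total + self.novsi_total
            # printed totals are whole fish; components are 2-decimal
            if not math.isclose(accounted, self.total_chinook, abs_tol=0.011):
                raise ValidationError(
                    f"total_chinook={self.total_chinook} != "
                    f"sampled+noVSI={accounted:.2f}{where}")


# ---------------------------------------------------------------------------
# Individual fish
# ---------------------------------------------------------------------------


@dataclass
class FishSample:
    """One genotyped fish with VSI, fin clip, GSI and optional PBT labels."""

    sample_id: str
    year: int
    stat_week: int
    origin_site: str = "SCTF"  # SCTF | BON_AFF | ESTUARY
    fork_length_mm: float = 700.0
    vsi_stock: str = "none"  # lower | upriver | none
    fin_clip: str = "AD"
    genstock_obs: str = ""
    pbt_broodstock: Optional[str] = None
    genstock_exp: Optional[str] = None

    @property
    def is_adult(self) -> bool:
        return self.fork_length_mm > ADULT_FORK_LENGTH_MM

    @property
    def is_pbt_assigned(self) -> bool:
        return self.pbt_broodstock is not None

    @property
    def genstock(self) -> str:
        """Best available reporting group: PBT-informed when assigned."""
        return self.genstock_exp if self.genstock_exp else self.genstock_obs

    @property
    def category(self) -> str:
        """Origin category H / HNC / W from fin clip and PBT status."""
        if self.fin_clip == "AD":
            return "H"
        return "HNC" if self.is_pbt_assigned else "W"

    def validate(self, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.fin_clip not in CLIPS:
            raise ValidationError(f"unknown fin_clip {self.fin_clip!r}{where}")
        if self.vsi_stock not in ("lower", "upriver", "none"):
            raise ValidationError(
                f"unknown vsi_stock {self.vsi_stock!r}{where}")
        if self.fork_length_mm <= 0:
            raise ValidationError(
                f"fork_length_mm must be positive{where}")
        if (self.genstock_exp is None) != (self.pbt_broodstock is None):
            raise ValidationError(
                "genstock_exp must be set exactly when pbt_broodstock is set"
                f"{where}")


# ---------------------------------------------------------------------------
# Reporting-group catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenStockCatalog:
    """The reporting groups (GenStocks) and their lower/upriver split.

    ``lower_set`` and ``upriver_set`` are the groups managed within the
    spring period; ``spring_excluded`` are groups whose run timing does not
    typically overlap it.  Every code, excluded or not, still lies on one
    geographic side of Bonneville dam (``side``), which is what the
    VSI-vs-GSI concordance arithmetic uses.
    """

    codes: tuple
    lower_set: frozenset
    upriver_set: frozenset
    spring_excluded: frozenset
    excluded_side: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.lower_set & self.upriver_set:
            raise ValidationError("lower_set and upriver_set overlap")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def classify(self, code: str) -> str:
        """lower / upriver / excluded (spring-management classification)."""
        if code in self.spring_excluded:
            return "excluded"
        if code in self.lower_set:
            return "lower"
        if code in self.upriver_set:
            return "upriver"
        raise KeyError(f"unknown GenStock code {code!r}")

    def side(self, code: str) -> str:
        """Geographic side (lower/upriver) for every code, even excluded."""
        if code in self.lower_set:
            return "lower"
        if code in self.upriver_set:
            return "upriver"
        if code in self.spring_excluded:
            return self.excluded_side[code]
        raise KeyError(f"unknown GenStock code {code!r}")


DEFAULT_CATALOG = GenStockCatalog(
    codes=(
        "01_YOUNGS", "02_WCASSP", "03_WCASFA", "04_WILLAM", "05_SPCRTU",
        "06_KLICKR", "07_DESCSP", "08_JOHNDR", "09_YAKIMA", "10_UCOLSP",
        "11_TUCANO", "12_HELLSC", "13_SFSALM", "14_CHMBLN", "15_MFSALM",
        "16_UPSALM", "17_DESCFA", "18_UCOLSF", "19_SRFALL", "20_BONPOOLSP",
        "21_UMATILLASP",
    ),
    lower_set=frozenset({"01_YOUNGS", "02_WCASSP", "04_WILLAM"}),
    upriver_set=frozenset({
        "06_KLICKR", "07_DESCSP", "08_JOHNDR", "09_YAKIMA", "10_UCOLSP",
        "11_TUCANO", "12_HELLSC", "13_SFSALM", "14_CHMBLN", "15_MFSALM",
        "16_UPSALM", "18_UCOLSF", "20_BONPOOLSP", "21_UMATILLASP",
    }),
    spring_excluded=frozenset({
        "03_WCASFA", "05_SPCRTU", "17_DESCFA", "19_SRFALL",
    }),
    excluded_side={
        "03_WCASFA": "lower",      # west Cascades fall run, below Bonneville
        "05_SPCRTU": "upriver",    # Bonneville-pool tule fall run
        "17_DESCFA": "upriver",
        "19_SRFALL": "upriver",
    },
)


# ---------------------------------------------------------------------------
# Tag rates
# ---------------------------------------------------------------------------


class TagRateTable:
    """PBT tag rate per broodstock: the fraction of that broodstock's
    parents that were genotyped.  1/rate expands PBT-assigned counts to
    include untagged hatchery siblings."""

    def __init__(self, rates: Mapping[str, float]):
        for brood, rate in rates.items():
            if not (0.0 < rate <= 1.0):
                raise ValidationError(
                    f"tag rate for {brood!r} must be in (0, 1], got {rate}")
        self._rates = dict(rates)

    def __getitem__(self, broodstock: str) -> float:
        try:
            return self._rates[broodstock]
        except KeyError:
            raise ValidationError(
                f"no tag rate for broodstock {broodstock!r}") from None

    def __contains__(self, broodstock: str) -> bool:
        return broodstock in self._rates

    def __len__(self) -> int:
        return len(self._rates)

    def items(self):
        return self._rates.items()

    def require(self, broodstocks: Iterable[str]) -> None:
        missing = sorted({b for b in broodstocks if b not in self._rates})
        if missing:
            raise ValidationError(f"missing tag rates for {missing}")


# ---------------------------------------------------------------------------
# Dam counts, strata, travel
# ---------------------------------------------------------------------------


@dataclass
class DamCount:
    """Adult-sized Chinook passing a dam for one week or a pooled stratum.

    Weekly series use ``week_lo == week_hi``; pooled strata span a range.
    """

    year: int
    week_lo: int
    week_hi: int
    ad_count: float
    ai_count: float
    stratum: Optional[int] = None

    @classmethod
    def weekly(cls, year: int, week: int, ad: float, ai: float) -> "DamCount":
        return cls(year=year, week_lo=week, week_hi=week,
                   ad_count=ad, ai_count=ai)

    @property
    def is_weekly(self) -> bool:
        return self.week_lo == self.week_hi

    @property
    def total(self) -> float:
        return self.ad_count + self.ai_count

    def validate(self, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.week_lo > self.week_hi:
            raise ValidationError(f"week_lo > week_hi{where}")
        if self.ad_count < 0 or self.ai_count < 0:
            raise ValidationError(f"negative dam count{where}")


@dataclass
class StratumDef:
    """A contiguous block of statistical weeks pooled for composition."""

    year: int
    label: str
    week_lo: int
    week_hi: int
    deficient: bool = False  # set when sample-size guidelines could not be met

    def contains(self, week: int) -> bool:
        return self.week_lo <= week <= self.week_hi


@dataclass
class TravelRecord:
    """One PIT-tagged fish: estuary capture week and days until first
    detection at Bonneville dam."""

    year: int
    capture_week: int
    travel_days: float

    def validate(self, row: Optional[int] = None) -> None:
        if self.travel_days <= 0:
            where = f" (row {row})" if row is not None else ""
            raise ValidationError(f"travel_days must be positive{where}")


# ---------------------------------------------------------------------------
# Estimates
# ---------------------------------------------------------------------------


@dataclass
class CategoryEstimate:
    """Estimated total and CPUE for one (year, week, VSI stock, clip) cell."""

    year: int
    stat_week: int
    vsi_stock: str
    clip: str
    proportion: float
    est_total: float
    cpue: float


@dataclass
class CompositionEstimate:
    """Abundance of one composition cell with a bootstrap interval."""

    year: int
    stratum: str
    category: str                 # one of L-H ... U-W
    genstock: Optional[str]
    broodstock: Optional[str]
    value: float
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None
    units: str = "cpue"           # cpue | dam_count

    def __post_init__(self):
        if self.ci_lo is not None and self.ci_hi is not None:
            if not (self.ci_lo - 1e-9 <= self.value <= self.ci_hi + 1e-9):
                raise ValidationError(
                    "point estimate outside its confidence interval")


@dataclass
class ForecastRow:
    """State of the in-season regression after n weekly data points."""

    year: int
    n_points: int
    slope: float
    intercept: float
    r2: float
    predictions: tuple = ()
    pred_cumulative: Optional[float] = None
    observed: tuple = ()
    obs_cumulative: Optional[float] = None
    ape: Optional[float] = None
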