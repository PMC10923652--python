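"""Synthetic test-fishery scenarios with known ground truth.

The generator emulates the data-generating structure the analysis assumes:
a unimodal (Gaussian-shaped) weekly run curve per stock, a drift fishery
sampling the estuary cohort with Poisson catches at a fixed catchability,
visual stock calls flipped with stock-specific misclassification
probabilities, hatchery/natural structure through fin clips and PBT tag
rates, sea-lion removals thinned out of the catch before identification,
dam arrivals lagged by week-dependent travel times, and PIT travel records.
Every latent parameter is kept in a truth record so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .datamodel import (
    DamCount,
    DriftWeekRecord,
    FishSample,
    TagRateTable,
    TravelRecord,
)
from . import cpue as _cpue

__all__ = ["ScenarioConfig", "SimulatedBundle", "simulate_scenario",
           "sample_fish", "recover_parameters"]


def _default_genstock_weights() -> Dict[str, Dict[str, float]]:
    return {
        "upriver": {
            "12_HELLSC": 0.40, "10_UCOLSP": 0.15, "20_BONPOOLSP": 0.15,
            "16_UPSALM": 0.10, "09_YAKIMA": 0.10, "07_DESCSP": 0.10,
        },
        "lower": {"04_WILLAM": 0.75, "02_WCASSP": 0.25},
    }


def _default_broodstock_weights() -> Dict[str, Dict[str, float]]:
    weights: Dict[str, Dict[str, float]] = {}
    for stock_weights in _default_genstock_weights().values():
        for code in stock_weights:
            weights[code] = {f"{code}-BYA": 0.6, f"{code}-BYB": 0.4}
    return weights


def _default_tag_rates() -> Dict[str, float]:
    rates = {}
    for code, broods in _default_broodstock_weights().items():
        for i, brood in enumerate(broods):
            rates[brood] = (0.85, 0.60)[i % 2]
    return rates


@dataclass
class ScenarioConfig:
    """Knobs of the generator; the defaults are the study conditions.

    Run sizes are the recent-decade averages; the dam-count peak sits at
    week 19 with the fishery's CPUE peak two travel-weeks earlier; VSI
    misclassification matches the pooled VSI/GSI discordance (11.4% upriver,
    26.4% lower); travel means fall linearly from 44 to 12.5 days over
    weeks 13-19; and PBT tag rates span the published [0.18, 1.0] range.
    ``catchability`` is the expected CPUE (fish per drift) per 1000 fish of
    the weekly estuary cohort.
    """

    seed: int = 0
    n_years: int = 1
    first_year: int = 2018
    weeks: Tuple[int, int] = (12, 25)
    run_size_upriver: float = 150485.0
    run_size_lower: float = 77442.0
    peak_week_dam: float = 19.0
    run_spread_weeks: float = 2.0
    bimodal: bool = False
    travel_mean_endpoints: Tuple[float, float] = (44.0, 12.5)
    travel_mean_weeks: Tuple[int, int] = (13, 19)
    travel_cv: float = 0.25
    catchability: float = 0.20
    vsi_discordance: Mapping[str, float] = field(
        default_factory=lambda: {"upriver": 0.114, "lower": 0.264})
    clip_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"lower": 0.85, "upriver": 0.83})
    hnc_fraction: float = 0.30   # of AI fish, share that is untagged hatchery
    genstock_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_genstock_weights)
    broodstock_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_broodstock_weights)
    tag_rates: Mapping[str, float] = field(default_factory=_default_tag_rates)
    sealion_rate: float = 0.30
    drifts_per_week: int = 15
    travel_tags_per_week: int = 30

    def validate(self) -> None:
        from .datamodel import ValidationError

        for stock, weights in self.genstock_weights.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"genstock weights for {stock!r} do not sum to 1")
        for code, weights in self.broodstock_weights.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"broodstock weights for {code!r} do not sum to 1")
        for name in ("sealion_rate", "hnc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for stock, p in self.vsi_discordance.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"vsi_discordance[{stock!r}] not in [0,1]")
        for brood, rate in self.tag_rates.items():
            if not 0.0 < rate <= 1.0:
                raise ValidationError(f"tag rate for {brood!r} not in (0, 1]")

    def travel_mean(self, week: int) -> float:
        """Mean travel days for fish entering in a given week (linear
        decrease, clamped at the endpoint weeks)."""
        w0, w1 = self.travel_mean_weeks
        d0, d1 = self.travel_mean_endpoints
        t = min(max((week - w0) / (w1 - w0), 0.0), 1.0)
        return d0 + t * (d1 - d0)


@dataclass
class SimulatedBundle:
    """One synthetic study dataset plus its generating truth."""

    config: ScenarioConfig
    drift_records: List[DriftWeekRecord]
    samples: List[FishSample]
    dam_counts: List[DamCount]
    travel_records: List[TravelRecord]
    tag_rates: TagRateTable
    truth: Dict


def _run_curve(config: ScenarioConfig, weeks: np.ndarray,
               peak: float) -> np.ndarray:
    """Weekly arrival proportions; Gaussian by default, optional bimodal
    variant to stress-test initial-peak detection."""
    main = np.exp(-0.5 * ((weeks - peak) / config.run_spread_weeks) ** 2)
    if config.bimodal:
        main = main + 0.7 * np.exp(
            -0.5 * ((weeks - peak - 3.0) / config.run_spread_weeks) ** 2)
    return main / main.sum()


def sample_fish(
    config: ScenarioConfig,
    n: int,
    stock: str,
    year: int,
    week: int,
    rng: np.random.Generator,
    origin_site: str = "SCTF",
    id_prefix: str = "SIM",
) -> List[FishSample]:
    """Draw n fish of one true stock with clip, GenStock, broodstock, PBT
    and (possibly misclassified) VSI labels."""
    gen_codes = list(config.genstock_weights[stock])
    gen_p = np.array([config.genstock_weights[stock][c] for c in gen_codes])
    flips = rng.random(n) < config.vsi_discordance[stock]
    clips = rng.random(n) < config.clip_fraction[stock]
    gens = rng.choice(len(gen_codes), size=n, p=gen_p / gen_p.sum())
    out: List[FishSample] = []
    other = "lower" if stock == "upriver" else "upriver"
    for i in range(n):
        code = gen_codes[gens[i]]
        clip = "AD" if clips[i] else "AI"
        hatchery = clip == "AD" or rng.random() < config.hnc_fraction
        brood = None
        if hatchery:
            broods = list(config.broodstock_weights[code])
            bp = np.array([config.broodstock_weights[code][b] for b in broods])
            candidate = broods[rng.choice(len(broods), p=bp / bp.sum())]
            if rng.random() < config.tag_rates[candidate]:
                brood = candidate
        out.append(FishSample(
            sample_id=f"{id_prefix}-{year}-{week}-{stock[:3]}-{i:05d}",
            year=year, stat_week=week, origin_site=origin_site,
            fork_length_mm=float(rng.normal(750.0, 60.0)),
            vsi_stock=other if flips[i] else stock,
            fin_clip=clip, genstock_obs=code,
            pbt_broodstock=brood, genstock_exp=code if brood else None,
        ))
    return out


def simulate_scenario(config: ScenarioConfig) -> SimulatedBundle:
    """Generate a full synthetic dataset bundle (catch table, fish samples,
    weekly dam counts, travel records, tag rates, truth record)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    week_lo, week_hi = config.weeks
    weeks = np.arange(week_lo, week_hi + 1)

    drift_records: List[DriftWeekRecord] = []
    samples: List[FishSample] = []
    travel_records: List[TravelRecord] = []
    dam_ad: Dict[Tuple[int, int], float] = {}
    dam_ai: Dict[Tuple[int, int], float] = {}
    truth_years = {}

    for y in range(config.n_years):
        year = config.first_year + y
        cohorts = {}
        for stock, run_size in (("upriver", config.run_size_upriver),
                                ("lower", config.run_size_lower)):
            # estuary timing = dam timing shifted back by the travel weeks
            shift = round(config.travel_mean(int(config.peak_week_dam)) / 7)
            curve = _run_curve(config, weeks,
                               config.peak_week_dam - shift)
            cohorts[stock] = run_size * curve

        # upriver fish arrive at the dam after their weekly travel time
        for wi, week in enumerate(weeks):
            cohort = cohorts["upriver"][wi]
            mean_days = config.travel_mean(int(week))
            offsets = np.arange(0, 9)
            if config.travel_cv <= 0:
                # noiseless: every fish takes exactly mean_days; week offset
                # is integer division of days by 7
                probs = np.zeros(len(offsets))
                probs[min(int(mean_days // 7), len(offsets) - 1)] = 1.0
            else:
                sigma = np.sqrt(np.log(1 + config.travel_cv ** 2))
                mu = np.log(mean_days) - sigma ** 2 / 2
                edges = np.concatenate([offsets * 7.0, [1e9]])
                from scipy.stats import lognorm
                cdf = lognorm.cdf(edges, s=sigma, scale=np.exp(mu))
                probs = np.diff(cdf)
                probs = probs / probs.sum()
            arrivals = rng.multinomial(int(round(cohort)), probs)
            for off, count in zip(offsets, arrivals):
                if count == 0:
                    continue
                wk = int(week + off)
                key = (year, wk)
                ad = rng.binomial(count, config.clip_fraction["upriver"])
                dam_ad[key] = dam_ad.get(key, 0.0) + ad
                dam_ai[key] = dam_ai.get(key, 0.0) + (count - ad)

        for wi, week in enumerate(weeks):
            week = int(week)
            caught: List[FishSample] = []
            for stock in ("upriver", "lower"):
                lam = (config.catchability * cohorts[stock][wi] / 1000.0
                       * config.drifts_per_week)
                n_caught = int(rng.poisson(lam))
                caught.extend(sample_fish(
                    config, n_caught, stock, year, week, rng))
            # sea lions remove fish from the net before any identification
            take = int(rng.binomial(len(caught), config.sealion_rate))
            rng.shuffle(caught)
            kept = caught[take:]
            samples.extend(kept)
            counts = {(s, c): 0 for s in ("lower", "upriver")
                      for c in ("AD", "AI")}
            for f in kept:
                counts[(f.vsi_stock, f.fin_clip)] += 1
            rec = DriftWeekRecord(
                year=year, stat_week=week, n_drifts=config.drifts_per_week,
                lower_ad=counts[("lower", "AD")],
                lower_ai=counts[("lower", "AI")],
                upriver_ad=counts[("upriver", "AD")],
                upriver_ai=counts[("upriver", "AI")],
                sealion_take=take,
            )
            if take > 0 and rec.sampled_total > 0:
                rec.novsi_ad, rec.novsi_ai = _cpue.apportion_sealion_by_clip(rec)
            elif take > 0:
                rec.novsi_ad = float(take)  # no biodata: default to AD
            rec.total_chinook = rec.sampled_total + rec.novsi_total
            drift_records.append(rec)

            # PIT-tagged estuary fish of the upriver stock
            if cohorts["upriver"][wi] > 0:
                n_tags = min(config.travel_tags_per_week,
                             int(round(cohorts["upriver"][wi] / 100)))
                mean_days = config.travel_mean(week)
                sigma = np.sqrt(np.log(1 + config.travel_cv ** 2))
                mu = np.log(mean_days) - sigma ** 2 / 2
                for d in rng.lognormal(mu, sigma, size=n_tags):
                    travel_records.append(TravelRecord(
                        year=year, capture_week=week, travel_days=float(d)))

        truth_years[year] = {
            "cpue_expected": {
                stock: {int(w): config.catchability * cohorts[stock][i] / 1000.0
                        for i, w in enumerate(weeks)}
                for stock in ("lower", "upriver")
            },
        }

    dam_counts = [
        DamCount.weekly(year, week, dam_ad.get((year, week), 0.0),
                        dam_ai.get((year, week), 0.0))
        for (year, week) in sorted(set(dam_ad) | set(dam_ai))
    ]

    truth = {
        "genstock_weights": {k: dict(v)
                             for k, v in config.genstock_weights.items()},
        "clip_fraction": dict(config.clip_fraction),
        "vsi_discordance": dict(config.vsi_discordance),
        "catchability": config.catchability,
        "run_size": {"upriver": config.run_size_upriver,
                     "lower": config.run_size_lower},
        "lag_weeks": round(config.travel_mean(int(config.peak_week_dam)) / 7),
        "per_year": truth_years,
    }
    return SimulatedBundle(
        config=config, drift_records=drift_records, samples=samples,
        dam_counts=dam_counts, travel_records=travel_records,
        tag_rates=TagRateTable(dict(config.tag_rates)), truth=truth)


def recover_parameters(bundle: SimulatedBundle) -> Dict:
    """Run the full pipeline on a simulated bundle and compare against truth.

    Reports estimated vs. true GenStock proportions (upriver stock), VSI/GSI
    concordance vs. 1 - discordance, the selected lag vs. the generating
    travel shift, and the lagged-regression slope.
    """
    import pandas as pd

    from . import composition as comp
    from . import concordance as conc
    from . import forecasting as fore
    from . import travel as trav

    config = bundle.config
    table = _cpue.estimate_table(bundle.drift_records)

    report: Dict = {"years": {}}
    dam = pd.DataFrame([{"year": d.year, "week": d.week_lo,
                         "total": d.total} for d in bundle.dam_counts])
    for year in sorted({r.year for r in bundle.drift_records}):
        sub = table[table["year"] == year]
        cpue_up = pd.Series(sub["upriver_total_cpue"].to_numpy(),
                            index=sub["stat_week"].to_numpy())
        dam_y = dam[dam["year"] == year]
        dam_total = pd.Series(dam_y["total"].to_numpy(),
                              index=dam_y["week"].to_numpy())

        year_samples = [s for s in bundle.samples if s.year == year]
        strata = comp.build_strata(year_samples)
        comps = comp.estimate_composition_cpue(
            year_samples, bundle.tag_rates, sub, strata)
        est = pd.concat([c.by_genstock(vsi_stock="upriver") for c in comps])
        est = est.groupby(level=0).sum()
        est_prop = (est / est.sum()).to_dict() if est.sum() else {}

        lag = trav.select_lag(cpue_up, dam_total)
        reg = fore.lagged_regression(cpue_up, dam_total, lag)
        report["years"][year] = {
            "genstock_prop_est": est_prop,
            "lag_est": lag,
            "slope_est": reg.slope,
            "r2": reg.r2,
        }

    concord = conc.concordance_table(bundle.samples)
    pooled = concord[concord["year"] == "pooled"].iloc[0]
    report["concordance_est"] = {
        "lower": float(pooled["lower_pct"]),
        "upriver": float(pooled["upriver_pct"]),
    }
    report["concordance_truth"] = {
        stock: 100.0 * (1.0 - config.vsi_discordance[stock])
        for stock in ("lower", "upriver")
    }
    report["genstock_prop_truth"] = dict(
        bundle.truth["genstock_weights"]["upriver"])
    report["lag_truth"] = bundle.truth["lag_weeks"]
    return report
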