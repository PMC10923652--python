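"""Stratification, tag-rate-balanced expansion and the stratified bootstrap."""

import itertools
import math
import warnings
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_fish
from rivercast import composition as comp
from rivercast import cpue as rcpue
from rivercast import fixtures
from rivercast.datamodel import (
    DamCount,
    StratumDef,
    TagRateTable,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def fish_for_weeks(week_counts):
    """week_counts: {week: (lower_ad, lower_ai, upriver_ad, upriver_ai)}."""
    out, i = [], 0
    for week, (lad, lai, uad, uai) in week_counts.items():
        for vsi, clip, n in (("lower", "AD", lad), ("lower", "AI", lai),
                             ("upriver", "AD", uad), ("upriver", "AI", uai)):
            for _ in range(n):
                out.append(make_fish(i, week=week, vsi=vsi, clip=clip))
                i += 1
    return out


def brute_force_max_strata(week_counts, min_vsi=20, min_ai=2):
    """Enumerate all contiguous partitions of the week sequence and return
    the maximum number of blocks for which every block meets the minima."""
    weeks = sorted(week_counts)

    def ok(block):
        lad = sum(week_counts[w][0] for w in block)
        lai = sum(week_counts[w][1] for w in block)
        uad = sum(week_counts[w][2] for w in block)
        uai = sum(week_counts[w][3] for w in block)
        return (lad + lai >= min_vsi and uad + uai >= min_vsi
                and lai >= min_ai and uai >= min_ai)

    best = 0
    n = len(weeks)
    for cuts in itertools.chain.from_iterable(
            itertools.combinations(range(1, n), k) for k in range(n)):
        bounds = [0, *cuts, n]
        blocks = [weeks[a:b] for a, b in zip(bounds, bounds[1:])]
        if all(ok(b) for b in blocks):
            best = max(best, len(blocks))
    return best


class TestBuildStrata:
    @pytest.mark.parametrize("week_counts", [
        # weekly counts consistent with the published 2017 split (12-13 | 14-15)
        {12: (12, 2, 17, 2), 13: (10, 1, 17, 2),
         14: (12, 4, 43, 5), 15: (12, 4, 42, 4)},
        # a fat early week followed by lean ones
        {12: (30, 4, 30, 4), 13: (2, 1, 2, 1), 14: (30, 3, 30, 3)},
        # nothing mergeable until the very end
        {12: (5, 1, 5, 1), 13: (5, 1, 5, 1), 14: (20, 2, 20, 2)},
    ])
    def test_greedy_matches_brute_force_maximum(self, week_counts):
        samples = fish_for_weeks(week_counts)
        strata = comp.build_strata(samples)
        assert len(strata) == brute_force_max_strata(week_counts)
        # strata are contiguous and cover the sampled weeks
        weeks = sorted(week_counts)
        assert strata[0].week_lo == weeks[0]
        assert strata[-1].week_hi == weeks[-1]
        for a, b in zip(strata, strata[1:]):
            assert b.week_lo == a.week_hi + 1

    def test_each_week_sufficient_gives_one_stratum_per_week(self):
        week_counts = {w: (20, 2, 20, 2) for w in range(12, 16)}
        strata = comp.build_strata(fish_for_weeks(week_counts))
        assert len(strata) == 4

    def test_published_strata_satisfy_the_guidelines(self):
        df = fixtures.fixture("table3")
        assert (df["lower_total"] >= 20).all()
        assert (df["upriver_total"] >= 20).all()
        assert (df["lower_ai"] >= 2).all()
        assert (df["upriver_ai"] >= 2).all()

    def test_infeasible_year_collapses_to_deficient_stratum(self):
        samples = fish_for_weeks({12: (3, 1, 3, 1), 13: (2, 0, 2, 1)})
        with pytest.warns(UserWarning, match="minima"):
            strata = comp.build_strata(samples)
        assert len(strata) == 1 and strata[0].deficient

    def test_mixed_years_rejected(self):
        samples = [make_fish(0, year=2020), make_fish(1, year=2021)]
        with pytest.raises(ValidationError, match="years"):
            comp.build_strata(samples)


# ---------------------------------------------------------------------------
# spibetr balancing
# ---------------------------------------------------------------------------


def brute_force_expand(samples, tag_rates):
    """Independent one-fish-at-a-time enumeration of the balancing rule.

    Walks every PBT-assigned fish individually: each contributes
    1/rate - 1 surplus, drawn from the unassigned fish of its expected
    reporting group one equal share at a time (equivalently: proportional
    subtraction), clamping when the pool is exhausted.  Returns expanded
    counts keyed like the cells of the vectorised path.
    """
    out = {}
    for key in {(s.vsi_stock, s.fin_clip) for s in samples}:
        members = [s for s in samples if (s.vsi_stock, s.fin_clip) == key]
        vsi, clip = key
        pools = Counter(s.genstock_obs for s in members
                        if not s.is_pbt_assigned)
        pools = {g: float(n) for g, n in pools.items()}
        demands = {}
        for s in members:
            if s.is_pbt_assigned:
                extra = 1.0 / tag_rates[s.pbt_broodstock] - 1.0
                demands.setdefault(s.genstock_exp, []).append(
                    (s.pbt_broodstock, extra))
        expanded = Counter()
        for s in members:
            if s.is_pbt_assigned:
                expanded[(s.pbt_broodstock, s.genstock_exp)] += 1.0
        for g, wants in demands.items():
            avail = pools.get(g, 0.0)
            total_want = sum(w for _, w in wants)
            if total_want <= 0:
                continue
            granted = min(total_want, avail)
            for brood, want in wants:
                expanded[(brood, g)] += granted * want / total_want
            pools[g] = avail - granted
        for (brood, g), n in expanded.items():
            cat = "H" if clip == "AD" else "HNC"
            out[(vsi, clip, cat, g, brood)] = n
        for g, n in pools.items():
            if n > 1e-12:
                cat = "H" if clip == "AD" else "W"
                out[(vsi, clip, cat, g, None)] = n
    return out


def cells_dict(composition):
    return {
        (r.vsi_stock, r.clip, r.category, r.genstock,
         r.broodstock if r.broodstock is not None else None): r.count
        for r in composition.cells.itertuples()
    }


class TestSpibetrExpand:
    def test_full_tag_rates_reproduce_raw_proportions(self):
        rates = TagRateTable({"B1": 1.0})
        samples = ([make_fish(i, genstock="12_HELLSC", brood="B1")
                    for i in range(4)]
                   + [make_fish(10 + i, genstock="13_SFSALM")
                      for i in range(6)])
        result = comp.spibetr_expand(samples, rates,
                                     {("upriver", "AI"): 1.0})
        by_gen = result.by_genstock()
        assert math.isclose(by_gen["12_HELLSC"], 0.4)
        assert math.isclose(by_gen["13_SFSALM"], 0.6)

    def test_hand_enumerated_balancing(self):
        # 4 fish at rate 0.5 expand to 8; 2 of the 6 matching unassigned remain
        rates = TagRateTable({"B1": 0.5})
        samples = ([make_fish(i, brood="B1") for i in range(4)]
                   + [make_fish(10 + i) for i in range(6)])
        result = comp.spibetr_expand(samples, rates,
                                     {("upriver", "AI"): 10.0})
        cells = cells_dict(result)
        assert math.isclose(
            cells[("upriver", "AI", "HNC", "12_HELLSC", "B1")], 8.0)
        assert math.isclose(
            cells[("upriver", "AI", "W", "12_HELLSC", None)], 2.0)
        assert math.isclose(result.total("upriver", "AI"), 10.0)

    def test_clamping_conserves_the_cell_total(self):
        # rate 0.2 demands 16 extra but only 6 unassigned exist
        rates = TagRateTable({"B1": 0.2})
        samples = ([make_fish(i, brood="B1") for i in range(4)]
                   + [make_fish(10 + i) for i in range(6)])
        with pytest.warns(UserWarning, match="clamped"):
            result = comp.spibetr_expand(samples, rates,
                                         {("upriver", "AI"): 10.0})
        cells = cells_dict(result)
        assert math.isclose(
            cells[("upriver", "AI", "HNC", "12_HELLSC", "B1")], 10.0)
        assert ("upriver", "AI", "W", "12_HELLSC", None) not in cells
        assert math.isclose(result.total("upriver", "AI"), 10.0)
        assert result.warnings

    def test_missing_tag_rate_names_the_broodstock(self):
        samples = [make_fish(0, brood="MYSTERY")]
        with pytest.raises(ValidationError, match="MYSTERY"):
            comp.spibetr_expand(samples, TagRateTable({"B1": 0.5}),
                                {("upriver", "AI"): 1.0})

    def test_abundance_without_samples_is_an_error(self):
        with pytest.raises(ValidationError, match="no samples"):
            comp.spibetr_expand([make_fish(0, clip="AD")],
                                TagRateTable({}),
                                {("upriver", "AI"): 2.0})

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_and_conserves(self, data):
        genstocks = ["12_HELLSC", "13_SFSALM", "16_UPSALM"]
        broods = {"BA": "12_HELLSC", "BB": "12_HELLSC", "BC": "13_SFSALM"}
        rates = TagRateTable({
            b: data.draw(st.floats(min_value=0.18, max_value=1.0),
                         label=f"rate {b}")
            for b in broods
        })
        n = data.draw(st.integers(min_value=1, max_value=6), label="n")
        samples = []
        for i in range(n):
            clip = data.draw(st.sampled_from(["AD", "AI"]), label=f"clip{i}")
            if data.draw(st.booleans(), label=f"pbt{i}"):
                brood = data.draw(st.sampled_from(sorted(broods)),
                                  label=f"brood{i}")
                samples.append(make_fish(i, clip=clip, brood=brood,
                                         genstock=broods[brood]))
            else:
                samples.append(make_fish(
                    i, clip=clip,
                    genstock=data.draw(st.sampled_from(genstocks),
                                       label=f"gen{i}")))
        abundance = {key: float(sum(
            1 for s in samples if (s.vsi_stock, s.fin_clip) == key))
            for key in {(s.vsi_stock, s.fin_clip) for s in samples}}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = comp.spibetr_expand(samples, rates, abundance)
        expected = brute_force_expand(samples, rates)
        got = cells_dict(result)
        assert set(got) == set(expected)
        for cell, value in expected.items():
            assert math.isclose(got[cell], value, abs_tol=1e-9), cell
        # conservation: every group's cells sum to its abundance
        for (vsi, clip), abund in abundance.items():
            assert math.isclose(result.total(vsi, clip), abund, abs_tol=1e-9)

    def test_lower_tag_rate_monotonicity(self):
        samples = ([make_fish(i, brood="B1") for i in range(3)]
                   + [make_fish(10 + i) for i in range(8)])
        hnc, wild = [], []
        for rate in (1.0, 0.8, 0.6, 0.5):
            cells = cells_dict(comp.spibetr_expand(
                samples, TagRateTable({"B1": rate}),
                {("upriver", "AI"): 11.0}))
            hnc.append(cells[("upriver", "AI", "HNC", "12_HELLSC", "B1")])
            wild.append(cells.get(("upriver", "AI", "W", "12_HELLSC", None),
                                  0.0))
        assert all(b >= a - 1e-12 for a, b in zip(hnc, hnc[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(wild, wild[1:]))


# ---------------------------------------------------------------------------
# Stratified estimators
# ---------------------------------------------------------------------------


def cpue_frame(rows):
    import pandas as pd

    cols = {}
    for stock in ("lower", "upriver"):
        for clip in ("ad", "ai"):
            cols[f"{stock}_{clip}_cpue"] = 0.0
    return pd.DataFrame([{**cols, **r} for r in rows])


class TestCompositionCpue:
    def test_single_genstock_takes_all_cpue(self):
        samples = [make_fish(i, clip="AD", genstock="12_HELLSC")
                   for i in range(5)]
        strata = [StratumDef(year=2020, label="1", week_lo=15, week_hi=15)]
        table = cpue_frame([{"year": 2020, "stat_week": 15,
                             "upriver_ad_cpue": 4.0}])
        (result,) = comp.estimate_composition_cpue(
            samples, TagRateTable({}), table, strata)
        assert math.isclose(result.by_genstock()["12_HELLSC"], 4.0)

    def test_even_split_halves_the_cpue(self):
        samples = ([make_fish(i, clip="AD", genstock="12_HELLSC")
                    for i in range(3)]
                   + [make_fish(10 + i, clip="AD", genstock="13_SFSALM")
                      for i in range(3)])
        strata = [StratumDef(year=2020, label="1", week_lo=15, week_hi=15)]
        table = cpue_frame([{"year": 2020, "stat_week": 15,
                             "upriver_ad_cpue": 4.0}])
        (result,) = comp.estimate_composition_cpue(
            samples, TagRateTable({}), table, strata)
        assert math.isclose(result.by_genstock()["12_HELLSC"], 2.0)
        assert math.isclose(result.by_genstock()["13_SFSALM"], 2.0)

    def test_genstock_sums_conserve_the_stock_cpue(self, table5_sample_list):
        samples = [s for s in table5_sample_list if s.year == 2017]
        strata = [StratumDef(year=2017, label="1", week_lo=12, week_hi=18)]
        table = cpue_frame([{
            "year": 2017, "stat_week": 15, "upriver_ad_cpue": 3.2,
            "upriver_ai_cpue": 0.5, "lower_ad_cpue": 1.1,
            "lower_ai_cpue": 0.3,
        }])
        rates = TagRateTable({s.pbt_broodstock: 1.0
                              for s in samples if s.pbt_broodstock})
        (result,) = comp.estimate_composition_cpue(samples, rates, table,
                                                   strata)
        up = result.by_genstock(vsi_stock="upriver").sum()
        assert math.isclose(up, 3.7, abs_tol=1e-9)
        assert math.isclose(result.cells["value"].sum(), 5.1, abs_tol=1e-9)

    def test_uncovered_week_with_cpue_is_an_error(self):
        samples = [make_fish(i, clip="AD") for i in range(5)]
        strata = [StratumDef(year=2020, label="1", week_lo=15, week_hi=15)]
        table = cpue_frame([
            {"year": 2020, "stat_week": 15, "upriver_ad_cpue": 1.0},
            {"year": 2020, "stat_week": 16, "upriver_ad_cpue": 2.0},
        ])
        with pytest.raises(ValidationError, match="no covering stratum"):
            comp.estimate_composition_cpue(samples, TagRateTable({}),
                                           table, strata)


class TestDamComposition:
    def dam(self, ad, ai, week_lo=12, week_hi=20):
        return [DamCount(year=2020, week_lo=week_lo, week_hi=week_hi,
                         ad_count=ad, ai_count=ai, stratum=1)]

    def test_pure_stratum_receives_the_whole_count(self):
        samples = [make_fish(i, vsi="none", clip="AD", genstock="12_HELLSC")
                   for i in range(100)]
        (result,) = comp.estimate_dam_composition(
            samples, TagRateTable({}), self.dam(5000, 0))
        assert math.isclose(result.by_genstock()["12_HELLSC"], 5000.0)
        assert result.by_category().to_dict() == {"H": 5000.0}

    def test_half_assigned_at_full_rate_gives_half_hnc(self):
        samples = ([make_fish(i, vsi="none", clip="AI", brood="B1")
                    for i in range(50)]
                   + [make_fish(100 + i, vsi="none", clip="AI")
                      for i in range(50)])
        (result,) = comp.estimate_dam_composition(
            samples, TagRateTable({"B1": 1.0}), self.dam(0, 8000))
        by_cat = result.by_category()
        assert math.isclose(by_cat["HNC"], 4000.0)
        assert math.isclose(by_cat["W"], 4000.0)

    def test_published_dam_table_proportions_reproduce_subtotals(self):
        """Samples matching the published 2018 dam composition proportions
        reproduce the printed AI natural-origin subtotal (16,902) when fed
        the matching AD/AI abundance."""
        df = fixtures.fixture("table6")
        sub = df[df["year"] == 2018]
        samples, i = [], 0
        for row in sub.itertuples():
            # one fish per 25 estimated -> integer-ish counts, same shares
            n = int(round(row.abundance / 25))
            for _ in range(n):
                clip = "AD" if row.category == "H" else "AI"
                brood = f"{row.genstock}-B" if row.category == "HNC" else None
                samples.append(make_fish(i, vsi="none", clip=clip,
                                         genstock=row.genstock, brood=brood))
                i += 1
        rates = TagRateTable({s.pbt_broodstock: 1.0
                              for s in samples if s.pbt_broodstock})
        ad_total = float(sub[sub["category"] == "H"]["abundance"].sum())
        ai_total = float(
            sub[sub["category"].isin(["HNC", "W"])]["abundance"].sum())
        (result,) = comp.estimate_dam_composition(
            samples, rates, self.dam(ad_total, ai_total))
        upriver_codes = {c for c in sub["genstock"]
                         if not c.startswith(("01", "02", "03", "04"))}
        w_cells = result.cells[
            (result.cells["category"] == "W")
            & result.cells["genstock"].isin(upriver_codes)]
        assert abs(w_cells["value"].sum() - 16902) < 90  # 0.5% of printed


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def proportion_estimator(samples):
    n = len(samples)
    k = sum(1 for s in samples if s.genstock_obs == "12_HELLSC")
    return {"p": k / n if n else 0.0}


class TestBootstrap:
    def test_homogeneous_stratum_has_zero_width(self):
        samples = [make_fish(i) for i in range(20)]
        ci = comp.bootstrap_ci(proportion_estimator, samples, B=50, seed=1)
        assert ci["p"] == (1.0, 1.0)

    def test_single_replicate_degenerates_to_that_replicate(self):
        samples = [make_fish(i) for i in range(10)]
        ci = comp.bootstrap_ci(proportion_estimator, samples, B=1, seed=0)
        lo, hi = ci["p"]
        assert lo == hi == 1.0

    def test_deterministic_given_seed(self):
        samples = ([make_fish(i) for i in range(25)]
                   + [make_fish(100 + i, genstock="13_SFSALM")
                      for i in range(25)])
        a = comp.bootstrap_ci(proportion_estimator, samples, B=200, seed=7)
        b = comp.bootstrap_ci(proportion_estimator, samples, B=200, seed=7)
        assert a == b

    def test_matches_exact_binomial_percentiles(self):
        """A 50/50 cell resampled within one group is Binomial(50, 0.5)/50;
        the percentile CI must sit on the closed-form binomial quantiles."""
        from scipy.stats import binom

        samples = ([make_fish(i) for i in range(25)]
                   + [make_fish(100 + i, genstock="13_SFSALM")
                      for i in range(25)])
        ci = comp.bootstrap_ci(proportion_estimator, samples, B=1000, seed=3)
        lo, hi = ci["p"]
        assert abs(lo - binom.ppf(0.05, 50, 0.5) / 50) <= 0.03
        assert abs(hi - binom.ppf(0.95, 50, 0.5) / 50) <= 0.03

    def test_spibetr_point_inside_its_interval(self):
        rates = TagRateTable({"B1": 0.5})
        samples = ([make_fish(i, brood="B1") for i in range(8)]
                   + [make_fish(100 + i) for i in range(12)]
                   + [make_fish(200 + i, genstock="13_SFSALM")
                      for i in range(10)])
        abundance = {("upriver", "AI"): 30.0}
        point = comp.spibetr_expand(samples, rates, abundance)
        series = point.cell_series()

        def estimator(ss):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return comp.spibetr_expand(ss, rates,
                                           abundance).cell_series().to_dict()

        ci = comp.bootstrap_ci(estimator, samples, B=300, seed=11)
        for cell, value in series.items():
            lo, hi = ci[cell]
            assert lo - 1e-9 <= value <= hi + 1e-9
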