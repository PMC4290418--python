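import dendropy
import numpy as np
import pandas as pd
import pytest

from adepd.prioritize import (
    adepd_cost,
    compare_rankings,
    current_spending_projection,
    greedy_complementarity_ranking,
    load_cohort,
    optimal_spending_curve,
    price_of_pd,
)
from adepd.scores import score_table
from adepd.tree import PhyloTree, TreeSet
from helpers import exhaustive_greedy, random_statuses, random_tree


def tree_from_newick(s: str) -> PhyloTree:
    return PhyloTree.from_dendropy(dendropy.Tree.get(data=s, schema="newick"))


def make_cohort(rows):
    return pd.DataFrame(
        [dict(iucn_category=c, cost_usd=cost, expenditure_usd=e) for _, c, cost, e in rows],
        index=pd.Index([r[0] for r in rows], name="species"),
    )


class TestAdepdCost:
    def test_unit_conversion(self, fixture_bundle, iucn50):
        ts, statuses, cohort, _ = fixture_bundle
        tab = score_table(ts, statuses, iucn50, species=list(cohort.index))
        tab.loc["B", "ADEPD_mean"] = 1.0
        cohort.loc["B", "cost_usd"] = 1_000_000.0
        s = adepd_cost(tab, cohort)
        assert s["B"] == pytest.approx(1e-6)  # 1 Myr per $1M = 1e-6 Myr/$
        assert adepd_cost(tab, cohort, per_year=True)["B"] == pytest.approx(1.0)

    def test_cost_scale_invariance_of_ranking(self, fixture_bundle, iucn50):
        ts, statuses, cohort, _ = fixture_bundle
        tab = score_table(ts, statuses, iucn50, species=list(cohort.index))
        base = adepd_cost(tab, cohort)
        doubled = cohort.copy()
        doubled["cost_usd"] *= 2
        halved = adepd_cost(tab, doubled)
        assert np.allclose(halved, base / 2)
        assert list(halved.sort_values().index) == list(base.sort_values().index)

    def test_nonpositive_cost_names_species(self, fixture_bundle, iucn50):
        ts, statuses, cohort, _ = fixture_bundle
        tab = score_table(ts, statuses, iucn50, species=list(cohort.index))
        cohort.loc["D", "cost_usd"] = 0.0
        with pytest.raises(ValueError, match="D"):
            adepd_cost(tab, cohort)


class TestGreedyComplementarity:
    def test_unrelated_tips_match_static_order(self, iucn50):
        # cohort tips in disjoint subtrees share no edges: greedy == static
        tree = tree_from_newick("((A:1,B:9):1,(C:1,D:9):1);")
        ts = TreeSet([tree])
        statuses = {"A": "CR", "B": "LC", "C": "EN", "D": "LC"}
        cohort = make_cohort([("A", "CR", 1e6, 0.0), ("C", "EN", 1e6, 0.0)])
        g = greedy_complementarity_ranking(ts, statuses, iucn50, cohort)
        tab = score_table(ts, statuses, iucn50, species=["A", "C"])
        static = adepd_cost(tab, cohort)
        assert list(g.index) == list(static.sort_values(ascending=False).index)
        assert np.allclose(g["greedy_score_mean"], static.loc[g.index])

    def test_sister_pair_complementarity_shifts_second_score(self, iucn50):
        # two CR sisters on a long shared stem: once one is downlisted the
        # stem is safer, so the second's greedy score < its static score
        tree = tree_from_newick("((A:1,B:1):10,(C:1,D:1):10);")
        ts = TreeSet([tree])
        statuses = {"A": "CR", "B": "CR", "C": "LC", "D": "LC"}
        cohort = make_cohort([("A", "CR", 1e6, 0.0), ("B", "CR", 1e6, 0.0)])
        g = greedy_complementarity_ranking(ts, statuses, iucn50, cohort)
        tab = score_table(ts, statuses, iucn50, species=["A", "B"])
        static = adepd_cost(tab, cohort)
        second = g.index[1]
        assert g.at[second, "greedy_score_mean"] < static[second]
        # tie on the first pick broke lexicographically
        assert g.index[0] == "A"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_matches_exhaustive_stepwise_oracle(self, seed, iucn50):
        tree = random_tree(8, seed)
        rng = np.random.default_rng(50 + seed)
        statuses = random_statuses(tree, rng, threatened_frac=0.7)
        threatened = sorted(s for s, c in statuses.items() if c in ("VU", "EN", "CR"))[:4]
        assert len(threatened) == 4
        costs = {s: float(c) for s, c in zip(threatened, [2e6, 5e5, 1e6, 3e6])}
        cohort = make_cohort([(s, statuses[s], costs[s], 0.0) for s in threatened])
        g, seqs = greedy_complementarity_ranking(
            TreeSet([tree]), statuses, iucn50, cohort, return_sequences=True
        )
        order, scores = exhaustive_greedy(tree, statuses, iucn50, costs)
        assert seqs[0] == order
        got = [g.at[s, "greedy_score_mean"] for s in order]
        assert np.allclose(got, scores, rtol=1e-9)


class TestSpendingCurve:
    def test_empty_cohort_is_origin_only(self, fixture_bundle, iucn50):
        ts, statuses, cohort, _ = fixture_bundle
        sc = optimal_spending_curve(ts, statuses, iucn50, cohort.iloc[:0])
        assert len(sc.events) == 0
        assert sc.total_cost == 0.0 and sc.total_gain == 0.0
        assert sc.gain_at_budget(1e9) == 0.0

    def test_fixture_curve_values(self, fixture_bundle, iucn50):
        ts, statuses, cohort, expected = fixture_bundle
        sc = optimal_spending_curve(ts, statuses, iucn50, cohort)
        assert list(sc.events["species"]) == expected["greedy_order"]
        assert np.allclose(sc.events["cum_cost_usd"], expected["curve_cum_cost"])
        assert np.allclose(sc.events["cum_gain_myr"], expected["curve_cum_gain"], rtol=1e-9)
        assert sc.baseline_epd_mean == pytest.approx(expected["epd_baseline"], rel=1e-9)

    def test_endpoint_is_order_independent(self, fixture_bundle, iucn50):
        ts, statuses, cohort, expected = fixture_bundle
        forward = optimal_spending_curve(ts, statuses, iucn50, cohort,
                                         ranking=list(cohort.index))
        backward = optimal_spending_curve(ts, statuses, iucn50, cohort,
                                          ranking=list(cohort.index)[::-1])
        assert forward.total_gain == pytest.approx(backward.total_gain, rel=1e-9)
        assert forward.total_gain == pytest.approx(
            expected["epd_after_all"] - expected["epd_baseline"], rel=1e-9
        )

    def test_curve_monotone_and_greedy_derivative_non_increasing(self, iucn50):
        tree = random_tree(14, seed=6)
        rng = np.random.default_rng(60)
        statuses = random_statuses(tree, rng, threatened_frac=0.6)
        threatened = sorted(s for s, c in statuses.items() if c in ("VU", "EN", "CR"))
        costs = 1e6 * rng.lognormal(0, 1, size=len(threatened))
        cohort = make_cohort(
            [(s, statuses[s], c, 0.0) for s, c in zip(threatened, costs)]
        )
        sc = optimal_spending_curve(TreeSet([tree]), statuses, iucn50, cohort)
        assert (np.diff(sc.events["cum_cost_usd"]) > 0).all()
        assert (np.diff(sc.events["cum_gain_myr"]) >= -1e-12).all()
        # on a single tree the greedy rule picks the best ratio first
        marg = sc.events["marginal_myr_per_usd"].to_numpy()
        assert (np.diff(marg) <= 1e-12).all()


class TestProjection:
    def test_spending_full_cost_recovers_full_static_gain(self, fixture_bundle, iucn50):
        ts, statuses, cohort, expected = fixture_bundle
        cohort = cohort.copy()
        cohort["expenditure_usd"] = cohort["cost_usd"]
        proj = current_spending_projection(ts, statuses, iucn50, cohort)
        assert proj["gain_mean_myr"].sum() == pytest.approx(
            sum(expected["adepd"].values()), rel=1e-9
        )

    def test_zero_spend_zero_gain(self, fixture_bundle, iucn50):
        ts, statuses, cohort, _ = fixture_bundle
        cohort = cohort.copy()
        cohort["expenditure_usd"] = 0.0
        proj = current_spending_projection(ts, statuses, iucn50, cohort)
        assert proj["gain_mean_myr"].sum() == 0.0

    def test_fixture_projection_values(self, fixture_bundle, iucn50):
        ts, statuses, cohort, expected = fixture_bundle
        proj = current_spending_projection(ts, statuses, iucn50, cohort)
        for sp, want in expected["projection"].items():
            assert proj.at[sp, "gain_mean_myr"] == pytest.approx(want, rel=1e-9, abs=0)
        assert proj["gain_mean_myr"].sum() == pytest.approx(
            expected["projection_total"], rel=1e-9
        )

    def test_cap_limits_extrapolated_gain(self, fixture_bundle, iucn50):
        ts, statuses, cohort, expected = fixture_bundle
        cohort = cohort.copy()
        cohort.loc["B", "expenditure_usd"] = 10 * cohort.loc["B", "cost_usd"]
        uncapped = current_spending_projection(ts, statuses, iucn50, cohort)
        capped = current_spending_projection(
            ts, statuses, iucn50, cohort, cap_linear_gain=True
        )
        assert uncapped.at["B", "gain_mean_myr"] > expected["adepd"]["B"]
        assert capped.at["B", "gain_mean_myr"] == pytest.approx(expected["adepd"]["B"])

    def test_misallocated_spending_underperforms_optimal(self, iucn50):
        # expenditure piled on the worst-value species: the optimal curve at
        # the same total budget must strictly beat the projection
        tree = random_tree(16, seed=30)
        rng = np.random.default_rng(30)
        statuses = random_statuses(tree, rng, threatened_frac=0.6)
        threatened = sorted(s for s, c in statuses.items() if c in ("VU", "EN", "CR"))
        costs = {s: 1e6 * float(rng.lognormal(0, 1)) for s in threatened}
        cohort = make_cohort([(s, statuses[s], costs[s], 0.0) for s in threatened])
        ts = TreeSet([tree])
        tab = score_table(ts, statuses, iucn50, species=threatened)
        ac = adepd_cost(tab, cohort)
        worst = ac.sort_values().index[: max(2, len(ac) // 3)]
        cohort.loc[worst, "expenditure_usd"] = cohort.loc[worst, "cost_usd"]
        proj = current_spending_projection(ts, statuses, iucn50, cohort)
        budget = proj["expenditure_usd"].sum()
        sc = optimal_spending_curve(ts, statuses, iucn50, cohort)
        assert sc.gain_at_budget(budget) > proj["gain_mean_myr"].sum()


class TestPriceOfPd:
    def test_exact_dollar_per_year(self):
        out = price_of_pd(1e-6)
        assert out["usd_per_year"] == pytest.approx(1.0)
        assert out["years_per_usd"] == pytest.approx(1.0)

    def test_best_and_worst_case_conversions(self):
        best = price_of_pd(1.669e-5)  # 16.69 years of EPD per dollar
        assert best["years_per_usd"] == pytest.approx(16.69)
        assert best["usd_per_year"] == pytest.approx(0.0599, abs=5e-5)
        worst = price_of_pd(1.0 / 3915 / 1e6)  # $3915 buys one year
        assert worst["hours_per_usd"] == pytest.approx(8760 / 3915, rel=1e-9)
        assert worst["hours_per_usd"] == pytest.approx(2.24, abs=5e-3)

    def test_zero_score_prices_at_infinity(self):
        assert price_of_pd(0.0)["usd_per_year"] == float("inf")


class TestCompareRankings:
    def test_identical_and_reversed(self):
        a = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)])
        assert compare_rankings(a, a)[0] == pytest.approx(1.0)
        assert compare_rankings(a, a[::-1].set_axis(a.index[::-1]))[0] == pytest.approx(1.0)
        rev = pd.Series(range(10, 0, -1), index=a.index)
        assert compare_rankings(a, rev)[0] == pytest.approx(-1.0)

    def test_permutation_matches_textbook_pearson(self):
        rng = np.random.default_rng(17)
        idx = [f"s{i}" for i in range(20)]
        a = pd.Series(rng.permutation(np.arange(1, 21)), index=idx)
        b = pd.Series(rng.permutation(np.arange(1, 21)), index=idx)
        x, y = a.to_numpy(float), b.to_numpy(float)
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        r, p = compare_rankings(a, b)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert 0 <= p <= 1

    def test_top_k_restricts_to_first_ranking(self):
        idx = [f"s{i}" for i in range(10)]
        a = pd.Series(range(1, 11), index=idx)
        b = pd.Series(range(1, 11), index=idx)
        b.iloc[5:] = b.iloc[5:][::-1].to_numpy()  # disagree only outside top 5
        r_top, _ = compare_rankings(a, b, top_k=5)
        assert r_top == pytest.approx(1.0)

    def test_small_k_rejected(self):
        a = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="top_k"):
            compare_rankings(a, a, top_k=2)


class TestCohortIO:
    def test_round_trip_and_blank_expenditure(self, tmp_path, caplog):
        p = tmp_path / "cohort.csv"
        p.write_text(
            "species,iucn_category,cost_usd,expenditure_usd\n"
            "X,CR,100000,5000\nY,EN,200000,\n"
        )
        import logging

        with caplog.at_level(logging.WARNING):
            co = load_cohort(p)
        assert co.at["Y", "expenditure_usd"] == 0.0
        assert "Y" in caplog.text

    def test_rejects_undownlistable_cohort_member(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("species,iucn_category,cost_usd,expenditure_usd\nX,LC,1000,0\n")
        with pytest.raises(ValueError, match="non-downlistable"):
            load_cohort(p)
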