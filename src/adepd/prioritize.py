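"""Cost-aware prioritization: ADEPD-cost, greedy complementarity, spending curves.

The Noah's Ark question addressed here: given a cohort of threatened species,
each with a dollar cost to downlist it one Red List category, in what order
should a fixed budget be spent to maximize expected future phylogenetic
diversity? The answer used throughout is the greedy ratio rule — repeatedly
fund the species with the highest instantaneous EPD gain per dollar — applied
per tree and averaged over the tree distribution so that phylogenetic
uncertainty is carried into the ranking.

Complementarity matters because related species share edges: once one member
of a threatened sister pair is downlisted, the shared stem is safer and the
second member's marginal gain drops. The greedy pass recomputes scores after
every downlisting event, so this effect is priced in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk import RiskTransform, is_downlistable
from .scores import SurvivalState, score_table
from .tree import TreeSet

__all__ = [
    "load_cohort",
    "adepd_cost",
    "greedy_complementarity_ranking",
    "SpendingCurve",
    "optimal_spending_curve",
    "current_spending_projection",
    "price_of_pd",
    "compare_rankings",
]

logger = logging.getLogger(__name__)

#: USD per GBP implied by the published cost pairs (e.g. $810M = £486M).
USD_PER_GBP = 1.6667

#: Hours in a 365-day year, for "hours of PD per dollar" conversions.
HOURS_PER_YEAR = 365 * 24


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV: ``species,iucn_category,cost_usd[,expenditure_usd]``.

    Costs must be strictly positive; a missing expenditure column (or blank
    cells) is treated as zero spend with a logged warning, mirroring species
    with no reported conservation funding.
    """
    df = pd.read_csv(path)
    required = {"species", "iucn_category", "cost_usd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    df = df.set_index("species")
    if "expenditure_usd" not in df.columns:
        logger.warning("no expenditure_usd column in %s; assuming zero spend", path)
        df["expenditure_usd"] = 0.0
    blank = df["expenditure_usd"].isna()
    if blank.any():
        logger.warning(
            "no expenditure recorded for %s; assuming zero spend",
            ", ".join(df.index[blank]),
        )
        df.loc[blank, "expenditure_usd"] = 0.0
    _validate_cohort(df)
    return df


def _validate_cohort(cohort: pd.DataFrame) -> None:
    bad = cohort.index[cohort["cost_usd"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive downlisting cost for species: {list(bad)}")
    if (cohort["expenditure_usd"] < 0).any():
        raise ValueError("negative expenditure")
    not_dl = [
        s for s, c in cohort["iucn_category"].items() if not is_downlistable(c)
    ]
    if not_dl:
        raise ValueError(f"cohort species with non-downlistable status: {not_dl}")


def adepd_cost(
    scores: pd.DataFrame, cohort: pd.DataFrame, *, per_year: bool = False
) -> pd.Series:
    """EPD gain per dollar: mean ADEPD divided by downlisting cost.

    Returns Myr/USD by default; ``per_year=True`` converts to years of PD per
    dollar (x 10^6).
    """
    _validate_cohort(cohort)
    missing = cohort.index.difference(scores.index)
    if len(missing):
        raise ValueError(f"no ADEPD scores for cohort species: {list(missing)}")
    s = scores.loc[cohort.index, "ADEPD_mean"] / cohort["cost_usd"]
    if per_year:
        s = s * 1e6
    return s.rename("ADEPD_cost")


def greedy_complementarity_ranking(
    treeset: TreeSet,
    statuses: Mapping[str, str],
    transform: RiskTransform,
    cohort: pd.DataFrame,
    *,
    return_sequences: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[list[str]]]:
    """Complementarity-adjusted ADEPD-cost scores and the priority ranking.

    Per tree: repeatedly compute the instantaneous ADEPD-cost of every
    remaining cohort species on the current (partially downlisted) state,
    downlist the best one, and record its score at selection time. Each
    species' recorded scores are then averaged across trees and species are
    ranked by the average (1 = fund first). Ties in the per-tree argmax break
    lexicographically on species label, so runs are deterministic.

    Returns a DataFrame (index species) with ``greedy_score_mean`` (Myr/USD),
    ``greedy_score_sd`` and ``rank``; with ``return_sequences=True`` also the
    per-tree selection order.
    """
    _validate_cohort(cohort)
    species = list(cohort.index)
    treeset.require_species(species)
    costs = cohort["cost_usd"]
    n_trees = len(treeset)
    recorded = np.zeros((n_trees, len(species)))
    col = {s: j for j, s in enumerate(species)}
    sequences: list[list[str]] = []
    for k, tree in enumerate(treeset):
        state = SurvivalState(tree, statuses, transform)
        remaining = set(species)
        order: list[str] = []
        while remaining:
            best_sp, best_score = None, -np.inf
            for sp in sorted(remaining):  # sorted => lexicographic tie-break
                sc = state.downlist_gain(sp) / costs[sp]
                if sc > best_score:
                    best_sp, best_score = sp, sc
            assert best_sp is not None
            state.downlist(best_sp)
            recorded[k, col[best_sp]] = best_score
            remaining.remove(best_sp)
            order.append(best_sp)
        sequences.append(order)
    out = pd.DataFrame(index=pd.Index(species, name="species"))
    out["greedy_score_mean"] = recorded.mean(axis=0)
    out["greedy_score_sd"] = recorded.std(axis=0, ddof=1) if n_trees > 1 else 0.0
    # rank by mean score, lexicographic on ties for determinism
    order_idx = sorted(
        species, key=lambda s: (-out.at[s, "greedy_score_mean"], s)
    )
    out["rank"] = pd.Series(
        {s: r for r, s in enumerate(order_idx, start=1)}, name="rank"
    )
    out = out.sort_values("rank")
    if return_sequences:
        return out, sequences
    return out


@dataclass
class SpendingCurve:
    """Ordered downlisting events with cumulative cost and mean EPD gain.

    ``events`` columns: ``rank, species, cum_cost_usd, cum_gain_myr,
    gain_sd_myr, marginal_myr_per_usd`` (forward difference of gain over
    cost between consecutive events). A leading origin row (0, 0) is implied,
    not stored.
    """

    events: pd.DataFrame
    baseline_epd_mean: float
    baseline_epd_sd: float

    @property
    def total_cost(self) -> float:
        return float(self.events["cum_cost_usd"].iloc[-1]) if len(self.events) else 0.0

    @property
    def total_gain(self) -> float:
        return float(self.events["cum_gain_myr"].iloc[-1]) if len(self.events) else 0.0

    def gain_at_budget(self, budget: float) -> float:
        """Mean EPD gain (Myr) from funding whole events within ``budget``,
        plus a linear fraction of the first unaffordable event."""
        gain, prev_cost, prev_gain = 0.0, 0.0, 0.0
        for _, ev in self.events.iterrows():
            if ev["cum_cost_usd"] <= budget:
                prev_cost, prev_gain = ev["cum_cost_usd"], ev["cum_gain_myr"]
            else:
                step = ev["cum_cost_usd"] - prev_cost
                frac = (budget - prev_cost) / step if step > 0 else 0.0
                return prev_gain + max(0.0, min(1.0, frac)) * (
                    ev["cum_gain_myr"] - prev_gain
                )
        return prev_gain

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)


def optimal_spending_curve(
    treeset: TreeSet,
    statuses: Mapping[str, str],
    transform: RiskTransform,
    cohort: pd.DataFrame,
    ranking: Sequence[str] | None = None,
) -> SpendingCurve:
    """Downlist cohort species in rank order, recording the return curve.

    ``ranking`` defaults to the greedy complementarity ranking. After each
    event the cumulative cost and the mean (+/- sample SD over trees) EPD gain
    relative to the no-action baseline are recorded; the marginal column is
    the numerical differential of gain with respect to cost at that event.
    """
    _validate_cohort(cohort)
    if ranking is None:
        ranking = list(
            greedy_complementarity_ranking(treeset, statuses, transform, cohort).index
        )
    ranking = list(ranking)
    if set(ranking) != set(cohort.index):
        raise ValueError("ranking must cover exactly the cohort species")
    n_trees = len(treeset)
    if not ranking:
        return SpendingCurve(
            pd.DataFrame(
                columns=[
                    "rank",
                    "species",
                    "cum_cost_usd",
                    "cum_gain_myr",
                    "gain_sd_myr",
                    "marginal_myr_per_usd",
                ]
            ),
            *_epd_mean_sd(treeset, statuses, transform),
        )
    gains = np.zeros((n_trees, len(ranking)))  # cumulative per tree
    base = np.zeros(n_trees)
    for k, tree in enumerate(treeset):
        state = SurvivalState(tree, statuses, transform)
        base[k] = state.epd
        cum = 0.0
        for j, sp in enumerate(ranking):
            cum += state.downlist(sp)
            gains[k, j] = cum
    cum_cost = np.cumsum([cohort.at[s, "cost_usd"] for s in ranking])
    mean_gain = gains.mean(axis=0)
    sd_gain = gains.std(axis=0, ddof=1) if n_trees > 1 else np.zeros(len(ranking))
    marginal = np.diff(mean_gain, prepend=0.0) / np.diff(cum_cost, prepend=0.0)
    events = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking) + 1),
            "species": ranking,
            "cum_cost_usd": cum_cost,
            "cum_gain_myr": mean_gain,
            "gain_sd_myr": sd_gain,
            "marginal_myr_per_usd": marginal,
        }
    )
    sd_base = float(base.std(ddof=1)) if n_trees > 1 else 0.0
    return SpendingCurve(events, float(base.mean()), sd_base)


def _epd_mean_sd(treeset, statuses, transform) -> tuple[float, float]:
    vals = np.array(
        [SurvivalState(t, statuses, transform).epd for t in treeset]
    )
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def current_spending_projection(
    treeset: TreeSet,
    statuses: Mapping[str, str],
    transform: RiskTransform,
    cohort: pd.DataFrame,
    *,
    cap_linear_gain: bool = False,
) -> pd.DataFrame:
    """Projected EPD gain if past per-species spending were maintained.

    Assumes a linear response: per tree, species *j* contributes
    ``e_j * ADEPD_j / c_j`` where ``e_j`` is its past expenditure and ``c_j``
    its full downlisting cost; species with no recorded expenditure contribute
    zero. ``cap_linear_gain=True`` caps each species' projected gain at its
    full-downlisting ADEPD (the uncapped linear model can extrapolate past it
    when ``e_j > c_j``).

    Returns a per-species DataFrame with ``expenditure_usd, gain_mean_myr,
    gain_sd_myr``; totals are the column sums (total spend, total projected
    mean gain).
    """
    _validate_cohort(cohort)
    species = list(cohort.index)
    treeset.require_species(species)
    n_trees = len(treeset)
    gains = np.zeros((n_trees, len(species)))
    e = cohort["expenditure_usd"].to_numpy(float)
    c = cohort["cost_usd"].to_numpy(float)
    for k, tree in enumerate(treeset):
        state = SurvivalState(tree, statuses, transform)
        ad = np.array([state.downlist_gain(sp) for sp in species])
        g = e * ad / c
        if cap_linear_gain:
            g = np.minimum(g, ad)
        gains[k] = g
    out = pd.DataFrame(index=pd.Index(species, name="species"))
    out["expenditure_usd"] = e
    out["gain_mean_myr"] = gains.mean(axis=0)
    out["gain_sd_myr"] = gains.std(axis=0, ddof=1) if n_trees > 1 else 0.0
    return out


def price_of_pd(score_myr_per_usd: float) -> dict[str, float]:
    """Headline conversions for an ADEPD-cost score (Myr of EPD per USD).

    Returns years of PD per dollar, dollars per year of PD (``inf`` for a
    zero score), pounds per year at the configured exchange rate, and hours
    of PD per dollar.
    """
    years_per_usd = score_myr_per_usd * 1e6
    usd_per_year = 1.0 / years_per_usd if years_per_usd > 0 else float("inf")
    return {
        "years_per_usd": years_per_usd,
        "usd_per_year": usd_per_year,
        "gbp_per_year": usd_per_year / USD_PER_GBP,
        "hours_per_usd": years_per_usd * HOURS_PER_YEAR,
    }


def compare_rankings(
    rank_a: pd.Series,
    rank_b: pd.Series,
    top_k: int | None = None,
    *,
    on: str = "ranks",
) -> tuple[float, float]:
    """Pearson correlation between two prioritizations, with two-sided p-value.

    ``rank_a``/``rank_b`` map species to rank (1 = best) or to raw scores
    (set ``on='scores'``; ranks are then formed descending). ``top_k``
    restricts the comparison to the first ranking's top-k species.
    """
    common = rank_a.index.intersection(rank_b.index)
    if len(common) < len(rank_a.index) or len(common) < len(rank_b.index):
        raise ValueError("rankings must cover the same species")
    a, b = rank_a.loc[common].astype(float), rank_b.loc[common].astype(float)
    if on == "scores":
        a = a.rank(ascending=False)
        b = b.rank(ascending=False)
    elif on != "ranks":
        raise ValueError("on must be 'ranks' or 'scores'")
    if top_k is not None:
        if top_k < 3:
            raise ValueError("top_k must be >= 3 for a meaningful correlation")
        keep = a.nsmallest(top_k).index
        a, b = a.loc[keep], b.loc[keep]
    elif len(a) < 3:
        raise ValueError("need at least 3 species to correlate rankings")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p)
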