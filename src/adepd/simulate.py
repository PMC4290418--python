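"""Synthetic trees, Red List statuses, costs and expenditures.

The generator emulates the shape of the study inputs the pipeline is built
for — a distribution of ultrametric bird phylogenies, a Red List status per
tip, and a threatened cohort with expert-estimated downlisting costs and past
expenditures — at desk scale, so the whole pipeline is testable without any
download. Defaults:

* pure-birth (Yule) trees, branch lengths in Myr;
* status frequencies proportional to the global avian Red List tally
  (7656 LC, 877 NT, 59 DD, 111 NE, 710 VU, 393 EN, 183 CR, 4 EW of 9993);
* cohort threat mix proportional to 102 CR : 65 EN : 39 VU;
* log-normal costs spanning roughly four orders of magnitude, matching the
  spread between the cheapest and most expensive real downlisting estimates;
* expenditures as a log-normal fraction of cost, with 3% of the cohort
  receiving nothing.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from math import log

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .tree import PhyloTree, TreeSet

__all__ = [
    "SimulationConfig",
    "simulate_treeset",
    "simulate_statuses",
    "simulate_cohort",
    "worked_fixture",
]

#: Global avian Red List tally used for default status frequencies.
_STATUS_COUNTS = {
    "LC": 7656,
    "NT": 877,
    "DD": 59,
    "NE": 111,
    "VU": 710,
    "EN": 393,
    "CR": 183,
    "EW": 4,
}

#: Threat mix of the costed cohort (CR : EN : VU).
_COHORT_MIX = {"CR": 102, "EN": 65, "VU": 39}


def _normalize(d: dict[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study. All rates are per Myr, money in USD."""

    n_tips: int = 64
    n_trees: int = 20
    birth_rate: float = 0.05
    status_freqs: dict[str, float] = field(
        default_factory=lambda: _normalize(_STATUS_COUNTS)
    )
    cohort_size: int | None = None  # None: every VU/EN/CR tip
    cohort_mix: dict[str, float] = field(default_factory=lambda: _normalize(_COHORT_MIX))
    cost_median_usd: float = 1e6
    cost_sigma_ln: float = 2.3  # ~4 orders of magnitude across a cohort
    expenditure_fraction_median: float = 0.15
    expenditure_sigma_ln: float = 0.8
    zero_expenditure_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if abs(sum(self.status_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("status frequencies must sum to 1")


def simulate_treeset(config: SimulationConfig) -> TreeSet:
    """Simulate ``n_trees`` Yule trees on a shared tip-label set.

    Trees are ultrametric with branch lengths in Myr (expected total branch
    length is approximately ``(n_tips - 2) / birth_rate`` without the stem).
    Deterministic given ``config.seed``.
    """
    rng = random.Random(config.seed)
    labels = [f"S{i:04d}" for i in range(1, config.n_tips + 1)]
    trees = []
    for _ in range(config.n_trees):
        dtree = treesim.birth_death_tree(
            birth_rate=config.birth_rate,
            death_rate=0.0,
            num_extant_tips=config.n_tips,
            rng=rng,
        )
        for leaf, lab in zip(dtree.leaf_node_iter(), labels):
            leaf.taxon.label = lab
        dtree.seed_node.edge.length = None  # no stem edge
        trees.append(PhyloTree.from_dendropy(dtree))
    return TreeSet(trees)


def simulate_statuses(labels: list[str], config: SimulationConfig) -> dict[str, str]:
    """Assign a Red List category to every species by the configured frequencies."""
    rng = np.random.default_rng(config.seed + 1)
    cats = list(config.status_freqs)
    probs = np.array([config.status_freqs[c] for c in cats])
    draw = rng.choice(len(cats), size=len(labels), p=probs)
    return {lab: cats[i] for lab, i in zip(sorted(labels), draw)}


def simulate_cohort(
    treeset: TreeSet, config: SimulationConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Statuses for every tip plus a costed cohort of threatened species.

    The cohort is drawn from VU/EN/CR tips, stratified towards the configured
    threat mix; each member gets a log-normal downlisting cost and a past
    expenditure (a log-normal fraction of cost, zeroed with probability
    ``zero_expenditure_frac``). Returns ``(statuses, cohort)`` where
    ``cohort`` follows the ``species,iucn_category,cost_usd,expenditure_usd``
    schema (species as index).
    """
    labels = sorted(treeset.trees[0].tips)
    statuses = simulate_statuses(labels, config)
    rng = np.random.default_rng(config.seed + 2)
    threatened = {
        c: sorted(s for s, st in statuses.items() if st == c) for c in ("CR", "EN", "VU")
    }
    n_threat = sum(len(v) for v in threatened.values())
    size = n_threat if config.cohort_size is None else config.cohort_size
    if size > n_threat:
        raise ValueError(
            f"cohort size {size} exceeds the {n_threat} threatened tips available"
        )
    if size == n_threat:
        members = [s for c in ("CR", "EN", "VU") for s in threatened[c]]
    else:
        # stratify towards the configured mix, then top up from what's left
        members = []
        for c in ("CR", "EN", "VU"):
            want = min(int(round(size * config.cohort_mix.get(c, 0))), len(threatened[c]))
            members.extend(
                sorted(rng.choice(threatened[c], size=want, replace=False))
            )
        pool = sorted(
            set(s for v in threatened.values() for s in v) - set(members)
        )
        if len(members) > size:
            members = sorted(rng.choice(members, size=size, replace=False))
        elif len(members) < size:
            members.extend(
                sorted(rng.choice(pool, size=size - len(members), replace=False))
            )
    members = sorted(members)
    costs = config.cost_median_usd * np.exp(
        rng.normal(0.0, config.cost_sigma_ln, size=len(members))
    )
    frac = config.expenditure_fraction_median * np.exp(
        rng.normal(0.0, config.expenditure_sigma_ln, size=len(members))
    )
    spend = costs * frac
    spend[rng.random(len(members)) < config.zero_expenditure_frac] = 0.0
    cohort = pd.DataFrame(
        {
            "iucn_category": [statuses[s] for s in members],
            "cost_usd": np.round(costs, 2),
            "expenditure_usd": np.round(spend, 2),
        },
        index=pd.Index(members, name="species"),
    )
    return statuses, cohort


# ---------------------------------------------------------------------------
# Hand-verified worked fixture
# ---------------------------------------------------------------------------

#: Six-tip fixture tree; all arithmetic below was done by hand in decimal.
FIXTURE_NEWICK = "(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);"

FIXTURE_STATUSES = {"A": "CR", "B": "EN", "C": "LC", "D": "VU", "E": "LC", "F": "NT"}

#: Cohort: species, status, downlisting cost, past expenditure (USD).
FIXTURE_COHORT_ROWS = [
    ("A", "CR", 4_000_000.0, 1_000_000.0),
    ("B", "EN", 1_000_000.0, 2_000_000.0),
    ("D", "VU", 500_000.0, 0.0),
]

# IUCN50 tip probabilities: A .97, B .42, C/E .00005, D .05, F .004.
# Edge p: AB=.97*.42=.4074; ABC=.4074*.00005=.00002037; DE=.05*.00005=.0000025;
# DEF=.0000025*.004=1e-8. EPD = sum L(1-p):
#   tips  .03+.58+1.9999+.95+.99995+1.992            = 6.55185
#   inner .5926+.99997963+.9999975+.99999999          = 3.59257712
FIXTURE_EXPECTED = {
    "pd_total": 12.0,
    "epd_baseline": 10.14442712,
    # ADEPD: sum over the species' root path of L * (p_before - p_after)
    #   A (CR->EN): .55 + .2310 + .00001155                 = .78101155
    #   B (EN->VU): .37 + .3589 + .000017945                = .728917945
    #   D (VU->NT): .046 + .0000023 + .0000000092           = .0460023092
    "adepd": {"A": 0.78101155, "B": 0.728917945, "D": 0.0460023092},
    "adepd_cost": {"A": 0.78101155 / 4e6, "B": 0.728917945 / 1e6, "D": 0.0460023092 / 5e5},
    # Greedy: B first (7.289e-7); with B at VU, A's gain drops to
    # .55 + .0275 + .000001375 = .577501375 (score 1.4437534375e-7), still
    # above D's 9.20046184e-8; D last, unchanged (disjoint subtree).
    "greedy_order": ["B", "A", "D"],
    "greedy_scores": {
        "B": 0.728917945 / 1e6,
        "A": 0.577501375 / 4e6,
        "D": 0.0460023092 / 5e5,
    },
    "curve_cum_cost": [1_000_000.0, 5_000_000.0, 5_500_000.0],
    "curve_cum_gain": [0.728917945, 1.30641932, 1.3524216292],
    # Downlisting everything at once: EPD_after = 11.4968487492
    "epd_after_all": 11.4968487492,
    # Linear projection: e_j * ADEPD_j / c_j
    #   A: 1e6 * .78101155/4e6 = .1952528875 ; B: 2e6 * .728917945/1e6
    "projection": {"A": 0.1952528875, "B": 1.45783589, "D": 0.0},
    "projection_total": 1.6530887775,
    # Fair-proportion ED: A=B=D=E = 1 + 1/2 + 1/3; C=F = 2 + 1/3; sums to 12
    "ed": {
        "A": 11 / 6,
        "B": 11 / 6,
        "C": 7 / 3,
        "D": 11 / 6,
        "E": 11 / 6,
        "F": 7 / 3,
    },
}


def worked_fixture() -> tuple[TreeSet, dict[str, str], pd.DataFrame, dict]:
    """The hand-verified 6-tip fixture: treeset, statuses, cohort, expected values."""
    dtree = dendropy.Tree.get(data=FIXTURE_NEWICK, schema="newick")
    treeset = TreeSet([PhyloTree.from_dendropy(dtree)])
    cohort = pd.DataFrame(
        [
            {"iucn_category": c, "cost_usd": cost, "expenditure_usd": e}
            for _, c, cost, e in FIXTURE_COHORT_ROWS
        ],
        index=pd.Index([s for s, *_ in FIXTURE_COHORT_ROWS], name="species"),
    )
    return treeset, dict(FIXTURE_STATUSES), cohort, FIXTURE_EXPECTED
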