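"""Independent oracles used across the test suite.

Everything here deliberately avoids the package's own recursion/path-update
code paths: edge survival is formed as a brute-force product over descendant
tips, EPD by direct summation over the edge dump, and the Monte-Carlo oracle
simulates Bernoulli tip extinctions outright.
"""

from __future__ import annotations

import numpy as np

from adepd.risk import RiskTransform, downlist
from adepd.scores import SurvivalState
from adepd.simulate import SimulationConfig, simulate_treeset
from adepd.tree import PhyloTree


def random_tree(n_tips: int, seed: int, birth_rate: float = 0.1) -> PhyloTree:
    cfg = SimulationConfig(n_tips=n_tips, n_trees=1, birth_rate=birth_rate, seed=seed)
    return simulate_treeset(cfg).trees[0]


def random_statuses(
    tree: PhyloTree, rng: np.random.Generator, threatened_frac: float = 0.4
) -> dict[str, str]:
    """Random Red List statuses with a healthy share of threatened tips."""
    cats_threat = ["VU", "EN", "CR"]
    cats_safe = ["LC", "NT", "DD"]
    out = {}
    for t in tree.tips:
        pool = cats_threat if rng.random() < threatened_frac else cats_safe
        out[t] = pool[rng.integers(len(pool))]
    return out


def brute_edge_probs(
    tree: PhyloTree, statuses: dict[str, str], transform: RiskTransform
) -> np.ndarray:
    """p(i) for every node as the plain product over its descendant tips."""
    tip_p = np.array([transform[statuses[t]] for t in tree.tips])
    p = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes):
        p[v] = np.prod(tip_p[tree.descendant_tips(v)])
    return p


def brute_epd(
    tree: PhyloTree, statuses: dict[str, str], transform: RiskTransform
) -> float:
    """EPD summed edge-by-edge from the brute-force descendant products."""
    p = brute_edge_probs(tree, statuses, transform)
    return sum(
        tree.lengths[v] * (1.0 - p[v]) for v in range(tree.n_nodes) if v != tree.root
    )


def mc_surviving_pd(
    tree: PhyloTree,
    statuses: dict[str, str],
    transform: RiskTransform,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Surviving PD per draw under independent Bernoulli tip extinctions."""
    tip_p = np.array([transform[statuses[t]] for t in tree.tips])
    alive = (rng.random((n_draws, tree.n_tips)) >= tip_p).astype(np.float32)
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    mask = tree.tip_masks()[edges].astype(np.float32)  # (E, n_tips)
    survives = (alive @ mask.T) > 0  # an edge survives iff any tip below lives
    return survives @ tree.lengths[edges]


def exhaustive_greedy(
    tree: PhyloTree,
    statuses: dict[str, str],
    transform: RiskTransform,
    costs: dict[str, float],
) -> tuple[list[str], list[float]]:
    """Stepwise greedy via full EPD recomputation from descendant products.

    At every step, the EPD gain of each remaining species is obtained by
    rebuilding the whole edge-probability table from scratch for the
    downlisted status set; argmax of gain/cost, ties broken lexicographically.
    """
    current = dict(statuses)
    order: list[str] = []
    scores: list[float] = []
    remaining = sorted(costs)
    while remaining:
        epd_now = brute_epd(tree, current, transform)
        best, best_score = None, -np.inf
        for sp in remaining:
            trial = dict(current)
            trial[sp] = downlist(trial[sp])
            score = (brute_epd(tree, trial, transform) - epd_now) / costs[sp]
            if score > best_score:
                best, best_score = sp, score
        order.append(best)
        scores.append(best_score)
        current[best] = downlist(current[best])
        remaining.remove(best)
    return order, scores
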