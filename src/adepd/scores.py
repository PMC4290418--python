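"""Expected phylogenetic diversity (EPD), downlisting gains (ADEPD), ED and EDGE.

The model: each tip *i* goes extinct independently with probability ``p(i)``
given by a risk transform applied to its Red List status. An edge of the tree
is lost only if *every* tip below it is lost, so the extinction probability of
an interior edge is the product of its daughter edges' probabilities:

    p(i) = p(j) * p(k)        (edge i with daughters j, k)

and the expected surviving phylogenetic diversity of tree ``T`` is

    EPD(T) = sum_i L_i * (1 - p(i))     over all 2n - 2 edges.

ADEPD of species *j* is the EPD gain from downlisting *j* by one Red List
category: ``ADEPD(j) = EPD(DL(T, j)) - EPD(T)``. Because downlisting changes
extinction probabilities only on the root path of *j*, the gain is computed by
updating that path rather than recomputing the whole tree; the two routes
agree to floating-point tolerance and the test suite pins this equivalence.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .risk import RiskTransform, builtin_transform, downlist
from .tree import PhyloTree, TreeSet

__all__ = [
    "edge_survival",
    "expected_pd",
    "adepd",
    "ed_scores",
    "edge_score",
    "SurvivalState",
    "score_table",
]


def _tip_probs(
    tree: PhyloTree, statuses: Mapping[str, str], transform: RiskTransform
) -> np.ndarray:
    transform.require_probabilistic()
    missing = [t for t in tree.tips if t not in statuses]
    if missing:
        raise ValueError(f"no IUCN status for tips: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return np.array([transform[statuses[t]] for t in tree.tips], dtype=np.float64)


def edge_survival(
    tree: PhyloTree, statuses: Mapping[str, str], transform: RiskTransform
) -> np.ndarray:
    """Per-node extinction probabilities ``p(i)`` by the daughter-product recursion.

    Returns an array over all nodes (tips first); the root entry is the
    probability that the entire tree is lost and corresponds to no edge.
    For a multifurcating node the product runs over all children.
    """
    p = np.empty(tree.n_nodes, dtype=np.float64)
    p[: tree.n_tips] = _tip_probs(tree, statuses, transform)
    for node in tree.postorder:
        if node >= tree.n_tips:
            prob = 1.0
            for ch in tree.children[node]:
                prob *= p[ch]
            p[node] = prob
    return p


def expected_pd(
    tree: PhyloTree, statuses: Mapping[str, str], transform: RiskTransform
) -> float:
    """EPD(T) = sum over edges of L_i * (1 - p(i)), in Myr."""
    p = edge_survival(tree, statuses, transform)
    return _epd_from_p(tree, p)


def _epd_from_p(tree: PhyloTree, p: np.ndarray) -> float:
    keep = np.ones(tree.n_nodes, dtype=bool)
    keep[tree.root] = False  # the root has no edge above it
    return float(np.sum(tree.lengths[keep] * (1.0 - p[keep])))


class SurvivalState:
    """Mutable extinction-probability state of one tree, supporting downlisting.

    Used by the greedy complementarity ranking, where species are downlisted
    one after another on the same tree and every step must see the survival
    probabilities left behind by earlier steps.
    """

    def __init__(
        self, tree: PhyloTree, statuses: Mapping[str, str], transform: RiskTransform
    ) -> None:
        transform.require_probabilistic()
        self.tree = tree
        self.transform = transform
        self.statuses = dict(statuses)
        self.p = edge_survival(tree, statuses, transform)

    def copy(self) -> "SurvivalState":
        new = object.__new__(SurvivalState)
        new.tree = self.tree
        new.transform = self.transform
        new.statuses = dict(self.statuses)
        new.p = self.p.copy()
        return new

    @property
    def epd(self) -> float:
        return _epd_from_p(self.tree, self.p)

    def downlist_gain(self, species: str) -> float:
        """EPD gain if ``species`` were downlisted now, without applying it."""
        return self._update(species, apply=False)

    def downlist(self, species: str) -> float:
        """Downlist ``species`` in place and return the EPD gain."""
        return self._update(species, apply=True)

    def _update(self, species: str, apply: bool) -> float:
        tree = self.tree
        tip = tree.tip_id(species)
        new_status = downlist(self.statuses[species])
        new_p = self.transform[new_status]
        gain = 0.0
        changed: list[tuple[int, float]] = []
        current = new_p
        for node in tree.root_path(tip):
            if node != tip:
                # re-form the product over children with the child below
                # already updated; exact, no division by possibly-zero p
                current = 1.0
                for ch in tree.children[node]:
                    current *= prev_new if ch == prev_node else self.p[ch]
            if node != tree.root:
                gain += tree.lengths[node] * (self.p[node] - current)
            changed.append((node, current))
            prev_node, prev_new = node, current
        if apply:
            for node, val in changed:
                self.p[node] = val
            self.statuses[species] = new_status
        return gain


def adepd(
    tree: PhyloTree,
    statuses: Mapping[str, str],
    transform: RiskTransform,
    species: str,
) -> float:
    """ADEPD(j): the gain in expected PD when species ``j`` is downlisted one
    Red List category (Myr)."""
    return SurvivalState(tree, statuses, transform).downlist_gain(species)


def ed_scores(tree: PhyloTree) -> pd.Series:
    """Evolutionary distinctiveness (fair proportion) per tip, in Myr.

    Each edge's length is split equally among its descendant tips; a tip's ED
    is the sum of its shares, and tip EDs sum to PD(T) exactly.
    """
    share = np.zeros(tree.n_tips, dtype=np.float64)
    # accumulate per-tip shares top-down: carry the running sum of
    # length/n_desc from the root to each tip
    carry = np.zeros(tree.n_nodes, dtype=np.float64)
    for node in tree.postorder[::-1]:  # preorder-ish: parents before children
        if node != tree.root:
            carry[node] += tree.lengths[node] / tree.n_desc[node]
        if node < tree.n_tips:
            share[node] = carry[node]
        else:
            for ch in tree.children[node]:
                carry[ch] += carry[node]
    return pd.Series(share, index=list(tree.tips), name="ED")


def edge_score(
    ed: float, category: str, ge: RiskTransform | None = None
) -> float:
    """EDGE = ln(1 + ED) + GE * ln 2, the standard ED/endangerment combination.

    Provided for rank comparisons against ADEPD; GE is the ordinal Red List
    weight (LC 0 .. CR 4).
    """
    if ge is None:
        ge = builtin_transform("GE")
    return math.log1p(ed) + ge[category] * math.log(2.0)


def score_table(
    treeset: TreeSet,
    statuses: Mapping[str, str],
    transform: RiskTransform,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species scores averaged over a tree distribution.

    Columns: ``status, ED_mean, EDGE, ADEPD_mean, ADEPD_sd`` plus dense ranks
    ``ED_rank, EDGE_rank, ADEPD_rank`` (1 = best). ADEPD is computed for every
    downlistable species in ``species`` (default: all downlistable tips);
    the SD is the sample standard deviation across trees (0 for one tree).
    """
    if species is None:
        from .risk import is_downlistable

        species = sorted(
            s for s in treeset.trees[0].tips if is_downlistable(statuses.get(s, "LC"))
        )
    species = list(species)
    treeset.require_species(species)
    n_trees = len(treeset)
    ad = np.zeros((n_trees, len(species)))
    ed = np.zeros((n_trees, len(species)))
    for k, tree in enumerate(treeset):
        state = SurvivalState(tree, statuses, transform)
        ed_all = ed_scores(tree)
        for j, sp in enumerate(species):
            ad[k, j] = state.downlist_gain(sp)
            ed[k, j] = ed_all[sp]
    out = pd.DataFrame(index=pd.Index(species, name="species"))
    out["status"] = [statuses[s] for s in species]
    out["ED_mean"] = ed.mean(axis=0)
    out["EDGE"] = [
        edge_score(e, statuses[s]) for e, s in zip(out["ED_mean"], species)
    ]
    out["ADEPD_mean"] = ad.mean(axis=0)
    out["ADEPD_sd"] = ad.std(axis=0, ddof=1) if n_trees > 1 else 0.0
    for col in ("ED_mean", "EDGE", "ADEPD_mean"):
        out[col.replace("_mean", "") + "_rank"] = (
            out[col].rank(ascending=False, method="first").astype(int)
        )
    return out
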