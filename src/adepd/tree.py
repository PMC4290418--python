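"""Rooted time-scaled phylogenies and their edge bookkeeping.

Trees are stored in a flat array form tuned for the survival recursions in
:mod:`adepd.scores`: nodes are integers, tips first (``0..n-1``) then internal
nodes in postorder, root last. Every node except the root carries the length
of the edge to its parent, so a strictly bifurcating *n*-tip tree exposes
exactly ``2n - 2`` edges (*n* tip edges and ``n - 2`` interior edges); there
is never a stem edge above the root — one found in a Newick string is dropped
with a warning.

Branch lengths are interpreted as millions of years (Myr). Trees in other
units can be rescaled on load with ``scale``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = ["PhyloTree", "TreeSet", "read_newick", "write_newick"]


class PolytomyWarning(UserWarning):
    """A loaded tree contains a multifurcating node."""


def normalize_label(label: str) -> str:
    """Fold whitespace to underscores and strip quoting, for tip matching."""
    return "_".join(label.replace("'", "").strip().split())


class PhyloTree:
    """A rooted phylogeny with edge lengths, in flat array form.

    Parameters
    ----------
    tips
        Tip labels, in node-index order (node ``i`` is tip ``tips[i]``).
    parent
        Parent node index per node; the root has parent ``-1``.
    lengths
        Edge length above each node (Myr); the root entry is ignored.
    """

    def __init__(
        self, tips: Sequence[str], parent: Sequence[int], lengths: Sequence[float]
    ) -> None:
        self.tips: tuple[str, ...] = tuple(tips)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.n_tips = len(self.tips)
        self.n_nodes = len(self.parent)
        if self.n_tips < 2:
            raise ValueError("a tree needs at least 2 tips")
        root = np.flatnonzero(self.parent < 0)
        if len(root) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(root[0])
        edge_lengths = np.delete(self.lengths, self.root)
        if not np.all(np.isfinite(edge_lengths)) or np.any(edge_lengths < 0):
            raise ValueError("all edge lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                self.children[par].append(node)
        for node in range(self.n_tips, self.n_nodes):
            if len(self.children[node]) < 2:
                raise ValueError(f"internal node {node} has fewer than 2 children")
        self.postorder = self._postorder()
        # descendant-tip counts, bottom-up
        self.n_desc = np.zeros(self.n_nodes, dtype=np.int64)
        self.n_desc[: self.n_tips] = 1
        for node in self.postorder:
            for ch in self.children[node]:
                self.n_desc[node] += self.n_desc[ch] if ch >= self.n_tips else 1
        self._tip_index = {lab: i for i, lab in enumerate(self.tips)}
        if len(self._tip_index) != self.n_tips:
            raise ValueError("duplicate tip labels")

    # -- structure ---------------------------------------------------------

    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < self.n_tips:
                order.append(node)
            elif expanded:
                order.append(node)
            else:
                stack.append((node, True))
                stack.extend((ch, False) for ch in reversed(self.children[node]))
        return np.asarray(order, dtype=np.int64)

    @property
    def n_edges(self) -> int:
        """Number of edges: one per non-root node (2n-2 when bifurcating)."""
        return self.n_nodes - 1

    @property
    def is_bifurcating(self) -> bool:
        return all(
            len(self.children[n]) == 2 for n in range(self.n_tips, self.n_nodes)
        )

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def root_path(self, node: int) -> list[int]:
        """Nodes from ``node`` up to and including the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def descendant_tips(self, node: int) -> np.ndarray:
        """Tip indices below ``node`` (a tip is its own descendant)."""
        out: list[int] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                out.append(nd)
            else:
                stack.extend(self.children[nd])
        return np.asarray(sorted(out), dtype=np.int64)

    def tip_masks(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: mask[v, t] iff tip t descends from v."""
        mask = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        mask[np.arange(self.n_tips), np.arange(self.n_tips)] = True
        for node in self.postorder:
            for ch in self.children[node]:
                mask[node] |= mask[ch]
        return mask

    # -- metrics -----------------------------------------------------------

    def total_pd(self) -> float:
        """Faith's phylogenetic diversity: the sum of all edge lengths (Myr)."""
        return float(np.sum(np.delete(self.lengths, self.root)))

    def edge_table(self) -> pd.DataFrame:
        """One row per edge: id, parent, child node/tip label, length, tip count."""
        rows = []
        for node in range(self.n_nodes):
            if node == self.root:
                continue
            rows.append(
                {
                    "edge_id": node,
                    "parent": int(self.parent[node]),
                    "child": self.tips[node] if node < self.n_tips else f"node{node}",
                    "length_myr": float(self.lengths[node]),
                    "n_desc_tips": int(self.n_desc[node]),
                }
            )
        return pd.DataFrame(rows)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        *,
        scale: float = 1.0,
        strict_bifurcating: bool = False,
    ) -> "PhyloTree":
        seed = dtree.seed_node
        if seed.edge.length:
            warnings.warn(
                f"dropping stem edge of length {seed.edge.length} above the root",
                UserWarning,
                stacklevel=2,
            )
        leaves = [lf for lf in dtree.leaf_node_iter()]
        n = len(leaves)
        index: dict[int, int] = {}
        tips: list[str] = []
        for i, lf in enumerate(leaves):
            if lf.taxon is None or lf.taxon.label is None:
                raise ValueError("unlabelled tip in tree")
            index[id(lf)] = i
            tips.append(normalize_label(lf.taxon.label))
        nxt = n
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                continue
            nchild = len(node.child_nodes())
            if nchild > 2:
                msg = f"polytomy: internal node with {nchild} children"
                if strict_bifurcating:
                    raise ValueError(msg)
                warnings.warn(msg, PolytomyWarning, stacklevel=2)
            index[id(node)] = nxt
            nxt += 1
        parent = np.full(nxt, -1, dtype=np.int64)
        lengths = np.zeros(nxt, dtype=np.float64)
        for node in dtree.preorder_node_iter():
            i = index[id(node)]
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                if node.edge.length is None:
                    name = tips[i] if i < n else f"internal node {i}"
                    raise ValueError(f"missing branch length on edge above {name}")
                lengths[i] = node.edge.length * scale
        return cls(tips, parent, lengths)

    def to_newick(self, precision: int = 10) -> str:
        def render(node: int) -> str:
            if node < self.n_tips:
                body = self.tips[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return body + ";"
            return f"{body}:{self.lengths[node]:.{precision}g}"

        return render(self.root)


@dataclass
class TreeSet:
    """A weighted collection of trees over a shared tip-label universe."""

    trees: list[PhyloTree]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet needs at least one tree")
        if self.weights is None:
            self.weights = np.full(len(self.trees), 1.0 / len(self.trees))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.trees):
                raise ValueError("one weight per tree required")
            self.weights = self.weights / self.weights.sum()

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    @property
    def labels(self) -> set[str]:
        """Union of tip labels across trees."""
        out: set[str] = set()
        for t in self.trees:
            out.update(t.tips)
        return out

    def require_species(self, species: Iterable[str]) -> None:
        """Raise if any requested species is absent from any tree."""
        species = list(species)
        for k, t in enumerate(self.trees):
            missing = sorted(set(species) - set(t.tips))
            if missing:
                raise ValueError(
                    f"tree {k} is missing cohort species {missing}; every scored "
                    "species must appear in every tree"
                )


def read_newick(
    path: str | Path,
    *,
    scale: float = 1.0,
    strict_bifurcating: bool = False,
) -> TreeSet:
    """Read one or more Newick trees (one per line) into a :class:`TreeSet`.

    Tip labels are normalized (whitespace folded to underscores) so that
    species tables and trees match on the same keys. All edges must carry
    branch lengths; a stem edge above the root is dropped with a warning.
    """
    path = Path(path)
    try:
        tl = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    if not tl:
        raise ValueError(f"no trees found in {path}")
    trees = [
        PhyloTree.from_dendropy(t, scale=scale, strict_bifurcating=strict_bifurcating)
        for t in tl
    ]
    return TreeSet(trees)


def write_newick(treeset: TreeSet, path: str | Path, precision: int = 10) -> None:
    """Write a TreeSet as a multi-line Newick file (one tree per line)."""
    with open(path, "w") as fh:
        for t in treeset:
            fh.write(t.to_newick(precision=precision) + "\n")
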