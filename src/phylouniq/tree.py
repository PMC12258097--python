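"""Rooted phylogenetic trees, branch-set algebra and Faith's PD.

The tree is stored as flat arrays: every non-root node owns the edge to its
parent, and a boolean tip-by-edge ancestry matrix records which edges lie on
each tip-to-root path.  A community's branch set is then a single boolean OR
over tip rows, and Faith's PD a dot product with the branch-length vector.
This "root-inclusive" convention (every path runs to the root of the full
tree, never a re-rooted subtree) is used consistently by the dissimilarity,
endemism and prioritisation layers, so that deep branches shared by two
communities count as shared and the per-branch endemism contributions sum
exactly to total PD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "BranchSet",
    "Community",
    "ReconciliationError",
    "spanning_branch_set",
    "faith_pd",
]


class ReconciliationError(ValueError):
    """A species label does not match any tip of the tree."""


@dataclass(frozen=True)
class Community:
    """A site's species assemblage (presence/absence only)."""

    site_id: str
    species: frozenset[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"community {self.site_id!r} is empty")
        object.__setattr__(self, "species", frozenset(self.species))


@dataclass(frozen=True)
class BranchSet:
    """A subset of a tree's edges with its summed branch length."""

    edge_indices: frozenset[int]
    total_length: float


class PhyloTree:
    """Rooted tree with branch lengths and uniquely labelled tips.

    Parameters
    ----------
    dendropy_tree :
        A parsed :class:`dendropy.Tree`.  Branch lengths are required on
        every edge except the root's own edge (treated as absent).  An
        unrooted newick whose basal node is a trifurcation is accepted with
        a warning, the basal node acting as root.
    """

    def __init__(self, dendropy_tree: dendropy.Tree):
        self._dtree = dendropy_tree
        root = dendropy_tree.seed_node
        if len(root.child_nodes()) > 2:
            warnings.warn(
                "tree root is a polytomy (likely an unrooted newick); "
                "treating the basal node as the root",
                stacklevel=2,
            )

        # Edge i belongs to the i-th non-root node in preorder.
        nodes = [nd for nd in dendropy_tree.preorder_node_iter() if nd is not root]
        lengths = np.empty(len(nodes), dtype=float)
        edge_of = {}
        for i, nd in enumerate(nodes):
            ln = nd.edge.length
            if ln is None:
                label = nd.taxon.label if nd.taxon else "<internal>"
                raise ValueError(f"missing branch length on edge above {label!r}")
            if ln < 0:
                raise ValueError("negative branch length")
            lengths[i] = ln
            edge_of[nd] = i

        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("unlabelled tip")
            labels.append(nd.taxon.label.strip("'"))
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")

        ancestry = np.zeros((len(tips), len(nodes)), dtype=bool)
        for t, nd in enumerate(tips):
            cur = nd
            while cur is not root:
                ancestry[t, edge_of[cur]] = True
                cur = cur.parent_node

        self.edge_lengths: np.ndarray = lengths
        self.tip_labels: list[str] = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        self.tip_ancestry: np.ndarray = ancestry
        # index of each tip's terminal edge
        self._terminal_edge = np.array([edge_of[nd] for nd in tips])

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dt)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        dt = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(dt)

    def to_newick(self) -> str:
        return self._dtree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        )

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_edges(self) -> int:
        return self.edge_lengths.size

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def terminal_branch_lengths(self) -> np.ndarray:
        """Length of each tip's terminal edge, in tip order."""
        return self.edge_lengths[self._terminal_edge]

    # ------------------------------------------------------------------
    def tip_indices(self, species: Iterable[str]) -> np.ndarray:
        idx = []
        for sp in species:
            try:
                idx.append(self._tip_index[sp])
            except KeyError:
                raise ReconciliationError(
                    f"species {sp!r} is not a tip of the tree"
                ) from None
        return np.asarray(idx, dtype=int)

    def incidence(self, species: Iterable[str]) -> np.ndarray:
        """Boolean edge mask of the union of tip-to-root paths."""
        idx = self.tip_indices(species)
        if idx.size == 0:
            raise ValueError("species set is empty")
        return self.tip_ancestry[idx].any(axis=0)

    def community_incidence(self, communities: Sequence[Community]) -> np.ndarray:
        """Site-by-edge boolean incidence matrix for many communities."""
        out = np.zeros((len(communities), self.n_edges), dtype=bool)
        for i, com in enumerate(communities):
            out[i] = self.incidence(com.species)
        return out


def spanning_branch_set(tree: PhyloTree, species: Iterable[str]) -> BranchSet:
    """Union of all edges on paths from the given tips up to the root.

    Its total length is Faith's PD of the set under the root-inclusive
    convention (a single tip spans its whole path to the root).
    """
    mask = tree.incidence(species)
    total = float(tree.edge_lengths[mask].sum())
    return BranchSet(frozenset(np.flatnonzero(mask).tolist()), total)


def faith_pd(tree: PhyloTree, species: Iterable[str]) -> float:
    """Faith's phylogenetic diversity: total spanning branch length."""
    mask = tree.incidence(species)
    return float(tree.edge_lengths[mask].sum())
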