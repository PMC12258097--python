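"""Asymmetric phylogenetic dissimilarity (Ruggiero-type) and uniqueness.

The index is the proportion of a focal community's branch length that is
*not* shared with a comparison community:

    beta_rlb.phylo(focal, other) = PD_unique / PD_total

with PD_total the focal community's spanning branch length and PD_unique the
part of it absent from the other community's spanning set.  The index is
asymmetric by construction, so pairwise values live in a square (not
triangular) matrix whose rows are focal sites; the row mean excluding the
diagonal is the site's phylogenetic uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .tree import Community, PhyloTree

__all__ = [
    "RugMatrix",
    "rug_phylo_pair",
    "rug_taxonomic_pair",
    "rug_matrix",
    "iter_rug_rows",
    "uniqueness",
]


@dataclass
class RugMatrix:
    """Square focal-row dissimilarity matrix (rows = focal sites)."""

    site_ids: list[str]
    values: np.ndarray  # (n, n), diagonal 0, not symmetric in general

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match site_ids")

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def to_long(self) -> pd.DataFrame:
        """Long format (focal_id, other_id, dissimilarity), diagonal excluded."""
        rows = []
        for i, fi in enumerate(self.site_ids):
            for j, oj in enumerate(self.site_ids):
                if i != j:
                    rows.append((fi, oj, self.values[i, j]))
        return pd.DataFrame(rows, columns=["focal_id", "other_id", "dissimilarity"])


def rug_phylo_pair(tree: PhyloTree, focal: Community, other: Community) -> float:
    """Fraction of the focal community's branch length unique to it.

    0 when the focal spanning set is nested in the other's, 1 when the two
    spanning sets are disjoint.
    """
    f = tree.incidence(focal.species)
    o = tree.incidence(other.species)
    lengths = tree.edge_lengths
    pd_total = float(lengths[f].sum())
    if pd_total == 0.0:
        raise ValueError(
            f"focal community {focal.site_id!r} has zero total branch length"
        )
    pd_unique = float(lengths[f & ~o].sum())
    return pd_unique / pd_total


def rug_taxonomic_pair(focal: Community, other: Community) -> float:
    """Taxonomic version: fraction of focal species absent from the other site."""
    return len(focal.species - other.species) / len(focal.species)


def _incidence_and_pd(tree: PhyloTree, communities: Sequence[Community]):
    inc = tree.community_incidence(communities)
    pd_tot = inc @ tree.edge_lengths
    if np.any(pd_tot == 0.0):
        bad = [c.site_id for c, p in zip(communities, pd_tot) if p == 0.0]
        raise ValueError(f"communities with zero total branch length: {bad}")
    return inc, pd_tot


def rug_matrix(tree: PhyloTree, communities: Sequence[Community]) -> RugMatrix:
    """All-pairs focal-row dissimilarity matrix.

    Shared branch length is computed from per-edge community incidence, so
    the n^2 pairs reduce to one boolean matrix product.
    """
    ids = [c.site_id for c in communities]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site_ids in community list")
    if len(communities) < 2:
        raise ValueError("need at least 2 communities")
    inc, pd_tot = _incidence_and_pd(tree, communities)
    weighted = inc * tree.edge_lengths  # (n, E)
    shared = inc @ weighted.T  # shared[i, j] = length of edges in both
    values = (pd_tot[:, None] - shared) / pd_tot[:, None]
    np.clip(values, 0.0, 1.0, out=values)  # guard float round-off only
    np.fill_diagonal(values, 0.0)
    return RugMatrix(ids, values)


def iter_rug_rows(
    tree: PhyloTree, communities: Sequence[Community]
) -> Iterator[tuple[str, np.ndarray]]:
    """Stream focal rows one at a time (diagonal entry set to 0).

    Memory-light alternative to materialising the full square matrix: each
    yielded row can be consumed by a distance-increase fit and discarded.
    """
    inc, pd_tot = _incidence_and_pd(tree, communities)
    for i, com in enumerate(communities):
        shared = inc @ (tree.edge_lengths * inc[i])
        row = (pd_tot[i] - shared) / pd_tot[i]
        np.clip(row, 0.0, 1.0, out=row)
        row[i] = 0.0
        yield com.site_id, row


def uniqueness(matrix: RugMatrix) -> pd.Series:
    """Per-site phylogenetic uniqueness: row mean excluding the diagonal."""
    n = matrix.n
    if n < 2:
        raise ValueError("uniqueness needs at least 2 sites")
    vals = matrix.values.sum(axis=1) / (n - 1)  # diagonal is exactly 0
    return pd.Series(vals, index=matrix.site_ids, name="uniqueness")
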