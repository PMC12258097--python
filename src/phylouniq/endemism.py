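"""Phylogenetic endemism (Rosauer) and the PE-vs-uniqueness discrepancy.

Phylogenetic endemism at a site is the range-weighted branch length

    PE_i = sum over edges b in site i's spanning set of  L_b / R_b

where L_b is the branch length and R_b the number of sites whose spanning
set contains edge b (equivalently, sites holding at least one descendant tip
of b).  Because each edge's contributions across sites sum to exactly L_b,
the site PEs sum to the PD of the union of all occupied sites — an identity
used as an exact invariant test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tree import Community, PhyloTree

__all__ = ["phylo_endemism", "DiscrepancyResult", "discrepancy_analysis"]


def phylo_endemism(tree: PhyloTree, communities: Sequence[Community]) -> pd.Series:
    """Per-site phylogenetic endemism, in the tree's branch-length units."""
    if not communities:
        raise ValueError("need at least one community")
    inc = tree.community_incidence(communities)
    ranges = inc.sum(axis=0)  # R_b: number of sites containing each edge
    weights = np.divide(
        tree.edge_lengths,
        ranges,
        out=np.zeros_like(tree.edge_lengths),
        where=ranges > 0,
    )
    pe = inc @ weights
    return pd.Series(pe, index=[c.site_id for c in communities], name="pe")


def _minmax(x: np.ndarray) -> tuple[np.ndarray, bool]:
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x), True
    return (x - x.min()) / span, False


@dataclass
class DiscrepancyResult:
    """OLS of (standardised PE - standardised uniqueness) on log richness."""

    difference: pd.Series  # per-site standardised difference
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def discrepancy_analysis(
    pe: pd.Series, uniq: pd.Series, richness: pd.Series
) -> DiscrepancyResult:
    """Does the PE/uniqueness mismatch depend on species richness?

    Both variables are min-max standardised to [0, 1] over the analysed
    sites, their difference taken, and regressed on natural-log richness by
    ordinary least squares.  The log base only rescales the slope.
    """
    if not (pe.index.equals(uniq.index) and pe.index.equals(richness.index)):
        raise ValueError("site_ids of pe, uniqueness and richness must align")
    if len(pe) < 3:
        raise ValueError("regression needs at least 3 sites")
    pe_s, deg1 = _minmax(pe.to_numpy(dtype=float))
    un_s, deg2 = _minmax(uniq.to_numpy(dtype=float))
    if deg1 or deg2:
        warnings.warn(
            "constant PE or uniqueness vector: standardisation degenerates, "
            "reporting zeros",
            stacklevel=2,
        )
    diff = pd.Series(pe_s - un_s, index=pe.index, name="discrepancy")
    if np.allclose(diff.to_numpy(), diff.iloc[0]):
        # no variance to explain; r^2 reported as 0
        if not (deg1 or deg2):
            warnings.warn("discrepancy is constant; r^2 reported as 0", stacklevel=2)
        return DiscrepancyResult(diff, 0.0, float(diff.iloc[0]), 0.0, degenerate=True)
    x = sm.add_constant(np.log(richness.to_numpy(dtype=float)))
    fit = sm.OLS(diff.to_numpy(), x).fit()
    return DiscrepancyResult(
        diff,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
    )
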