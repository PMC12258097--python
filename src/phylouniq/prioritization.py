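"""Area-accumulation curves of cumulative Faith's PD under site orderings.

Sites are added in descending order of a per-site criterion (phylogenetic
endemism, uniqueness, richness, PD, EDGE-score sum, EDGE richness) and the
PD of the growing union of communities is tracked as a fraction of the PD
of the union of all analysed sites.  The curve answers: how fast does a
given prioritisation criterion accumulate total evolutionary history per
unit of protected area?  These curves rank simple per-site criteria; they
are not a complementarity-based reserve-selection algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Community, PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["PrioritizationCurve", "edge_metrics", "accumulation_curve"]

CRITERIA = ("pe", "uniqueness", "richness", "pd", "edge_sum", "edge_richness")


@dataclass
class PrioritizationCurve:
    criterion: str
    site_ids: list[str]  # in accumulation order
    area_fraction: np.ndarray  # k/n, strictly increasing to 1
    cum_pd_fraction: np.ndarray  # non-decreasing, final value 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": self.criterion,
                "step": np.arange(1, len(self.site_ids) + 1),
                "site_id": self.site_ids,
                "area_fraction": self.area_fraction,
                "cum_pd_fraction": self.cum_pd_fraction,
            }
        )

    def auc(self) -> float:
        """Area under the curve (trapezoid from the origin), in [0, 1]."""
        x = np.concatenate([[0.0], self.area_fraction])
        y = np.concatenate([[0.0], self.cum_pd_fraction])
        return float(np.trapezoid(y, x))


def edge_metrics(
    communities: Sequence[Community],
    scores: Mapping[str, float],
    edge_species: set[str],
) -> pd.DataFrame:
    """Per-site sum of EDGE scores and count of EDGE-listed species.

    Species missing from the score table count as 0 (the number of such
    species is logged); the EDGE flag set is independent of the scores.
    """
    missing: set[str] = set()
    rows = []
    for com in communities:
        total = 0.0
        for sp in com.species:
            if sp in scores:
                total += float(scores[sp])
            else:
                missing.add(sp)
        rows.append(
            (com.site_id, total, sum(1 for sp in com.species if sp in edge_species))
        )
    if missing:
        logger.info("edge_metrics: %d species missing from score table", len(missing))
    return pd.DataFrame(rows, columns=["site_id", "edge_sum", "edge_richness"]).set_index(
        "site_id"
    )


def accumulation_curve(
    tree: PhyloTree,
    communities: Sequence[Community],
    order_scores: Mapping[str, float],
    criterion_name: str,
) -> PrioritizationCurve:
    """Cumulative PD fraction as sites accumulate in descending score order.

    Ties are broken by ascending site_id (deterministic).  The union branch
    set is grown incrementally (boolean OR of edge incidences), so each
    prefix PD is exact, not approximated.
    """
    if not communities:
        raise ValueError("need at least one community")
    coms = sorted(communities, key=lambda c: (-float(order_scores[c.site_id]), c.site_id))
    inc = tree.community_incidence(coms)
    lengths = tree.edge_lengths
    total_pd = float(lengths[inc.any(axis=0)].sum())
    n = len(coms)
    cum = np.zeros(tree.n_edges, dtype=bool)
    cum_pd = np.empty(n)
    for k in range(n):
        cum |= inc[k]
        cum_pd[k] = lengths[cum].sum()
    return PrioritizationCurve(
        criterion=criterion_name,
        site_ids=[c.site_id for c in coms],
        area_fraction=np.arange(1, n + 1) / n,
        cum_pd_fraction=cum_pd / total_pd,
    )
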