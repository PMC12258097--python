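"""Landscape-level model: the full scale-explicit uniqueness analysis.

``PhyloUniquenessModel`` bundles a reconciled tree + community matrix +
site centroids (plus optional per-species conservation scores) and its
``fit()`` runs the whole pipeline: the asymmetric dissimilarity matrix and
per-site uniqueness, phylogenetic endemism and Faith's PD, the geodesic
distance matrix, one distance-increase GLM per focal site, the
hill/island classification, and the endemism-vs-uniqueness discrepancy
regression.  The returned ``PhyloUniquenessResults`` carries every table and
exposes accumulation curves, group contrasts, plots and a text summary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import beta, classification, endemism, io, prioritization, scaling, spatial
from .spatial import SiteCoordinates
from .tree import Community, PhyloTree, faith_pd

__all__ = ["PhyloUniquenessModel", "PhyloUniquenessResults"]


class PhyloUniquenessModel:
    """Scale-explicit phylogenetic uniqueness analysis of one landscape."""

    def __init__(
        self,
        tree: PhyloTree,
        matrix: pd.DataFrame,
        coordinates: Sequence[SiteCoordinates],
        species_scores: Mapping[str, float] | None = None,
        edge_species: set[str] | None = None,
        min_richness: int = 5,
        distance_method: str = "haversine",
    ):
        matrix, self.reconcile_report = io.reconcile(tree, matrix)
        matrix, self.filter_report = io.filter_sites(matrix, min_richness)
        coord_by_id = {c.site_id: c for c in coordinates}
        missing = [s for s in matrix.index if s not in coord_by_id]
        if missing:
            raise io.InputError(f"sites without coordinates: {missing[:5]}")
        self.tree = tree
        self.matrix = matrix
        self.coordinates = [coord_by_id[s] for s in matrix.index]
        self.species_scores = dict(species_scores or {})
        self.edge_species = set(edge_species or set())
        self.min_richness = min_richness
        self.distance_method = distance_method
        self.communities: list[Community] = io.matrix_to_communities(matrix)

    @classmethod
    def from_files(
        cls,
        tree_path,
        matrix_path,
        coords_path,
        scores_path=None,
        **kwargs,
    ) -> "PhyloUniquenessModel":
        scores, flags = ({}, set())
        if scores_path is not None:
            scores, flags = io.read_species_scores(scores_path)
            scores = scores.to_dict()
        return cls(
            io.read_tree(tree_path),
            io.read_community_matrix(matrix_path),
            io.read_coordinates(coords_path),
            species_scores=scores,
            edge_species=flags,
            **kwargs,
        )

    def fit(self, quartile_reference: str = "all") -> "PhyloUniquenessResults":
        rug = beta.rug_matrix(self.tree, self.communities)
        uniq = beta.uniqueness(rug)
        pe = endemism.phylo_endemism(self.tree, self.communities)
        dist = spatial.geodesic_matrix(self.coordinates, method=self.distance_method)
        fits = scaling.fit_all(rug, dist)
        classes = classification.classify_sites(pe, fits, reference=quartile_reference)
        return PhyloUniquenessResults(self, rug, uniq, pe, dist, fits, classes)


class PhyloUniquenessResults:
    """All per-site estimates of a fitted landscape analysis."""

    def __init__(self, model, rug, uniq, pe, distances, fits, classes):
        self.model = model
        self.rug: beta.RugMatrix = rug
        self.uniqueness: pd.Series = uniq
        self.pe: pd.Series = pe
        self.distances: pd.DataFrame = distances
        self.fits: list[scaling.ScalingFit] = fits
        self.classification: list[classification.SiteClassification] = classes

        richness = model.matrix.sum(axis=1).astype(int)
        pd_local = pd.Series(
            [faith_pd(model.tree, c.species) for c in model.communities],
            index=model.matrix.index, name="pd",
        )
        table = pd.DataFrame({"richness": richness, "pd": pd_local})
        table["pe"] = self.pe
        table["uniqueness"] = self.uniqueness
        em = prioritization.edge_metrics(
            model.communities, model.species_scores, model.edge_species
        )
        table = table.join(em)
        table = table.join(scaling.fits_to_frame(fits))
        table = table.join(classification.classification_to_frame(classes))
        table.index.name = "site_id"
        self.site_table: pd.DataFrame = table

    # ------------------------------------------------------------------
    @property
    def discrepancy(self) -> endemism.DiscrepancyResult:
        return endemism.discrepancy_analysis(
            self.pe, self.uniqueness, self.site_table["richness"]
        )

    def accumulation_curves(
        self, criteria: Sequence[str] | None = None
    ) -> dict[str, prioritization.PrioritizationCurve]:
        """One curve per prioritisation criterion (descending order)."""
        criteria = list(criteria or prioritization.CRITERIA)
        curves = {}
        for crit in criteria:
            if crit not in self.site_table.columns:
                raise ValueError(f"unknown criterion {crit!r}")
            scores = self.site_table[crit].to_dict()
            curves[crit] = prioritization.accumulation_curve(
                self.model.tree, self.model.communities, scores, crit
            )
        return curves

    def group_contrast(self, include_both: bool = False) -> pd.DataFrame:
        return classification.group_contrast(
            self.classification, self.site_table, include_both=include_both
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        t = self.site_table
        labels = t["label"].value_counts()
        disc = self.discrepancy
        lines = [
            "Scale-explicit phylogenetic uniqueness analysis",
            "=" * 47,
            f"sites analysed            {len(t)}",
            f"species (tips in matrix)  {self.model.matrix.shape[1]}",
            f"tree total branch length  {self.model.tree.total_length:.4f}",
            f"mean uniqueness           {t['uniqueness'].mean():.4f}",
            f"mean PE                   {t['pe'].mean():.4f}",
            f"distance-increase fits    {int(t['converged'].sum())}/{len(t)} converged",
            f"median dissim. intercept  {t['dissimilarity_intercept'].median():.4f}",
            f"median slope metric (-b)  {t['slope_metric'].median():.3e} per km",
            f"top-PE-quartile sites     {int(t['in_top_pe_quartile'].sum())}",
            "labels: "
            + ", ".join(f"{k}={int(v)}" for k, v in labels.items()),
            f"PE-uniqueness discrepancy vs log richness: "
            f"r^2={disc.r_squared:.3f}, slope={disc.slope:.4f}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_accumulation(self, criteria=None, ax=None):
        """PD fraction vs area fraction, one line per criterion."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for crit, curve in self.accumulation_curves(criteria).items():
            ax.plot(
                np.concatenate([[0.0], curve.area_fraction]),
                np.concatenate([[0.0], curve.cum_pd_fraction]),
                label=crit,
            )
        ax.set_xlabel("fraction of area (sites)")
        ax.set_ylabel("cumulative fraction of Faith's PD")
        ax.legend()
        return ax

    def plot_scaling(self, site_id: str, ax=None):
        """A focal site's dissimilarities vs distance with its fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ids = self.rug.site_ids
        i = ids.index(site_id)
        mask = np.arange(len(ids)) != i
        s = self.distances.to_numpy()[i, mask]
        d = self.rug.values[i, mask]
        ax.scatter(s, d, s=12, alpha=0.6)
        fit = next(f for f in self.fits if f.site_id == site_id)
        if np.isfinite(fit.a):
            grid = np.linspace(0, s.max(), 200)
            ax.plot(grid, 1 - fit.a * np.exp(fit.b * grid), "r-")
        ax.set_xlabel("distance (km)")
        ax.set_ylabel("phylogenetic dissimilarity")
        ax.set_title(site_id)
        return ax
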