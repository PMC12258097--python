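"""Synthetic landscapes with planted evolutionary hills and islands.

The generator emulates the structure of a gridded presence/absence dataset
reconciled to a dated phylogeny: a pure-birth ultrametric tree over the
species pool, a rectangular lattice of site centroids in degree space, and
spatially autocorrelated ranges (each species occupies all sites within a
circular radius of a random range centre), which makes compositional
similarity decay with distance.  Two structures are planted with known
ground truth:

* **islands** — a few sites receive a private endemic clade whose tips are
  (with probability = isolation strength) found nowhere else, while
  overlapping widespread species are excluded from the island with that
  same probability.  These sites should be recovered as top-quartile
  endemism with a high dissimilarity intercept.
* **hills** — range radii shrink toward the western edge of the lattice, so
  western communities turn over faster in space: steep distance-increase
  slopes without nearest-neighbour isolation.

It does not attempt macroevolutionary realism (no trait-dependent
diversification, no dispersal kernels, no climate surfaces); the spatial
unit is the degree lattice itself.  All randomness flows from a single
integer seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .spatial import SiteCoordinates
from .tree import Community, PhyloTree

__all__ = [
    "LandscapeRecipe",
    "Landscape",
    "GenerationError",
    "generate_tree",
    "generate_landscape",
    "generate_species_scores",
]


class GenerationError(RuntimeError):
    """The recipe cannot produce a landscape meeting its own constraints."""


@dataclass(frozen=True)
class LandscapeRecipe:
    """Parameters of a synthetic landscape.

    Defaults are the package's reference study conditions: a 10x10 degree
    lattice of 100 sites, 200 species, three island sites each carrying an
    8-tip endemic clade at isolation 0.9, mainland range radii growing from
    1.2 deg (west) to 4.0 deg (east), and the 5-species minimum-richness
    filter applied before analysis.
    """

    n_sites: int = 100
    extent_deg: float = 9.0  # lattice spans [0, extent] in lon and lat
    n_species: int = 200
    birth_rate: float = 1.0
    range_radius_min: float = 2.2  # deg, at the western edge
    range_radius_max: float = 5.0  # deg, at the eastern edge
    n_islands: int = 3
    endemic_clade_size: int = 8
    isolation: float = 0.9  # in [0, 1]
    min_richness: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.isolation <= 1.0):
            raise ValueError("isolation must lie in [0, 1]")
        for name in ("n_sites", "n_species", "extent_deg", "birth_rate",
                     "range_radius_min", "range_radius_max", "min_richness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Landscape:
    tree: PhyloTree
    coordinates: list[SiteCoordinates]
    matrix: pd.DataFrame  # sites x species, binary, after richness filter
    island_sites: list[str]  # planted ground truth
    hill_sites: list[str]  # steep-turnover-zone ground truth
    recipe: LandscapeRecipe

    @property
    def communities(self) -> list[Community]:
        return [
            Community(sid, frozenset(self.matrix.columns[row.to_numpy(bool)]))
            for sid, row in self.matrix.iterrows()
        ]


def generate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Reproducible pure-birth (Yule) ultrametric tree.

    Tips are relabelled sp0001.. in a deterministic traversal order, so the
    newick string is identical for identical seeds.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    dt = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(dt.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return PhyloTree(dt)


def _lattice(n_sites: int, extent: float) -> list[SiteCoordinates]:
    nx = int(round(np.sqrt(n_sites)))
    ny = int(np.ceil(n_sites / nx))
    coords = []
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            if k >= n_sites:
                break
            lon = extent * ix / max(nx - 1, 1)
            lat = extent * iy / max(ny - 1, 1)
            coords.append(SiteCoordinates(f"s{k:04d}", lon, lat))
            k += 1
    return coords


def _endemic_clade(tree: PhyloTree, size: int, used: set[str]) -> list[str]:
    """Tips of the deepest unused clade with between size and 2*size tips.

    Long-term isolation leaves an old, branch-rich endemic clade, so among
    candidate clades of acceptable size the one with the greatest total
    subtree branch length (stem included) is planted.  Deterministic given
    the tree.
    """
    best: tuple[float, int, list[str]] | None = None
    for nd in tree._dtree.postorder_node_iter():
        if nd.is_leaf():
            continue
        tips = [lf.taxon.label for lf in nd.leaf_iter()]
        if not (size <= len(tips) <= 2 * size) or (set(tips) & used):
            continue
        length = sum(
            ch.edge.length or 0.0 for ch in nd.preorder_iter() if ch is not nd
        )
        length += nd.edge.length or 0.0
        cand = (length, -len(tips), sorted(tips))
        if best is None or cand > best:
            best = cand
    if best is None:
        raise GenerationError(
            "no unused clade of the requested endemic size; "
            "reduce n_islands or endemic_clade_size"
        )
    return best[2]


def generate_landscape(recipe: LandscapeRecipe = LandscapeRecipe()) -> Landscape:
    """Build tree, coordinates and community matrix with planted structure."""
    rng = np.random.default_rng(recipe.seed)
    tree = generate_tree(
        recipe.n_species, recipe.birth_rate, seed=int(rng.integers(2**31))
    )
    coords = _lattice(recipe.n_sites, recipe.extent_deg)
    xy = np.array([(c.longitude, c.latitude) for c in coords])
    site_ids = [c.site_id for c in coords]
    n_sites = len(coords)
    species = list(tree.tip_labels)

    # pick island sites and their private endemic clades
    island_idx = sorted(
        rng.choice(n_sites, size=recipe.n_islands, replace=False).tolist()
    )
    island_sites = [site_ids[i] for i in island_idx]
    used: set[str] = set()
    endemics_of: dict[int, list[str]] = {}
    for i in island_idx:
        clade = _endemic_clade(tree, recipe.endemic_clade_size, used)
        used |= set(clade)
        endemics_of[i] = clade

    occ = np.zeros((n_sites, len(species)), dtype=bool)
    col = {sp: j for j, sp in enumerate(species)}

    # mainland species: circular ranges, radius growing west -> east
    for sp in species:
        j = col[sp]
        is_endemic = sp in used
        if is_endemic and rng.random() < recipe.isolation:
            continue  # exclusive to its island; range assigned below
        centre = rng.uniform(0.0, recipe.extent_deg, size=2)
        frac_east = centre[0] / recipe.extent_deg
        radius = recipe.range_radius_min + frac_east * (
            recipe.range_radius_max - recipe.range_radius_min
        )
        dist = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
        occ[:, j] |= dist <= radius

    # island assembly: endemic clade present; overlapping widespread species
    # excluded with probability = isolation strength
    for i in island_idx:
        keep = rng.random(len(species)) >= recipe.isolation
        occ[i] &= keep
        for sp in endemics_of[i]:
            occ[i, col[sp]] = True

    matrix = pd.DataFrame(occ.astype(np.int8), index=site_ids, columns=species)
    richness = matrix.sum(axis=1)
    retained = richness[richness >= recipe.min_richness].index
    if len(retained) < 4:
        raise GenerationError(
            "fewer than 4 sites satisfy min_richness; enlarge range radii"
        )
    missing_islands = [s for s in island_sites if s not in set(retained)]
    if missing_islands:
        raise GenerationError(
            f"island site(s) {missing_islands} fail the min_richness filter; "
            "increase endemic_clade_size"
        )
    matrix = matrix.loc[retained]
    # drop species left with no occurrences after the site filter
    matrix = matrix.loc[:, matrix.sum(axis=0) > 0]
    coords = [c for c in coords if c.site_id in set(retained)]

    west_cut = recipe.extent_deg / 3.0
    hill_sites = [
        c.site_id
        for c in coords
        if c.longitude <= west_cut and c.site_id not in island_sites
    ]
    return Landscape(tree, coords, matrix, island_sites, hill_sites, recipe)


def generate_species_scores(
    tree: PhyloTree, seed: int = 0, noise_sd: float = 0.35
) -> tuple[pd.Series, set[str]]:
    """Per-species conservation scores plus a flagged top decile.

    Scores are proportional to terminal branch length (an evolutionary
    distinctiveness proxy) with multiplicative lognormal noise, mimicking
    the rank structure of EDGE-style scores; the top ceil(n/10) species by
    score form the flag set.
    """
    rng = np.random.default_rng(seed)
    tbl = tree.terminal_branch_lengths()
    noise = np.exp(rng.normal(0.0, noise_sd, size=tbl.size))
    scores = pd.Series(tbl * noise, index=tree.tip_labels, name="score")
    k = int(np.ceil(len(scores) / 10))
    flagged = set(scores.sort_values(ascending=False).index[:k])
    return scores, flagged
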