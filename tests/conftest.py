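"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately avoid the package's array machinery: they
walk dendropy node objects tip-to-root and manipulate explicit Python sets
of edges, so agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

import random

import dendropy
import pytest

from phylouniq.tree import Community, PhyloTree


FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_tip_tree() -> PhyloTree:
    return PhyloTree.from_newick(FOUR_TIP_NEWICK)


def com(site_id: str, *species: str) -> Community:
    return Community(site_id, frozenset(species))


# ---------------------------------------------------------------------------
# brute-force oracles on raw dendropy trees
# ---------------------------------------------------------------------------

def brute_branch_edges(dtree: dendropy.Tree, species: set[str]) -> set:
    """Explicit union of tip-to-root edge paths (set of edge objects)."""
    edges = set()
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon.label in species:
            nd = leaf
            while nd.parent_node is not None:
                edges.add(nd.edge)
                nd = nd.parent_node
    return edges


def brute_pd(dtree: dendropy.Tree, species: set[str]) -> float:
    return sum(e.length for e in brute_branch_edges(dtree, species))


def brute_rug(dtree: dendropy.Tree, focal: set[str], other: set[str]) -> float:
    f = brute_branch_edges(dtree, focal)
    o = brute_branch_edges(dtree, other)
    total = sum(e.length for e in f)
    unique = sum(e.length for e in f - o)
    return unique / total


def random_tree(rng: random.Random, n_tips: int) -> dendropy.Tree:
    """Random binary topology with uniform branch lengths in (0, 2]."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = rng.uniform(1e-3, 2.0)
    return tree


def star_newick(n_tips: int, length: float = 1.0) -> str:
    tips = ",".join(f"t{i}:{length}" for i in range(n_tips))
    return f"({tips});"
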