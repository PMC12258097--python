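"""Readers, writers, reconciliation and the minimum-richness filter.

All tabular formats are plain CSV.  The community matrix is accepted either
dense (first column ``site_id``, remaining columns species, 0/1 cells) or as
sparse triplets (columns ``site_id, species[, presence]``), auto-detected
from the header.  Numeric outputs are written with 17 significant digits so
write-then-read round-trips are exact at double precision.  Output files
carry the run seed as a leading ``# seed=N`` comment line, which every
reader skips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beta import RugMatrix
from .spatial import SiteCoordinates
from .tree import Community, PhyloTree

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


class InputError(ValueError):
    """Malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_tree(path) -> PhyloTree:
    return PhyloTree.from_file(path)


def read_community_matrix(path) -> pd.DataFrame:
    """Site-by-species binary matrix from dense or sparse-triplet CSV."""
    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) >= 2 and cols[0] == "site_id" and cols[1] == "species":
        # sparse triplets
        wide = (
            df.assign(_p=1)
            .pivot_table(
                index=df.columns[0], columns=df.columns[1], values="_p",
                aggfunc="max", fill_value=0,
            )
            .astype(np.int8)
        )
        wide.index = wide.index.astype(str)
        wide.index.name = "site_id"
        wide.columns.name = None
        return wide
    mat = df.set_index(df.columns[0])
    mat.index = mat.index.astype(str)
    mat.index.name = "site_id"
    vals = mat.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise InputError("community matrix must be binary (0/1)")
    return mat.astype(np.int8)


def read_coordinates(path) -> list[SiteCoordinates]:
    df = pd.read_csv(path, comment="#")
    needed = {"site_id", "lon", "lat"}
    if not needed.issubset({c.strip().lower() for c in df.columns}):
        raise InputError("coordinates CSV needs columns site_id, lon, lat")
    df.columns = [c.strip().lower() for c in df.columns]
    out = [
        SiteCoordinates(str(r.site_id), float(r.lon), float(r.lat))
        for r in df.itertuples()
    ]
    if len({c.site_id for c in out}) != len(out):
        raise InputError("duplicate site_ids in coordinates")
    return out


def read_species_scores(path) -> tuple[pd.Series, set[str]]:
    """Two-column (species, score) CSV; optional third boolean column of
    EDGE-list flags.  Without flags, the flag set is empty."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns or "score" not in df.columns:
        raise InputError("scores CSV needs columns species, score")
    scores = pd.Series(
        df["score"].to_numpy(float), index=df["species"].astype(str), name="score"
    )
    flags: set[str] = set()
    if "edge_flag" in df.columns:
        flags = set(df.loc[df["edge_flag"].astype(bool), "species"].astype(str))
    return scores, flags


def read_square_matrix(path) -> RugMatrix:
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    return RugMatrix(list(df.index), df.to_numpy(float))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path, seed: int | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, float_format=FLOAT_FMT, index=index)


def write_matrix_csv(matrix: RugMatrix, path, seed: int | None = None) -> None:
    _write_csv(matrix.to_frame(), path, seed, index=True)


def write_long_matrix_csv(matrix: RugMatrix, path, seed: int | None = None) -> None:
    _write_csv(matrix.to_long(), path, seed, index=False)


def write_table(df: pd.DataFrame, path, seed: int | None = None, index: bool = True) -> None:
    _write_csv(df, path, seed, index=index)


def write_coordinates(coords: list[SiteCoordinates], path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {"site_id": [c.site_id for c in coords],
         "lon": [c.longitude for c in coords],
         "lat": [c.latitude for c in coords]}
    )
    _write_csv(df, path, seed, index=False)


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(tree.to_newick())


# ---------------------------------------------------------------------------
# reconciliation and filtering
# ---------------------------------------------------------------------------

@dataclass
class ReconcileReport:
    dropped_species: list[str] = field(default_factory=list)
    n_dropped: int = 0
    n_matched: int = 0


def reconcile(tree: PhyloTree, matrix: pd.DataFrame) -> tuple[pd.DataFrame, ReconcileReport]:
    """Drop matrix species absent from the tree's tips.

    Tree tips absent from the matrix are retained in the tree; under the
    root-inclusive convention they only contribute edges that no community
    spans, which affects nothing downstream.
    """
    tips = set(tree.tip_labels)
    present = [c for c in matrix.columns if c in tips]
    dropped = sorted(c for c in matrix.columns if c not in tips)
    if not present:
        raise InputError("no matrix species match the tree's tips")
    report = ReconcileReport(dropped, len(dropped), len(present))
    if dropped:
        logger.info("reconcile: dropped %d species not in tree: %s",
                    len(dropped), ", ".join(dropped[:10]))
    return matrix[present], report


@dataclass
class FilterReport:
    n_removed: int = 0
    removed_sites: list[str] = field(default_factory=list)


def filter_sites(matrix: pd.DataFrame, min_richness: int = 5) -> tuple[pd.DataFrame, FilterReport]:
    """Remove sites with fewer than ``min_richness`` species (idempotent)."""
    richness = matrix.sum(axis=1)
    keep = richness >= min_richness
    removed = sorted(matrix.index[~keep].astype(str))
    if not keep.any():
        raise InputError(f"all sites fall below min_richness={min_richness}")
    if removed:
        logger.info("filter_sites: removed %d site(s) below richness %d",
                    len(removed), min_richness)
    return matrix.loc[keep], FilterReport(len(removed), removed)


def matrix_to_communities(matrix: pd.DataFrame) -> list[Community]:
    cols = np.asarray(matrix.columns)
    return [
        Community(str(sid), frozenset(cols[row.to_numpy().astype(bool)]))
        for sid, row in matrix.iterrows()
    ]
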