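"""Evolutionary hills versus evolutionary islands.

High-endemism sites (top quartile of phylogenetic endemism) are classified
by how their uniqueness scales with distance:

* **hill** — top-quartile slope metric (-b): uniqueness accrues gradually
  with distance; globally distinct but regionally ordinary.
* **island** — top-quartile dissimilarity intercept (1 - a): unique even to
  the nearest neighbours, the signature of long-term isolation.
* **both** — top quartile in slope and intercept; **neither** otherwise.

Quartile thresholds for slope and intercept are computed over all analysed
sites by default (a ``reference`` switch restricts them to the top-PE sites
instead).  Group contrasts between hills and islands use two-sided Wilcoxon
rank-sum tests in the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scaling import ScalingFit

__all__ = [
    "SiteClassification",
    "top_quartile_flags",
    "classify_sites",
    "classification_to_frame",
    "group_contrast",
    "multi_taxon_overlap",
]


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    in_top_pe_quartile: bool
    label: str  # hill | island | both | neither


def top_quartile_flags(values: pd.Series) -> pd.Series:
    """Flag values at or above the 75th percentile (linear interpolation).

    Ties at the threshold are included, so between 25% and 100% of sites
    can be flagged.
    """
    if len(values) < 4:
        raise ValueError("quartile flags need at least 4 sites")
    v = values.to_numpy(dtype=float)
    threshold = np.percentile(v, 75, method="linear")
    return pd.Series(v >= threshold, index=values.index, name=f"top_{values.name}")


def classify_sites(
    pe: pd.Series,
    fits: Sequence[ScalingFit],
    reference: str = "all",
) -> list[SiteClassification]:
    """Label each site hill / island / both / neither.

    Unconverged fits are excluded from the quartile computation, labelled
    ``neither`` and counted in a warning.  ``reference`` selects the
    population over which slope/intercept quartiles are computed: ``"all"``
    analysed sites (default) or ``"top_pe"`` sites only.
    """
    if reference not in ("all", "top_pe"):
        raise ValueError("reference must be 'all' or 'top_pe'")
    fit_by_id = {f.site_id: f for f in fits}
    ids = list(pe.index)
    if set(fit_by_id) != set(ids):
        raise ValueError("site_ids of pe and fits must align")
    top_pe = top_quartile_flags(pe.rename("pe"))

    ok = [f for f in fit_by_id.values() if f.converged and np.isfinite(f.a)]
    n_bad = len(fits) - len(ok)
    if n_bad:
        warnings.warn(
            f"{n_bad} unconverged fit(s) excluded from quartiles and labelled "
            "'neither'",
            stacklevel=2,
        )
    ref_ids = [f.site_id for f in ok if reference == "all" or top_pe[f.site_id]]
    slope = pd.Series(
        {f.site_id: f.slope_metric for f in ok}, name="slope_metric"
    )
    icpt = pd.Series(
        {f.site_id: f.dissimilarity_intercept for f in ok},
        name="dissimilarity_intercept",
    )
    if not ref_ids:
        raise ValueError("no converged fits in the quartile reference population")
    slope_thr = np.percentile(slope.loc[ref_ids], 75, method="linear")
    icpt_thr = np.percentile(icpt.loc[ref_ids], 75, method="linear")

    out = []
    for sid in ids:
        f = fit_by_id[sid]
        usable = f.converged and np.isfinite(f.a)
        if not (top_pe[sid] and usable):
            out.append(SiteClassification(sid, bool(top_pe[sid]), "neither"))
            continue
        hi_slope = f.slope_metric >= slope_thr
        hi_icpt = f.dissimilarity_intercept >= icpt_thr
        if hi_slope and hi_icpt:
            label = "both"
        elif hi_icpt:
            label = "island"
        elif hi_slope:
            label = "hill"
        else:
            label = "neither"
        out.append(SiteClassification(sid, True, label))
    return out


def classification_to_frame(classes: Sequence[SiteClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [c.site_id for c in classes],
            "in_top_pe_quartile": [c.in_top_pe_quartile for c in classes],
            "label": [c.label for c in classes],
        }
    ).set_index("site_id")


def group_contrast(
    classes: Sequence[SiteClassification],
    scores: pd.DataFrame,
    include_both: bool = False,
) -> pd.DataFrame:
    """Hills vs islands: richness, PE per species, EDGE score per species.

    ``scores`` must carry columns richness, pe and (optionally) edge_sum
    indexed by site_id.  Sites labelled ``both`` are excluded from the two
    contrast groups unless ``include_both``.  Returns one row per
    (group, metric) with n, median, mean and the shared two-sided Wilcoxon
    rank-sum p-value of the hill-island contrast.
    """
    labels = {c.site_id: c.label for c in classes}
    wanted_h = ("hill", "both") if include_both else ("hill",)
    wanted_i = ("island", "both") if include_both else ("island",)
    hills = [s for s, l in labels.items() if l in wanted_h]
    islands = [s for s, l in labels.items() if l in wanted_i]
    if not hills or not islands:
        raise ValueError("both groups must be non-empty")

    derived = pd.DataFrame(index=scores.index)
    derived["richness"] = scores["richness"].astype(float)
    derived["pe_per_species"] = scores["pe"] / scores["richness"]
    metrics = ["richness", "pe_per_species"]
    if "edge_sum" in scores.columns:
        derived["edge_per_species"] = scores["edge_sum"] / scores["richness"]
        metrics.append("edge_per_species")

    rows = []
    for metric in metrics:
        x = derived.loc[hills, metric].to_numpy()
        y = derived.loc[islands, metric].to_numpy()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(
                f"group with fewer than 2 sites: Wilcoxon test skipped for {metric}",
                stacklevel=2,
            )
            p = np.nan
        else:
            # rank-sum, normal approximation, tie + continuity corrections
            p = float(
                stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic",
                    use_continuity=True,
                ).pvalue
            )
        for group, vals in (("hill", x), ("island", y)):
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "mean": float(np.mean(vals)),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def multi_taxon_overlap(
    flags_by_taxon: Mapping[str, pd.Series], site_ids: Sequence[str] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Cross-taxon concordance of top-endemism flags.

    ``flags_by_taxon`` maps taxon name to a boolean Series indexed by
    site_id; sites missing from a taxon count as unflagged.  Returns the
    per-site count of taxa flagging it (0..k) and a summary with the
    fraction of sites at each exact count and at "at least m" counts.
    """
    if site_ids is None:
        universe: list[str] = sorted(
            set().union(*(set(f.index) for f in flags_by_taxon.values()))
        )
    else:
        universe = list(site_ids)
    k = len(flags_by_taxon)
    counts = pd.Series(0, index=universe, dtype=int, name="n_taxa")
    for flags in flags_by_taxon.values():
        aligned = flags.reindex(universe, fill_value=False).astype(bool)
        counts += aligned.astype(int)
    n = len(universe)
    rows = []
    for m in range(k + 1):
        rows.append(
            {
                "count": m,
                "fraction_exact": float((counts == m).sum()) / n,
                "fraction_at_least": float((counts >= m).sum()) / n,
            }
        )
    return counts, pd.DataFrame(rows)
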