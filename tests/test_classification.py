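"""Quartile flags, hill/island labels, group contrasts, multi-taxon overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylouniq.classification import (
    classify_sites,
    group_contrast,
    multi_taxon_overlap,
    top_quartile_flags,
)
from phylouniq.scaling import ScalingFit


def _fit(sid, a, b, converged=True):
    return ScalingFit(sid, a, b, 0.9, 10, converged)


def test_quartile_interpolated_threshold():
    """Values 1..8: the 75th percentile is 6.25, so only 7 and 8 flag."""
    v = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
    flags = top_quartile_flags(v)
    assert flags.sum() == 2
    assert flags.iloc[-2:].all()


def test_quartile_all_equal_all_flagged():
    v = pd.Series([3.0] * 5, index=list("abcde"))
    assert top_quartile_flags(v).all()


def test_quartile_outlier_flagged_and_bounds():
    v = pd.Series([1.0, 2.0, 3.0, 100.0], index=list("abcd"))
    flags = top_quartile_flags(v)
    assert flags["d"]
    assert 0.25 <= flags.mean() <= 1.0
    with pytest.raises(ValueError):
        top_quartile_flags(v.iloc[:3])


def test_labels_follow_definitions():
    ids = [f"s{i}" for i in range(8)]
    pe = pd.Series(np.arange(8.0), index=ids)  # top quartile: s6, s7
    # s7: top intercept only -> island; s6: top slope and intercept -> both
    intercepts = [0.1, 0.1, 0.1, 0.1, 0.2, 0.2, 0.9, 0.95]
    slopes = [1e-4, 1e-4, 2e-4, 2e-4, 3e-4, 3e-4, 9e-3, 1e-5]
    fits = [
        _fit(s, 1 - ic, -sl) for s, ic, sl in zip(ids, intercepts, slopes)
    ]
    classes = {c.site_id: c for c in classify_sites(pe, fits)}
    assert classes["s6"].label == "both"
    assert classes["s7"].label == "island"
    for s in ids[:6]:
        assert classes[s].label == "neither"
        assert classes[s].in_top_pe_quartile is False


def test_label_invariants_random_inputs():
    rng = np.random.default_rng(0)
    ids = [f"s{i}" for i in range(40)]
    pe = pd.Series(rng.random(40), index=ids)
    fits = [_fit(s, rng.uniform(0.1, 1.0), -rng.uniform(0, 0.01)) for s in ids]
    for c in classify_sites(pe, fits):
        if c.label != "neither":
            assert c.in_top_pe_quartile


def test_unconverged_fits_labelled_neither():
    ids = [f"s{i}" for i in range(8)]
    pe = pd.Series(np.arange(8.0), index=ids)
    fits = [_fit(s, 0.5, -1e-3) for s in ids[:-1]]
    fits.append(_fit(ids[-1], np.nan, np.nan, converged=False))
    with pytest.warns(UserWarning, match="unconverged"):
        classes = {c.site_id: c for c in classify_sites(pe, fits)}
    assert classes[ids[-1]].label == "neither"


def test_reference_population_switch():
    ids = [f"s{i}" for i in range(8)]
    pe = pd.Series(np.arange(8.0), index=ids)
    fits = [_fit(s, 1 - ic, -1e-4) for s, ic in
            zip(ids, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])]
    all_ref = {c.site_id: c for c in classify_sites(pe, fits, reference="all")}
    top_ref = {c.site_id: c for c in classify_sites(pe, fits, reference="top_pe")}
    # under the all-sites threshold both s6 and s7 are top-quartile intercept;
    # restricted to the two top-PE sites the threshold rises to s7's value
    assert all_ref["s6"].label in ("island", "both")
    assert top_ref["s6"].label != top_ref["s7"].label or top_ref["s7"].label != "neither"


def test_group_contrast_identical_groups_p_near_one():
    """No location shift between groups: two-sided p close to 1."""
    from phylouniq.classification import SiteClassification

    vals = [3.0, 5.0, 7.0, 9.0, 11.0]
    ids = [f"h{i}" for i in range(5)] + [f"i{i}" for i in range(5)]
    classes = [SiteClassification(s, True, "hill") for s in ids[:5]] + [
        SiteClassification(s, True, "island") for s in ids[5:]
    ]
    scores = pd.DataFrame(
        {"richness": vals + vals, "pe": [1.0] * 10, "edge_sum": [0.0] * 10},
        index=ids,
    )
    out = group_contrast(classes, scores)
    p = out.query("metric=='richness'")["p_value"].iloc[0]
    assert p > 0.85


def test_group_contrast_complete_separation():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([10.0, 11.0, 12.0])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.statistic == 0.0  # extreme value: no x exceeds any y
    ids = [f"s{i}" for i in range(6)]
    classes = []
    from phylouniq.classification import SiteClassification
    for i, sid in enumerate(ids):
        classes.append(SiteClassification(sid, True, "hill" if i < 3 else "island"))
    scores = pd.DataFrame(
        {"richness": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
         "pe": [1.0] * 6, "edge_sum": [0.0] * 6},
        index=ids,
    )
    out = group_contrast(classes, scores)
    rich = out[out.metric == "richness"]
    assert (rich["p_value"] < 0.1).all()
    assert rich["p_value"].iloc[0] == rich["p_value"].iloc[1]  # shared two-sided p


def test_group_contrast_small_group_skips_test():
    from phylouniq.classification import SiteClassification

    classes = [
        SiteClassification("a", True, "hill"),
        SiteClassification("b", True, "island"),
        SiteClassification("c", True, "island"),
    ]
    scores = pd.DataFrame(
        {"richness": [5.0, 6.0, 7.0], "pe": [1.0, 2.0, 3.0]},
        index=["a", "b", "c"],
    )
    with pytest.warns(UserWarning, match="fewer than 2"):
        out = group_contrast(classes, scores)
    assert out["p_value"].isna().all()


def test_group_contrast_order_invariance():
    rng = np.random.default_rng(1)
    from phylouniq.classification import SiteClassification

    ids = [f"s{i}" for i in range(12)]
    classes = [
        SiteClassification(s, True, "hill" if i < 6 else "island")
        for i, s in enumerate(ids)
    ]
    swapped = [
        SiteClassification(s, True, "island" if i < 6 else "hill")
        for i, s in enumerate(ids)
    ]
    scores = pd.DataFrame(
        {"richness": rng.integers(5, 40, 12).astype(float),
         "pe": rng.random(12) * 3},
        index=ids,
    )
    p1 = group_contrast(classes, scores).query("metric=='richness'")["p_value"].iloc[0]
    p2 = group_contrast(swapped, scores).query("metric=='richness'")["p_value"].iloc[0]
    assert p1 == pytest.approx(p2)
    assert 0 < p1 <= 1


def test_multi_taxon_overlap_disjoint_and_identical():
    idx = [f"s{i}" for i in range(8)]
    f1 = pd.Series([True, True] + [False] * 6, index=idx)
    f2 = pd.Series([False, False, True, True] + [False] * 4, index=idx)
    counts, summary = multi_taxon_overlap({"amph": f1, "rept": f2})
    assert counts.max() == 1
    at_least_1 = summary.loc[summary["count"] == 1, "fraction_at_least"].iloc[0]
    assert at_least_1 == pytest.approx(4 / 8)
    counts2, summary2 = multi_taxon_overlap({"a": f1, "b": f1.copy()})
    assert (counts2 == 2).sum() == 2
    assert summary2.loc[summary2["count"] == 2, "fraction_exact"].iloc[0] == pytest.approx(2 / 8)


def test_multi_taxon_overlap_independent_rate():
    rng = np.random.default_rng(0)
    n = 4000
    idx = [f"s{i}" for i in range(n)]
    flags = {
        t: pd.Series(rng.random(n) < 0.25, index=idx) for t in "abcd"
    }
    counts, summary = multi_taxon_overlap(flags)
    frac4 = summary.loc[summary["count"] == 4, "fraction_exact"].iloc[0]
    assert frac4 == pytest.approx(0.25**4, abs=3 * np.sqrt(0.25**4 / n) + 2e-3)


def test_missing_sites_count_unflagged():
    f1 = pd.Series([True], index=["a"])
    f2 = pd.Series([True], index=["b"])
    counts, _ = multi_taxon_overlap({"x": f1, "y": f2})
    assert counts["a"] == 1 and counts["b"] == 1
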