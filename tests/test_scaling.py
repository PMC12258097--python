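"""Distance-increase model fitting: exact recovery, noise bias, NLS agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from phylouniq.beta import RugMatrix
from phylouniq.scaling import (
    DegenerateFitError,
    DistanceIncreaseModel,
    fit_all,
    fits_to_frame,
)


def _curve(s, a, b):
    return 1.0 - a * np.exp(b * s)


def test_noise_free_exact_recovery():
    s = np.arange(100.0, 5001.0, 100.0)
    d = _curve(s, 0.8, -0.002)
    res = DistanceIncreaseModel(d, s).fit()
    assert res.a == pytest.approx(0.8, rel=1e-6)
    assert res.b == pytest.approx(-0.002, rel=1e-6)
    assert res.pseudo_r2 == pytest.approx(1.0, abs=1e-9)
    assert res.converged
    assert res.dissimilarity_intercept == pytest.approx(0.2, rel=1e-6)
    assert res.slope_metric == pytest.approx(0.002, rel=1e-6)


@pytest.mark.parametrize("a,b", [(1.0, -0.0005), (0.3, -0.01), (0.65, 0.0)])
def test_noise_free_recovery_across_parameters(a, b):
    s = np.linspace(50, 4000, 60)
    res = DistanceIncreaseModel(_curve(s, a, b), s).fit()
    assert res.a == pytest.approx(a, rel=1e-6, abs=1e-9)
    assert res.b == pytest.approx(b, rel=1e-6, abs=1e-12)


def test_constant_dissimilarity_flat_model():
    s = np.linspace(100, 2000, 30)
    res = DistanceIncreaseModel(np.full_like(s, 0.4), s).fit()
    assert res.a == pytest.approx(0.6, rel=1e-9)
    assert res.b == pytest.approx(0.0, abs=1e-12)


def test_all_dissimilar_degenerate():
    s = np.linspace(100, 2000, 10)
    with pytest.raises(DegenerateFitError):
        DistanceIncreaseModel(np.ones_like(s), s).fit()


def test_preconditions():
    with pytest.raises(ValueError):
        DistanceIncreaseModel(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="positive"):
        DistanceIncreaseModel(np.array([0.1, 0.2, 0.3]), np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        DistanceIncreaseModel(np.array([0.1, 1.2, 0.3]), np.array([1.0, 2.0, 3.0]))


def test_noisy_recovery_bias_bounds():
    """Mean estimates over replicate noisy fits stay near the truth."""
    rng = np.random.default_rng(2024)
    a_hat, b_hat = [], []
    for _ in range(60):
        s = rng.uniform(100, 5000, 500)
        d = np.clip(_curve(s, 0.8, -0.002) + rng.normal(0, 0.02, 500), 0, 1)
        res = DistanceIncreaseModel(d, s).fit()
        assert res.converged
        a_hat.append(res.a)
        b_hat.append(res.b)
    assert abs(np.mean(a_hat) - 0.8) < 0.01
    assert abs(np.mean(b_hat) - (-0.002)) < 0.1 * 0.002


def test_agreement_with_independent_nls():
    rng = np.random.default_rng(7)
    for _ in range(5):
        s = rng.uniform(100, 5000, 400)
        d = np.clip(_curve(s, 0.7, -0.0015) + rng.normal(0, 0.02, 400), 0, 1)
        res = DistanceIncreaseModel(d, s).fit()
        popt, _ = curve_fit(
            lambda s, a, b: a * np.exp(b * s), s, 1.0 - d, p0=[0.5, -0.001],
            maxfev=20000,
        )
        assert res.a == pytest.approx(popt[0], abs=1e-4)
        assert res.b == pytest.approx(popt[1], abs=1e-4)


def test_pseudo_r2_decreases_with_noise():
    rng = np.random.default_rng(3)
    s = rng.uniform(100, 5000, 400)
    r2 = []
    for sd in (0.0, 0.02, 0.1):
        vals = []
        for _ in range(5):
            d = np.clip(_curve(s, 0.8, -0.002) + rng.normal(0, sd, 400), 0, 1)
            vals.append(DistanceIncreaseModel(d, s).fit().pseudo_r2)
        r2.append(np.mean(vals))
    assert r2[0] == pytest.approx(1.0, abs=1e-9)
    assert r2[0] > r2[1] > r2[2]


def test_positive_b_allowed_but_flagged():
    s = np.linspace(100, 2000, 40)
    d = _curve(s, 0.5, 0.0002)  # dissimilarity decreasing with distance
    with pytest.warns(UserWarning, match="b > 0"):
        res = DistanceIncreaseModel(d, s).fit()
    assert res.b > 0


def _toy_matrix_and_distances(n=5, a=0.9, b=-0.001):
    rng = np.random.default_rng(0)
    lon = rng.uniform(0, 20, n)
    pts = np.stack([lon, np.zeros(n)], axis=1)
    dist = np.abs(lon[:, None] - lon[None, :]) * 111.0
    vals = 1 - a * np.exp(b * dist)
    np.fill_diagonal(vals, 0.0)
    ids = [f"s{i}" for i in range(n)]
    return RugMatrix(ids, vals), pd.DataFrame(dist, index=ids, columns=ids)


def test_fit_all_recovers_per_row_and_permutation_invariance():
    m, dist = _toy_matrix_and_distances()
    fits = fit_all(m, dist)
    for f in fits:
        assert f.a == pytest.approx(0.9, rel=1e-6)
        assert f.b == pytest.approx(-0.001, rel=1e-6)
        assert f.n_pairs == m.n - 1
    # permute site order: same per-site parameters
    perm = [2, 0, 4, 1, 3]
    m2 = RugMatrix([m.site_ids[i] for i in perm], m.values[np.ix_(perm, perm)])
    fits2 = {f.site_id: f for f in fit_all(m2, dist)}
    for f in fits:
        assert fits2[f.site_id].a == pytest.approx(f.a, rel=1e-9)


def test_fit_all_too_few_sites():
    ids = ["a", "b"]
    m = RugMatrix(ids, np.array([[0.0, 0.5], [0.4, 0.0]]))
    d = pd.DataFrame([[0.0, 10.0], [10.0, 0.0]], index=ids, columns=ids)
    with pytest.raises(ValueError, match="at least 3"):
        fit_all(m, d)


def test_fit_all_drops_zero_distance_pairs():
    m, dist = _toy_matrix_and_distances(6)
    dist.iloc[0, 1] = dist.iloc[1, 0] = 0.0
    with pytest.warns(UserWarning, match="zero-distance"):
        fits = fit_all(m, dist)
    assert fits[0].n_pairs == m.n - 2


def test_fit_table_columns():
    m, dist = _toy_matrix_and_distances()
    df = fits_to_frame(fit_all(m, dist))
    assert list(df.columns) == [
        "a", "b", "dissimilarity_intercept", "slope_metric",
        "pseudo_r2", "n_pairs", "converged",
    ]
    assert np.allclose(df["dissimilarity_intercept"], 1 - df["a"])
    assert np.allclose(df["slope_metric"], -df["b"])


def test_summary_mentions_parameters():
    s = np.linspace(100, 3000, 50)
    res = DistanceIncreaseModel(_curve(s, 0.8, -0.002), s, site_id="cellA").fit()
    text = res.summary()
    assert "cellA" in text and "pseudo R^2" in text
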