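"""Per-site distance-increase models of phylogenetic uniqueness.

For each focal site the dissimilarity d of its community to every other
community is modelled against geodesic distance s (km) with the negative
exponential

    d = 1 - a * exp(b * s)

i.e. expected *similarity* 1 - d follows exp(log a + b s).  The model is fit
as a Gaussian GLM with log link (iteratively reweighted least squares),
with starting values from OLS on log-similarity.  Two derived quantities
drive the hill/island classification:

* ``dissimilarity_intercept`` = 1 - a: how dissimilar the focal community is
  even at zero distance (high for long-isolated "evolutionary islands");
* ``slope_metric`` = -b: the exponential rate at which similarity decays
  with distance (high for "evolutionary hills", whose uniqueness accrues
  gradually over space).

Both the raw (a, b) and derived metrics are reported so either
parameterisation can be used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .beta import RugMatrix

__all__ = [
    "DegenerateFitError",
    "DistanceIncreaseModel",
    "DistanceIncreaseResults",
    "ScalingFit",
    "fit_uniqueness_model",
    "fit_all",
    "fits_to_frame",
]

CLIP_EPS = 1e-10  # similarity floor used only for the log-scale start values


class DegenerateFitError(ValueError):
    """The dissimilarities admit no log-link fit (e.g. all exactly 1)."""


@dataclass
class ScalingFit:
    """Fitted parameters of one focal site's distance-increase model."""

    site_id: str
    a: float  # similarity multiplier, dimensionless
    b: float  # exponential rate, per km (negative for decay)
    pseudo_r2: float  # 1 - residual deviance / null deviance
    n_pairs: int
    converged: bool

    @property
    def dissimilarity_intercept(self) -> float:
        return 1.0 - self.a

    @property
    def slope_metric(self) -> float:
        return -self.b


class DistanceIncreaseResults:
    """Results wrapper exposing estimates, uncertainty and a summary table."""

    def __init__(self, model: "DistanceIncreaseModel", irls: "_IRLSResult"):
        self.model = model
        self._irls = irls
        self.a = float(np.exp(irls.params[0]))
        self.b = float(irls.params[1])
        self.converged = bool(irls.converged)
        y = model.similarity
        null_dev = float(np.sum((y - y.mean()) ** 2))
        self.pseudo_r2 = 1.0 - irls.deviance / null_dev if null_dev > 0 else 0.0
        if self.b > 0:
            warnings.warn(
                "fitted b > 0: dissimilarity decreases with distance for "
                f"site {model.site_id!r}",
                stacklevel=3,
            )

    # -- parameter accessors ------------------------------------------------
    @property
    def dissimilarity_intercept(self) -> float:
        """Dissimilarity of the fitted curve at distance 0, i.e. 1 - a."""
        return 1.0 - self.a

    @property
    def slope_metric(self) -> float:
        """-b: exponential rate of similarity decay per km."""
        return -self.b

    @property
    def n_pairs(self) -> int:
        return self.model.n_pairs

    def bse(self) -> np.ndarray:
        """Standard errors of (log a, b) from the IRLS information matrix."""
        return np.asarray(self._irls.bse, dtype=float)

    def predict(self, distance_km: np.ndarray) -> np.ndarray:
        """Expected dissimilarity at the given distances."""
        s = np.asarray(distance_km, dtype=float)
        return 1.0 - self.a * np.exp(self.b * s)

    def to_fit(self, site_id: str = "") -> ScalingFit:
        return ScalingFit(
            site_id=site_id or self.model.site_id,
            a=self.a,
            b=self.b,
            pseudo_r2=self.pseudo_r2,
            n_pairs=self.n_pairs,
            converged=self.converged,
        )

    def summary(self) -> str:
        se = self.bse()
        lines = [
            f"Distance-increase model: d = 1 - a*exp(b*s)   site={self.model.site_id}",
            f"  n_pairs                  {self.n_pairs}",
            f"  a (similarity at s=0)    {self.a:.6g}  (se of log a: {se[0]:.3g})",
            f"  b (per km)               {self.b:.6g}  (se: {se[1]:.3g})",
            f"  dissimilarity intercept  {self.dissimilarity_intercept:.6g}",
            f"  slope metric (-b)        {self.slope_metric:.6g}",
            f"  pseudo R^2               {self.pseudo_r2:.4f}",
            f"  converged                {self.converged}",
        ]
        return "\n".join(lines)


class DistanceIncreaseModel:
    """Negative-exponential model of dissimilarity against distance.

    Parameters
    ----------
    dissimilarity :
        Focal-row dissimilarities in [0, 1], self-pair excluded.
    distance_km :
        Matching geodesic distances, all > 0.
    site_id :
        Optional focal-site label carried into results.
    """

    def __init__(
        self,
        dissimilarity: np.ndarray,
        distance_km: np.ndarray,
        site_id: str = "",
    ):
        d = np.asarray(dissimilarity, dtype=float)
        s = np.asarray(distance_km, dtype=float)
        if d.shape != s.shape or d.ndim != 1:
            raise ValueError("dissimilarity and distance must be equal-length vectors")
        if d.size < 3:
            raise ValueError("need at least 3 pairs to fit")
        if np.any((d < 0) | (d > 1)):
            raise ValueError("dissimilarities must lie in [0, 1]")
        if np.any(s <= 0):
            raise ValueError("distances must be strictly positive (self-pair excluded)")
        self.dissimilarity = d
        self.distance_km = s
        self.similarity = 1.0 - d
        self.site_id = site_id

    @property
    def n_pairs(self) -> int:
        return self.dissimilarity.size

    def _start_params(self) -> np.ndarray:
        # OLS on log of clipped similarity; clipping only here, the IRLS
        # itself sees the raw similarities.
        ly = np.log(np.clip(self.similarity, CLIP_EPS, None))
        x = np.column_stack([np.ones_like(self.distance_km), self.distance_km])
        beta, *_ = np.linalg.lstsq(x, ly, rcond=None)
        return beta

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> DistanceIncreaseResults:
        """IRLS fit of E[1 - d] = exp(log a + b s).

        Fisher scoring for the Gaussian family with log link, with step
        halving whenever a full step would increase the deviance (the
        log-link Gaussian IRLS can oscillate without damping).  Convergence
        is a relative deviance change below ``tol``; non-convergence never
        raises — the last iterate is returned flagged.
        """
        if np.all(self.similarity == 0.0):
            raise DegenerateFitError(
                "all dissimilarities equal 1: no similarity signal to fit"
            )
        x = np.column_stack([np.ones_like(self.distance_km), self.distance_km])
        res = _irls_gaussian_log(self.similarity, x, self._start_params(),
                                 maxiter=maxiter, tol=tol)
        return DistanceIncreaseResults(self, res)


@dataclass
class _IRLSResult:
    params: np.ndarray  # (log a, b)
    deviance: float
    bse: np.ndarray
    converged: bool
    n_iter: int


def _irls_gaussian_log(
    y: np.ndarray, x: np.ndarray, start: np.ndarray,
    maxiter: int = 100, tol: float = 1e-8,
) -> _IRLSResult:
    """Damped IRLS for E[y] = exp(X beta) with Gaussian errors."""

    def dev(beta: np.ndarray) -> float:
        return float(np.sum((y - np.exp(np.clip(x @ beta, -700, 50))) ** 2))

    beta = np.asarray(start, dtype=float)
    deviance = dev(beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = np.clip(x @ beta, -700, 50)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu  # working response; dmu/deta = mu
        w = mu  # sqrt of the IRLS weight mu^2
        new, *_ = np.linalg.lstsq(x * w[:, None], z * w, rcond=None)
        # step-halve until the deviance does not increase
        step = 1.0
        cand = new
        cand_dev = dev(cand)
        while cand_dev > deviance and step > 2.0**-30:
            step /= 2.0
            cand = beta + step * (new - beta)
            cand_dev = dev(cand)
        if not np.all(np.isfinite(cand)):
            break
        rel_change = abs(deviance - cand_dev) / max(deviance, 1e-300)
        beta, deviance = cand, cand_dev
        if rel_change < tol or deviance == 0.0:
            converged = True
            break
    # observed-information standard errors at the solution
    mu = np.exp(np.clip(x @ beta, -700, 50))
    n, p = x.shape
    try:
        xtwx = (x * (mu**2)[:, None]).T @ x
        sigma2 = deviance / max(n - p, 1)
        bse = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtwx)))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return _IRLSResult(beta, deviance, bse, converged, it)


def fit_uniqueness_model(
    dissimilarity: np.ndarray, distance_km: np.ndarray, site_id: str = ""
) -> ScalingFit:
    """Convenience wrapper: build the model, fit, return a flat record."""
    return DistanceIncreaseModel(dissimilarity, distance_km, site_id).fit().to_fit()


def fit_all(matrix: RugMatrix, distances: pd.DataFrame) -> list[ScalingFit]:
    """One distance-increase fit per focal row of the dissimilarity matrix.

    Zero-distance pairs (duplicate coordinates) are dropped per row with a
    warning; per-site failures are recorded in the returned table as
    non-converged NaN fits, never raised.
    """
    if matrix.n - 1 < 3:
        raise ValueError("each focal row needs at least 3 comparison sites")
    ids = matrix.site_ids
    dist = distances.loc[ids, ids].to_numpy(dtype=float)
    fits: list[ScalingFit] = []
    n = matrix.n
    dropped_zero = 0
    for i, sid in enumerate(ids):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        zero = mask & (dist[i] == 0.0)
        if zero.any():
            dropped_zero += int(zero.sum())
            mask &= dist[i] > 0.0
        d = matrix.values[i, mask]
        s = dist[i, mask]
        try:
            fits.append(fit_uniqueness_model(d, s, site_id=sid))
        except (ValueError, DegenerateFitError):
            fits.append(
                ScalingFit(sid, np.nan, np.nan, np.nan, int(mask.sum()), False)
            )
    if dropped_zero:
        warnings.warn(
            f"dropped {dropped_zero} zero-distance pair(s) before fitting",
            stacklevel=2,
        )
    return fits


def fits_to_frame(fits: Sequence[ScalingFit]) -> pd.DataFrame:
    """Fit table with the derived classification metrics."""
    return pd.DataFrame(
        {
            "site_id": [f.site_id for f in fits],
            "a": [f.a for f in fits],
            "b": [f.b for f in fits],
            "dissimilarity_intercept": [f.dissimilarity_intercept for f in fits],
            "slope_metric": [f.slope_metric for f in fits],
            "pseudo_r2": [f.pseudo_r2 for f in fits],
            "n_pairs": [f.n_pairs for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).set_index("site_id")
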