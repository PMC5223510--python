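"""Relating the genetic embedding to geography and culture.

Gaussian-mixture clustering with BIC model selection over the number of
clusters and covariance families, 2-D kernel utilization regions
(smallest density superlevel set holding a stated probability mass), a
Procrustes superposition test between geographic and genetic
coordinates with permutation significance, and k-fold cross-validated
predictive-error comparison of covariate models for the embedding
dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .lamds import CorrectedDistanceMatrix, MDSConfiguration, classical_mds

log = logging.getLogger(__name__)

_COV_TYPES = ("spherical", "diag", "tied", "full")


@dataclass
class ClusterModel:
    """Selected Gaussian-mixture clustering.

    ``responsibilities`` rows sum to 1; ``scores`` is the BIC table over
    (K, covariance family); ``population_table`` averages soft
    assignments per population when labels were provided.
    """

    k_star: int
    covariance_type: str
    labels: np.ndarray
    responsibilities: np.ndarray
    scores: pd.DataFrame
    population_table: pd.DataFrame | None = None


def _as_points(data, embed_dims: int = 10) -> tuple:
    if isinstance(data, CorrectedDistanceMatrix):
        cfg = classical_mds(data, k=min(embed_dims, data.n_samples - 1))
        return cfg.coords, list(cfg.populations)
    if isinstance(data, MDSConfiguration):
        return data.coords, list(data.populations)
    return np.asarray(data, float), None


def gmm_cluster(
    data,
    k_range=range(1, 10),
    seed: int = 0,
    n_init: int = 10,
    covariance_types=_COV_TYPES,
    populations=None,
    embed_dims: int = 10,
    max_iter: int = 500,
) -> ClusterModel:
    """EM Gaussian-mixture clustering with BIC selection over K and
    covariance family.

    ``data`` may be a coordinate array, an MDS configuration, or a
    corrected distance matrix (first embedded by classical MDS in
    ``embed_dims`` dimensions, since a mixture on raw distances is
    undefined). Non-convergence keeps the best-so-far fit with a warning.
    """
    points, pops = _as_points(data, embed_dims)
    if populations is not None:
        pops = list(populations)
    k_range = list(k_range)
    if len(points) < max(k_range) + 1:
        raise ValueError("need at least K_max + 1 samples")
    rows, fits = [], {}
    for k in k_range:
        for cov in covariance_types:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                n_init=n_init,
                random_state=seed,
                reg_covar=1e-6,
                max_iter=max_iter,
            )
            gm.fit(points)
            if not gm.converged_:
                log.warning("EM did not converge for K=%d cov=%s; best-so-far kept", k, cov)
            bic = gm.bic(points)
            rows.append((k, cov, bic))
            fits[(k, cov)] = gm
    scores = pd.DataFrame(rows, columns=["k", "covariance_type", "bic"])
    best = scores.loc[scores["bic"].idxmin()]
    gm = fits[(int(best["k"]), best["covariance_type"])]
    resp = gm.predict_proba(points)
    labels = resp.argmax(axis=1)
    pop_table = None
    if pops is not None:
        df = pd.DataFrame(resp, columns=[f"cluster{c}" for c in range(resp.shape[1])])
        df["population"] = pops
        pop_table = df.groupby("population").mean()
    return ClusterModel(
        int(best["k"]), str(best["covariance_type"]), labels, resp, scores, pop_table
    )


@dataclass
class KUDRegion:
    """Kernel utilization region: the smallest density superlevel set
    containing ``level`` of the estimated probability mass."""

    level: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray
    threshold: float
    inside: np.ndarray  # per input point
    fraction_inside: float

    def region_mask(self) -> np.ndarray:
        return self.density >= self.threshold


def kud_region(
    points: np.ndarray,
    level: float = 0.90,
    bandwidth_rule: str = "scott",
    grid_size: int = 128,
    bounds=None,
    pad: float = 0.25,
) -> KUDRegion:
    """2-D kernel utilization distribution region for one group of points.

    A Gaussian KDE (Scott or Silverman bandwidth) is evaluated on a
    regular grid; the region is the set of grid cells of highest density
    whose mass sums to ``level``. Degenerate (collinear/duplicate) point
    sets get a small jitter floor with a warning. ``bounds``
    ``(xmin, xmax, ymin, ymax)`` fixes a common grid across groups.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 5 or pts.shape[1] != 2:
        raise ValueError("need >= 5 two-dimensional points")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    xy = pts.T
    try:
        kde = gaussian_kde(xy, bw_method=bandwidth_rule)
    except np.linalg.LinAlgError:
        log.warning("degenerate point configuration; applying jitter floor")
        scale = max(np.abs(xy).max(), 1.0) * 1e-6
        rng = np.random.default_rng(0)
        xy = xy + rng.normal(scale=scale, size=xy.shape)
        kde = gaussian_kde(xy, bw_method=bandwidth_rule)
    if bounds is None:
        span = xy.max(axis=1) - xy.min(axis=1)
        span = np.where(span > 0, span, 1.0)
        lo = xy.min(axis=1) - pad * span
        hi = xy.max(axis=1) + pad * span
        bounds = (lo[0], hi[0], lo[1], hi[1])
    gx = np.linspace(bounds[0], bounds[1], grid_size)
    gy = np.linspace(bounds[2], bounds[3], grid_size)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    density = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(grid_size, grid_size)
    mass = density / density.sum()
    order = np.argsort(density.ravel())[::-1]
    cum = np.cumsum(mass.ravel()[order])
    cutoff_idx = int(np.searchsorted(cum, level))
    cutoff_idx = min(cutoff_idx, order.size - 1)
    threshold = float(density.ravel()[order[cutoff_idx]])
    point_density = kde(np.asarray(points, float).T)
    inside = point_density >= threshold
    return KUDRegion(
        level, gx, gy, density, threshold, inside, float(inside.mean())
    )


def procrustes_correlation(
    x: np.ndarray, y: np.ndarray, allow_reflection: bool = True
) -> float:
    """Correlation after optimal translation/rotation/uniform scaling.

    Both configurations are centered and scaled to unit Frobenius norm;
    the correlation is the sum of singular values of Y'X (trace of the
    optimal rotation product), in [0, 1]; 1 means exact superposition.
    Reflections are allowed by default.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.shape[0] < 3:
        raise ValueError("configurations must match and have >= 3 rows")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc)
    yn = np.linalg.norm(yc)
    if xn == 0 or yn == 0:
        raise ValueError("degenerate (all-identical) configuration")
    xc /= xn
    yc /= yn
    u, s, vt = np.linalg.svd(yc.T @ xc)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    return float(np.clip(s.sum(), 0.0, 1.0))


def procrustes_test(
    geo_coords: np.ndarray,
    genetic_coords: np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    allow_reflection: bool = True,
) -> tuple:
    """Procrustes superposition test with row-permutation significance.

    Returns ``(correlation, p_value)`` with
    p = (1 + #{permuted r >= observed r}) / (n_iter + 1).
    """
    rng = np.random.default_rng(seed)
    geo = np.asarray(geo_coords, float)
    gen = np.asarray(genetic_coords, float)
    r_obs = procrustes_correlation(geo, gen, allow_reflection)
    n = geo.shape[0]
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(n)
        if procrustes_correlation(geo[perm], gen, allow_reflection) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_iter + 1)


# ----------------------------------------------------------- predictive power

DEFAULT_MODELS = {
    "geography": ("geo",),
    "language": ("language",),
    "subsistence1": ("subsistence1",),
    "subsistence2": ("subsistence2",),
    "geography+language": ("geo", "language"),
    "geography+subsistence1": ("geo", "subsistence1"),
    "geography+language+subsistence1": ("geo", "language", "subsistence1"),
}


@dataclass
class PredictiveErrorReport:
    """Mean cross-validated squared error per covariate model and
    embedding dimension; identical folds across models within a rep."""

    table: pd.DataFrame
    folds: int
    reps: int

    def best_model(self, dim: int) -> str:
        sub = self.table[self.table["dim"] == dim]
        return str(sub.loc[sub["mse"].idxmin(), "model"])


def _design_matrix(covariates: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones((len(covariates), 1))]
    for term in terms:
        if term == "geo":
            cols.append(covariates[["lat", "lon"]].to_numpy(float))
        else:
            dummies = pd.get_dummies(covariates[term]).to_numpy(float)
            cols.append(dummies)
    return np.hstack(cols)


def kfold_predictive_error(
    mds_coords: np.ndarray,
    covariates: pd.DataFrame,
    folds: int = 5,
    reps: int = 1,
    seed: int | np.random.Generator = 0,
    models: dict | None = None,
    dims=None,
) -> PredictiveErrorReport:
    """Five-fold (by default) CV of linear models predicting embedding
    dimensions from geography/language/subsistence covariates.

    Categorical covariates are one-hot encoded on the full table;
    categories absent from a training fold effectively fall back to the
    intercept via the minimum-norm least-squares fit (which also covers
    rank-deficient designs). All models share the same fold partition
    within a repetition; errors are mean held-out squared errors.
    """
    rng = np.random.default_rng(seed)
    coords = np.atleast_2d(np.asarray(mds_coords, float))
    if coords.shape[0] != len(covariates):
        raise ValueError("coordinates and covariates must align")
    if coords.shape[0] < folds:
        raise ValueError("need at least `folds` samples")
    models = models or DEFAULT_MODELS
    dims = list(dims) if dims is not None else list(range(min(2, coords.shape[1])))
    designs = {name: _design_matrix(covariates, terms) for name, terms in models.items()}
    acc = {(name, d): [] for name in models for d in dims}
    n = coords.shape[0]
    for _ in range(reps):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        for f in range(folds):
            test = fold_of == f
            train = ~test
            for name, x in designs.items():
                xt = x[train]
                for d in dims:
                    yt = coords[train, d]
                    beta, *_ = np.linalg.lstsq(xt, yt, rcond=None)
                    pred = x[test] @ beta
                    acc[(name, d)].extend(((coords[test, d] - pred) ** 2).tolist())
    rows = [
        (name, d, float(np.mean(acc[(name, d)])))
        for name in models
        for d in dims
    ]
    return PredictiveErrorReport(
        pd.DataFrame(rows, columns=["model", "dim", "mse"]), folds, reps
    )
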