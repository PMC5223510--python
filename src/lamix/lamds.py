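"""Missing-data-corrected IBS distances and classical MDS embedding.

The distance between two masked haploids is 1 - IBS computed over the
markers jointly non-missing in the pair. Dividing the all-marker
similarity by the jointly non-missing fraction is algebraically the same
thing, and is the only reading of the "ibs / (1 - sum(md))" correction
that keeps IBS in [0, 1]; it removes the downward bias that differing
masking patterns would otherwise induce. The corrected matrix is
embedded with classical (Torgerson) MDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, MaskedHaplotypeSet

log = logging.getLogger(__name__)


@dataclass
class CorrectedDistanceMatrix:
    """Symmetric (1 - IBS) distances with per-pair shared-marker counts.

    Pairs with fewer than the minimum shared markers are NaN.
    """

    hap_ids: list
    populations: list
    distances: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        if not np.allclose(d, d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance diagonal must be zero")

    @property
    def n_samples(self) -> int:
        return len(self.hap_ids)

    def finite_pair_fraction(self) -> float:
        i, j = np.triu_indices(self.n_samples, k=1)
        return float(np.isfinite(self.distances[i, j]).mean())

    def drop_incomplete_samples(self) -> "CorrectedDistanceMatrix":
        """Iteratively drop the sample with most NaN pairs until complete."""
        keep = np.arange(self.n_samples)
        d = self.distances.copy()
        while True:
            bad = np.isnan(d[np.ix_(keep, keep)]).sum(axis=1)
            if bad.max(initial=0) == 0:
                break
            worst = keep[bad.argmax()]
            keep = keep[keep != worst]
            log.warning("dropping sample %s with missing pairwise distances",
                        self.hap_ids[worst])
        return CorrectedDistanceMatrix(
            [self.hap_ids[i] for i in keep],
            [self.populations[i] for i in keep],
            self.distances[np.ix_(keep, keep)],
            self.pair_counts[np.ix_(keep, keep)],
        )


def corrected_ibs_matrix(
    masked: MaskedHaplotypeSet, min_shared: int = 100
) -> CorrectedDistanceMatrix:
    """Pairwise corrected (1 - IBS) distances between masked haploids.

    Per pair, similarity = matches / jointly-non-missing markers (haploid
    0/1 alleles: a site matches iff equal). Pairs sharing fewer than
    ``min_shared`` markers (default 100; real-data pair minima sit just
    above this) are set NaN with a warning.
    """
    h = masked.alleles
    if h.shape[0] < 2:
        raise ValueError("need at least 2 haploids")
    valid = (h != MISSING).astype(np.float64)
    ones = ((h == 1) & (h != MISSING)).astype(np.float64)
    zeros = ((h == 0) & (h != MISSING)).astype(np.float64)
    shared = valid @ valid.T
    matches = ones @ ones.T + zeros @ zeros.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = matches / shared
    dist = 1.0 - sim
    low = shared < min_shared
    if low[np.triu_indices_from(low, k=1)].any():
        log.warning(
            "%d pairs share fewer than %d markers; distances set missing",
            int(low[np.triu_indices_from(low, k=1)].sum()), min_shared,
        )
    dist[low] = np.nan
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry against float noise
    return CorrectedDistanceMatrix(
        list(masked.hap_ids),
        list(masked.haplotypes.populations),
        dist,
        shared.astype(int),
    )


@dataclass
class MDSConfiguration:
    """Classical-MDS embedding: coordinates, eigenvalues, variance captured."""

    hap_ids: list
    populations: list
    coords: np.ndarray
    eigenvalues: np.ndarray
    positive_variance_fraction: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"dim{i+1}" for i in range(self.coords.shape[1])]
        )
        df.insert(0, "hap_id", self.hap_ids)
        df["population"] = self.populations
        return df


def classical_mds(dmat: CorrectedDistanceMatrix, k: int = 10) -> MDSConfiguration:
    """Torgerson double-centering + eigendecomposition of the distance matrix.

    Coordinates use the top-k positive eigenvalues (k truncated with a
    warning if fewer are positive); negative eigenvalues are retained in
    ``eigenvalues`` for diagnostics.
    """
    d = dmat.distances
    if not np.isfinite(d).all():
        raise ValueError(
            "distance matrix has missing entries; call drop_incomplete_samples first"
        )
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-10).sum())
    if k > n_pos:
        if n_pos < k and n_pos < n - 1:
            log.warning("only %d positive eigenvalues; truncating k=%d", n_pos, k)
        k = max(n_pos, 0)
    if k == 0:
        coords = np.zeros((n, 1))
        k = 1
    else:
        coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_var = float(eigval[:k].sum() / eigval[eigval > 0].sum()) if (eigval > 0).any() else 1.0
    return MDSConfiguration(
        list(dmat.hap_ids), list(dmat.populations), coords, eigval, pos_var
    )


def flag_outlier_samples(
    config: MDSConfiguration,
    z_threshold: float = 6.0,
    explicit_exclusions: list | None = None,
    max_removed_fraction: float = 0.20,
    rule: str = "isolation",
    n_neighbors: int = 5,
) -> list:
    """Retained sample ids after outlier removal on the first two dimensions.

    The default ``"isolation"`` rule flags samples whose median distance
    to their ``n_neighbors`` nearest neighbours has a robust z-score
    (|d - median| / (1.4826 * MAD)) above ``z_threshold`` — isolated
    points are removed while multimodal cluster structure is left alone.
    The ``"coordinate_mad"`` rule applies the robust z-score to the
    coordinates themselves (appropriate only for unimodal embeddings).
    An explicit exclusion list is always honoured. Removing more than
    ``max_removed_fraction`` of samples is treated as an error
    (suspicious input).
    """
    if config.coords.shape[1] < 2:
        raise ValueError("need at least 2 MDS dimensions")
    xy = config.coords[:, :2]
    if rule == "isolation":
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        k = min(n_neighbors, len(xy) - 1)
        nn = np.sort(d, axis=1)[:, :k]
        # log scale symmetrizes the right-skewed neighbour-distance stat
        stat = np.log(np.maximum(np.median(nn, axis=1), 1e-300))
        med = np.median(stat)
        mad = np.median(np.abs(stat - med))
        scale = 1.4826 * (mad if mad > 0 else 1e-12)
        z = (stat - med) / scale  # one-sided: only isolation is suspicious
        flagged = set(np.array(config.hap_ids)[z > z_threshold])
    elif rule == "coordinate_mad":
        med = np.median(xy, axis=0)
        mad = np.median(np.abs(xy - med), axis=0)
        scale = 1.4826 * np.where(mad > 0, mad, 1e-12)
        z = np.abs(xy - med) / scale
        flagged = set(np.array(config.hap_ids)[(z > z_threshold).any(axis=1)])
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    flagged |= set(explicit_exclusions or ())
    if len(flagged) > max_removed_fraction * len(config.hap_ids):
        raise ValueError(
            f"outlier rule would remove {len(flagged)} of {len(config.hap_ids)} samples"
        )
    if flagged:
        log.info("flagged %d outlier samples: %s", len(flagged), sorted(flagged))
    return [hid for hid in config.hap_ids if hid not in flagged]


def resample_marker_curve(
    masked: MaskedHaplotypeSet,
    sizes: list,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    min_shared: int = 100,
) -> pd.DataFrame:
    """Robustness of the corrected-IBS matrix to marker downsampling.

    For each size N, ``reps`` marker subsets are drawn without
    replacement, the corrected distance matrix recomputed, and its
    correlation (r and R^2) with the full-marker matrix measured over
    pairs finite in both. Returns per-size mean/median r, the 95%
    interval across reps, and mean R^2. Sizes above the marker count are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    full = corrected_ibs_matrix(masked, min_shared=min_shared)
    iu = np.triu_indices(full.n_samples, k=1)
    full_vec = full.distances[iu]
    n_markers = masked.haplotypes.n_markers
    rows = []
    for size in sizes:
        if size > n_markers:
            log.warning("resample size %d exceeds %d markers; skipped", size, n_markers)
            continue
        rs = []
        for _ in range(reps):
            idx = rng.choice(n_markers, size=size, replace=False)
            sub = MaskedHaplotypeSet(
                masked.haplotypes.subset_markers(np.sort(idx)), masked.target_ancestry
            )
            # small subsets legitimately share few markers per pair
            dsub = corrected_ibs_matrix(sub, min_shared=min(min_shared, max(size // 10, 1)))
            vec = dsub.distances[iu]
            ok = np.isfinite(vec) & np.isfinite(full_vec)
            r = float(np.corrcoef(vec[ok], full_vec[ok])[0, 1]) if ok.sum() > 2 else np.nan
            rs.append(r)
        rs = np.array(rs)
        rows.append(
            (
                size,
                float(np.nanmean(rs)),
                float(np.nanmedian(rs)),
                float(np.nanpercentile(rs, 2.5)),
                float(np.nanpercentile(rs, 97.5)),
                float(np.nanmean(rs**2)),
            )
        )
    return pd.DataFrame(
        rows, columns=["n_markers", "mean_r", "median_r", "ci_low", "ci_high", "mean_r2"]
    )
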