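"""Quality control and cross-platform merging of SNP-array panels.

Implements the standard array-merging pipeline: per-marker/per-sample
missing-rate and call-rate filters, removal of strand-ambiguous (A/T,
C/G) SNPs, a position-based merge with strand/allele reconciliation, a
robust pairwise kinship estimator with greedy relative pruning, and the
cross-platform duplicate IBS check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypePanel,
    MarkerMap,
    complement_allele,
    is_strand_ambiguous,
)

log = logging.getLogger(__name__)


def filter_missingness(
    panel: GenotypePanel,
    sample_max_missing: float = 0.10,
    marker_max_missing: float = 0.10,
) -> GenotypePanel:
    """Drop markers then samples whose missing fraction exceeds the bounds.

    The marker pass runs first and the sample pass recomputes rates on
    the surviving markers.
    """
    for thr in (sample_max_missing, marker_max_missing):
        if not (0.0 < thr <= 1.0):
            raise ValueError("missingness thresholds must be in (0, 1]")
    miss = panel.missing_mask()
    marker_keep = np.flatnonzero(miss.mean(axis=0) <= marker_max_missing)
    panel = panel.subset_markers(marker_keep)
    sample_keep = np.flatnonzero(panel.missing_mask().mean(axis=1) <= sample_max_missing)
    if sample_keep.size == 0:
        raise ValueError("missingness filter removed every sample")
    log.info(
        "missingness filter: kept %d/%d markers, %d/%d samples",
        marker_keep.size, len(miss.T), sample_keep.size, panel.n_samples,
    )
    return panel.subset_samples(sample_keep)


def filter_call_rate(panel: GenotypePanel, min_call_rate: float = 0.98) -> GenotypePanel:
    """Call-rate filter: call rate = 1 - missing rate, markers then samples."""
    if not (0.0 <= min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in [0, 1]")
    if min_call_rate == 0.0:
        return panel
    return filter_missingness(
        panel,
        sample_max_missing=1.0 - min_call_rate if min_call_rate < 1 else 1e-12,
        marker_max_missing=1.0 - min_call_rate if min_call_rate < 1 else 1e-12,
    )


def drop_strand_ambiguous(panel: GenotypePanel) -> GenotypePanel:
    """Remove A/T and C/G SNPs, which cannot be strand-reconciled."""
    tab = panel.markers.table
    keep = np.array(
        [not is_strand_ambiguous(a1, a2) for a1, a2 in zip(tab["a1"], tab["a2"])]
    )
    if not keep.any():
        log.warning("all markers are strand-ambiguous; panel left with no markers")
    return panel.subset_markers(np.flatnonzero(keep))


def _reconcile_alleles(a1a, a2a, a1b, a2b):
    """How panel-B alleles relate to panel-A alleles at one position.

    Returns 'same', 'swap' (dosage must be reversed), or None when the
    allele pairs cannot be reconciled even after strand complementing.
    """
    pair_a = (a1a, a2a)
    for b in ((a1b, a2b), (complement_allele(a1b), complement_allele(a2b))):
        if b == pair_a:
            return "same"
        if (b[1], b[0]) == pair_a:
            return "swap"
    return None


def _shared_reconciled(panel_a: GenotypePanel, panel_b: GenotypePanel):
    """Positional indices of reconcilable shared markers and a swap mask."""
    _check_unique_positions(panel_a, "A")
    _check_unique_positions(panel_b, "B")
    ta = panel_a.markers.table[["chrom", "pos", "a1", "a2"]].reset_index(names="ix_a")
    tb = panel_b.markers.table[["chrom", "pos", "a1", "a2"]].reset_index(names="ix_b")
    joined = ta.merge(tb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    rels = [
        _reconcile_alleles(r.a1_a, r.a2_a, r.a1_b, r.a2_b)
        for r in joined.itertuples()
    ]
    keep = np.array([rel is not None for rel in rels])
    n_dropped = int((~keep).sum())
    idx_a = joined["ix_a"].to_numpy()[keep]
    idx_b = joined["ix_b"].to_numpy()[keep]
    flip = np.array([rel == "swap" for rel, k in zip(rels, keep) if k])
    order = np.argsort(idx_a)
    return idx_a[order], idx_b[order], flip[order], n_dropped


def _check_unique_positions(panel: GenotypePanel, tag: str) -> None:
    key = panel.markers.table[["chrom", "pos"]]
    dup = key[key.duplicated(keep=False)]
    if not dup.empty:
        positions = sorted(set(map(tuple, dup.to_numpy())))
        raise ValueError(f"duplicate positions in panel {tag}: {positions[:10]}")


def merge_on_position(panel_a: GenotypePanel, panel_b: GenotypePanel) -> GenotypePanel:
    """Merge two panels on (chromosome, bp): marker intersection, sample union.

    Allele codes of panel B are reconciled to panel A by strand
    complementing and/or allele swapping (dosage reversal); positions
    whose allele pairs remain irreconcilable are dropped and counted.
    Strand-ambiguous SNPs must already have been removed.
    """
    idx_a, idx_b, flip, n_dropped = _shared_reconciled(panel_a, panel_b)
    if n_dropped:
        log.warning("merge: dropped %d irreconcilable shared positions", n_dropped)

    ga = panel_a.genotypes[:, idx_a]
    gb = panel_b.genotypes[:, idx_b].copy()
    if flip.any():
        cols = np.flatnonzero(flip)
        valid = gb[:, cols] != MISSING
        gb[:, cols] = np.where(valid, 2 - gb[:, cols], MISSING)

    ids_a = set(panel_a.sample_ids)
    ids_b = [
        sid if sid not in ids_a else f"{sid}.{panel_b.platform or 'B'}"
        for sid in panel_b.sample_ids
    ]
    merged = GenotypePanel(
        list(panel_a.sample_ids) + ids_b,
        list(panel_a.populations) + list(panel_b.populations),
        panel_a.markers.subset(idx_a),
        np.vstack([ga, gb]),
        platform="merged",
    )
    return merged


@dataclass
class KinshipResult:
    """Pairwise kinship coefficients with flagged related pairs."""

    sample_ids: list
    phi: np.ndarray  # symmetric, diagonal 0.5
    n_shared: np.ndarray
    unreliable_pairs: list  # pairs with too few shared markers

    def pairs_above(self, threshold: float) -> pd.DataFrame:
        i, j = np.triu_indices(len(self.sample_ids), k=1)
        above = self.phi[i, j] > threshold
        return pd.DataFrame(
            {
                "id1": [self.sample_ids[a] for a in i[above]],
                "id2": [self.sample_ids[b] for b in j[above]],
                "n_markers": self.n_shared[i[above], j[above]],
                "kinship": self.phi[i[above], j[above]],
            }
        ).sort_values("kinship", ascending=False, ignore_index=True)

    def to_table(self) -> pd.DataFrame:
        i, j = np.triu_indices(len(self.sample_ids), k=1)
        return pd.DataFrame(
            {
                "id1": [self.sample_ids[a] for a in i],
                "id2": [self.sample_ids[b] for b in j],
                "n_markers": self.n_shared[i, j],
                "kinship": self.phi[i, j],
            }
        )


def kinship_matrix(panel: GenotypePanel, min_shared: int = 100) -> KinshipResult:
    """Robust pairwise kinship from heterozygote concordance counts.

    phi_ij = (N_AaAa - 2 * N_AAaa) / (N_Aa^i + N_Aa^j), all counts taken
    over markers non-missing in both samples; the between-family form of
    the KING-robust estimator. Duplicates give phi ~ 0.5, parent-offspring
    ~ 0.25, unrelated ~ 0. Pairs with fewer than ``min_shared`` jointly
    typed markers are flagged unreliable (phi reported but untrusted).
    """
    if panel.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    g = panel.genotypes
    valid = (g != MISSING).astype(np.float64)
    het = ((g == 1) & (g != MISSING)).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)

    n_shared = valid @ valid.T
    n_hetshared_i = het @ valid.T  # het count of i over markers shared with j
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    denom = n_hetshared_i + n_hetshared_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)

    i, j = np.triu_indices(panel.n_samples, k=1)
    bad = n_shared[i, j] < min_shared
    unreliable = [
        (panel.sample_ids[a], panel.sample_ids[b]) for a, b in zip(i[bad], j[bad])
    ]
    if unreliable:
        log.warning("%d sample pairs have < %d shared markers", len(unreliable), min_shared)
    return KinshipResult(
        list(panel.sample_ids), phi, n_shared.astype(int), unreliable
    )


def remove_relatives(
    kinship: KinshipResult, threshold: float = 0.0884, seed: int | np.random.Generator = 0
) -> list:
    """Greedy relative pruning: for each pair above the kinship threshold
    (highest first), randomly drop one member; returns kept sample ids."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rng = np.random.default_rng(seed)
    removed: set = set()
    pairs = kinship.pairs_above(threshold)
    for _, row in pairs.iterrows():
        if row["id1"] in removed or row["id2"] in removed:
            continue
        removed.add(row["id1"] if rng.random() < 0.5 else row["id2"])
    if removed:
        log.info("removed %d relatives above kinship %.4f", len(removed), threshold)
    return [sid for sid in kinship.sample_ids if sid not in removed]


def cross_platform_ibs(
    panel_a: GenotypePanel, panel_b: GenotypePanel, paired_ids: list
) -> pd.DataFrame:
    """IBS similarity for individuals genotyped on both platforms.

    For each (id_a, id_b) pair, similarity is averaged over
    position-shared, allele-reconciled, jointly non-missing markers:
    per marker (2 - |dosage_a - dosage_b|) / 2. Pairs with no shared
    typed markers get NaN with a warning.
    """
    idx_a, idx_b, flip, _ = _shared_reconciled(panel_a, panel_b)
    if idx_a.size == 0:
        raise ValueError("panels share no reconcilable positions")

    pos_a = {sid: k for k, sid in enumerate(panel_a.sample_ids)}
    pos_b = {sid: k for k, sid in enumerate(panel_b.sample_ids)}
    rows = []
    for id_a, id_b in paired_ids:
        da = panel_a.genotypes[pos_a[id_a], idx_a].astype(float)
        db = panel_b.genotypes[pos_b[id_b], idx_b].astype(float)
        db = np.where((db != MISSING) & flip, 2 - db, db)
        ok = (da != MISSING) & (db != MISSING)
        if not ok.any():
            log.warning("pair (%s, %s) shares no typed markers", id_a, id_b)
            rows.append((id_a, id_b, 0, np.nan))
            continue
        ibs = float(np.mean((2.0 - np.abs(da[ok] - db[ok])) / 2.0))
        rows.append((id_a, id_b, int(ok.sum()), ibs))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "n_markers", "ibs"])
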