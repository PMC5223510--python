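"""Windowed local-ancestry deconvolution.

For each ~1 cM window, a PCA space is fitted on labelled donor
haplotypes and target haplotypes are projected into it; per-ancestry
likelihoods come from Gaussian densities on the donor scores (shared
diagonal covariance), and a hidden Markov model smooths the window
sequence along each chromosome. Hard calls keep only windows whose
posterior exceeds a confidence threshold (default 0.99), which on
well-differentiated donor panels discards essentially all misassigned
windows at the cost of an unassigned fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeSet, MarkerMap, TractSet

log = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass(frozen=True)
class WindowGrid:
    """Half-open [start, end) genetic-distance windows tiling each chromosome.

    ``windows`` columns: ``chrom``, ``start_cm``, ``end_cm``; ``marker_index``
    holds, per window, the positional indices of its markers in the map.
    """

    windows: pd.DataFrame
    marker_index: list
    size_cm: float

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def midpoints(self) -> np.ndarray:
        return (
            self.windows["start_cm"].to_numpy(float)
            + self.windows["end_cm"].to_numpy(float)
        ) / 2.0

    def chrom_blocks(self) -> list:
        """Contiguous runs of window indices per chromosome."""
        chroms = self.windows["chrom"].to_numpy()
        blocks, start = [], 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append(np.arange(start, i))
                start = i
        return blocks


def build_window_grid(marker_map: MarkerMap, size_cm: float = 1.0) -> WindowGrid:
    """Tile each chromosome's mapped extent with windows of ``size_cm``.

    The last window per chromosome may be shorter. Windows containing no
    markers are dropped (count logged). A marker at exactly a window
    boundary belongs to the right-hand (half-open) window.
    """
    if size_cm <= 0:
        raise ValueError("size_cm must be positive")
    tab = marker_map.table
    rows, marker_idx = [], []
    n_empty = 0
    for chrom in marker_map.chroms:
        in_chrom = (tab["chrom"] == chrom).to_numpy()
        cms = tab["cm"].to_numpy(float)[in_chrom]
        pos_idx = np.flatnonzero(in_chrom)
        extent = float(cms.max())
        if extent <= 0:
            raise ValueError(f"chromosome {chrom} has zero mapped length")
        n_win = int(np.ceil(extent / size_cm))
        assign = np.minimum((cms / size_cm).astype(int), n_win - 1)
        for w in range(n_win):
            members = pos_idx[assign == w]
            if members.size == 0:
                n_empty += 1
                continue
            rows.append((chrom, w * size_cm, min((w + 1) * size_cm, extent)))
            marker_idx.append(members)
    if n_empty:
        log.info("window grid: dropped %d empty windows", n_empty)
    grid = pd.DataFrame(rows, columns=["chrom", "start_cm", "end_cm"])
    return WindowGrid(grid, marker_idx, size_cm)


@dataclass
class ReferencePanelSet:
    """Labelled donor haplotypes with per-donor purity.

    Donors whose purity does not exceed ``min_purity`` are excluded at
    construction (the donor-purity rule). At least two ancestry labels
    must remain.
    """

    haplotypes: HaplotypeSet
    labels: np.ndarray
    purity: np.ndarray
    min_purity: float = 0.99

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.purity = np.asarray(self.purity, dtype=float)
        if len(self.labels) != self.haplotypes.n_haplotypes:
            raise ValueError("labels must align with donor haplotypes")
        if (self.purity < self.min_purity).any():
            raise ValueError("all donors must satisfy the purity threshold")
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("need donors from at least 2 ancestries")

    @classmethod
    def select_donors(
        cls,
        haplotypes: HaplotypeSet,
        labels,
        purity=None,
        min_purity: float = 0.99,
    ) -> "ReferencePanelSet":
        """Keep donors with purity strictly above ``min_purity``."""
        labels = np.asarray(labels)
        purity = (
            np.ones(haplotypes.n_haplotypes)
            if purity is None
            else np.asarray(purity, dtype=float)
        )
        keep = np.flatnonzero(purity > min_purity)
        return cls(
            haplotypes.subset_haplotypes(keep), labels[keep], purity[keep], min_purity
        )

    @property
    def ancestries(self) -> list:
        return sorted(set(self.labels.tolist()))


def window_scores(
    donor_alleles: np.ndarray,
    target_alleles: np.ndarray,
    n_components: int,
    min_markers: int = 5,
):
    """PCA scores for one window: fit on donors, project targets.

    Returns ``(donor_scores, target_scores, informative)``. Missing target
    alleles are imputed at the donor mean (zero after centering). Windows
    with too few markers or no donor variance are flagged uninformative.
    """
    m = donor_alleles.shape[1]
    if m < min_markers:
        return None, None, False
    x = donor_alleles.astype(float)
    x[donor_alleles == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    xc = np.where(np.isnan(x), 0.0, x - mean)
    if not (xc.std(axis=0) > 0).any():
        return None, None, False
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, int((s > 1e-12).sum()))
    if k == 0:
        return None, None, False
    basis = vt[:k].T
    t = target_alleles.astype(float)
    tc = np.where(target_alleles == MISSING, 0.0, t - mean)
    return xc @ basis, tc @ basis, True


def window_likelihoods(
    donor_scores: np.ndarray,
    donor_labels: np.ndarray,
    target_scores: np.ndarray,
    ancestries: list,
    var_floor: float = 1e-6,
    emission_floor: float = 0.01,
) -> np.ndarray:
    """Per-ancestry normalized likelihoods from Gaussian densities.

    One Gaussian per ancestry with its own mean on the donor scores and a
    shared diagonal covariance (pooled within-ancestry variance, floored
    to avoid singularities); evaluated at target scores and normalized
    per target. ``emission_floor`` mixes the normalized likelihoods with
    a uniform component (a miscopying/outlier term): window markers are
    in LD and the Gaussian model is approximate, so raw window
    likelihoods are overconfident; the floor caps the evidence any
    single window can contribute.
    """
    k_dims = donor_scores.shape[1]
    means = np.zeros((len(ancestries), k_dims))
    pooled = np.zeros(k_dims)
    n_tot = 0
    for a, anc in enumerate(ancestries):
        grp = donor_scores[donor_labels == anc]
        means[a] = grp.mean(axis=0)
        pooled += ((grp - means[a]) ** 2).sum(axis=0)
        n_tot += len(grp)
    var = np.maximum(pooled / max(n_tot - len(ancestries), 1), var_floor)
    diff = target_scores[:, None, :] - means[None, :, :]  # targets x anc x dims
    loglik = -0.5 * (diff**2 / var).sum(axis=2) - 0.5 * np.log(var).sum()
    loglik -= loglik.max(axis=1, keepdims=True)
    lik = np.exp(loglik)
    lik = lik / lik.sum(axis=1, keepdims=True)
    k = len(ancestries)
    return (1.0 - emission_floor) * lik + emission_floor / k


@dataclass
class AncestryPosterior:
    """Per-haplotype, per-window, per-ancestry probabilities.

    ``likelihoods`` are the pre-HMM normalized window likelihoods;
    ``posteriors`` the forward-backward smoothed probabilities. Both are
    (haplotypes x windows x ancestries) arrays.
    """

    hap_ids: list
    grid: WindowGrid
    ancestries: list
    likelihoods: np.ndarray
    posteriors: np.ndarray

    def __post_init__(self) -> None:
        sums = self.posteriors.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 over ancestries")

    def to_table(self) -> pd.DataFrame:
        """Long-format posterior table (hap, window, best ancestry, probs)."""
        best = self.posteriors.argmax(axis=2)
        rows = []
        for h, hid in enumerate(self.hap_ids):
            for w in range(self.grid.n_windows):
                win = self.grid.windows.iloc[w]
                rows.append(
                    (
                        hid,
                        win["chrom"],
                        win["start_cm"],
                        win["end_cm"],
                        self.ancestries[best[h, w]],
                        self.posteriors[h, w, best[h, w]],
                        *self.posteriors[h, w],
                    )
                )
        cols = ["hap_id", "chrom", "win_start_cm", "win_end_cm", "best_ancestry", "p_best"]
        cols += [f"p_{a}" for a in self.ancestries]
        return pd.DataFrame(rows, columns=cols)


def hmm_smooth(
    likelihoods: np.ndarray,
    grid: WindowGrid,
    hap_ids: list,
    ancestries: list,
    switch_rate_per_cm: float = 0.1,
) -> AncestryPosterior:
    """Forward-backward smoothing of window likelihoods along chromosomes.

    Between adjacent windows at genetic distance d cM, the chain keeps
    its state with probability exp(-switch_rate * d) and otherwise draws
    a state uniformly (so the total probability of actually changing
    ancestry is spread evenly over the alternatives). As switch_rate
    grows the transition matrix becomes uniform and the posteriors
    converge to the unsmoothed per-window likelihoods.
    """
    if switch_rate_per_cm <= 0:
        raise ValueError("switch_rate_per_cm must be > 0")
    n_hap, n_win, k = likelihoods.shape
    post = np.empty_like(likelihoods, dtype=float)
    mids = grid.midpoints()
    eye = np.eye(k)
    uniform = np.ones((k, k)) / k
    for block in grid.chrom_blocks():
        lik = likelihoods[:, block, :]
        w = len(block)
        trans = []
        for j in range(w - 1):
            stay = np.exp(-switch_rate_per_cm * abs(mids[block[j + 1]] - mids[block[j]]))
            trans.append(stay * eye + (1.0 - stay) * uniform)
        alpha = np.empty((n_hap, w, k))
        a = lik[:, 0, :] / k
        alpha[:, 0, :] = a / a.sum(axis=1, keepdims=True)
        for j in range(1, w):
            a = (alpha[:, j - 1, :] @ trans[j - 1]) * lik[:, j, :]
            alpha[:, j, :] = a / a.sum(axis=1, keepdims=True)
        beta = np.ones((n_hap, w, k))
        for j in range(w - 2, -1, -1):
            b = (beta[:, j + 1, :] * lik[:, j + 1, :]) @ trans[j].T
            beta[:, j, :] = b / b.sum(axis=1, keepdims=True)
        p = alpha * beta
        post[:, block, :] = p / p.sum(axis=2, keepdims=True)
    return AncestryPosterior(list(hap_ids), grid, list(ancestries), likelihoods, post)


def deconvolve(
    targets: HaplotypeSet,
    donors: ReferencePanelSet,
    window_cm: float = 1.0,
    switch_rate_per_cm: float = 0.1,
    n_components: int | None = None,
    min_markers: int = 5,
    emission_floor: float = 0.01,
) -> AncestryPosterior:
    """Full windowed deconvolution of target haplotypes against donors.

    Windows with too few markers or no donor variation get uniform
    likelihood (uninformative). ``n_components`` defaults to the number
    of ancestries minus one.
    """
    grid = build_window_grid(targets.markers, window_cm)
    ancestries = donors.ancestries
    k = len(ancestries)
    n_pc = n_components if n_components is not None else k - 1
    lik = np.full((targets.n_haplotypes, grid.n_windows, k), 1.0 / k)
    n_uninformative = 0
    for w, members in enumerate(grid.marker_index):
        d_scores, t_scores, ok = window_scores(
            donors.haplotypes.alleles[:, members],
            targets.alleles[:, members],
            n_pc,
            min_markers,
        )
        if not ok:
            n_uninformative += 1
            continue
        lik[:, w, :] = window_likelihoods(
            d_scores, donors.labels, t_scores, ancestries,
            emission_floor=emission_floor,
        )
    if n_uninformative:
        log.info("deconvolve: %d uninformative windows", n_uninformative)
    return hmm_smooth(lik, grid, targets.hap_ids, ancestries, switch_rate_per_cm)


@dataclass
class AncestryCalls:
    """Hard per-window ancestry calls; :data:`UNASSIGNED` marks windows
    below the confidence threshold."""

    hap_ids: list
    grid: WindowGrid
    ancestries: list
    calls: np.ndarray  # haplotypes x windows, int codes into ancestries
    confidence: float

    def label(self, code: int) -> str:
        return "unassigned" if code == UNASSIGNED else self.ancestries[code]

    def target_mask(self, ancestry: str) -> np.ndarray:
        return self.calls == self.ancestries.index(ancestry)

    def ancestry_fraction(self, ancestry: str) -> np.ndarray:
        """Per-haplotype fraction of all windows called as ``ancestry``."""
        return self.target_mask(ancestry).mean(axis=1)


def call_ancestry(posterior: AncestryPosterior, confidence: float = 0.99) -> AncestryCalls:
    """Argmax calls where the top posterior strictly exceeds ``confidence``."""
    best = posterior.posteriors.argmax(axis=2)
    p_best = posterior.posteriors.max(axis=2)
    calls = np.where(p_best > confidence, best, UNASSIGNED)
    return AncestryCalls(
        posterior.hap_ids, posterior.grid, posterior.ancestries, calls, confidence
    )


def _true_window_labels(
    truth: TractSet, hap_ids: list, grid: WindowGrid, ancestries: list
) -> np.ndarray:
    """Majority-span truth label per (haplotype, window); ties get -2."""
    labels = np.full((len(hap_ids), grid.n_windows), -2, dtype=int)
    wins = grid.windows
    by_hap = dict(tuple(truth.table.groupby("hap_id", sort=False)))
    for h, hid in enumerate(hap_ids):
        sub = by_hap[hid]
        for chrom, chrom_tracts in sub.groupby("chrom", sort=False):
            in_chrom = np.flatnonzero((wins["chrom"] == chrom).to_numpy())
            if in_chrom.size == 0:
                continue
            starts = wins["start_cm"].to_numpy(float)[in_chrom]
            ends = wins["end_cm"].to_numpy(float)[in_chrom]
            cover = np.zeros((len(ancestries), in_chrom.size))
            for a, anc in enumerate(ancestries):
                tr = chrom_tracts[chrom_tracts["ancestry"] == anc]
                for s, e in zip(tr["start_cm"], tr["end_cm"]):
                    cover[a] += np.clip(
                        np.minimum(ends, e) - np.maximum(starts, s), 0.0, None
                    )
            span = ends - starts
            best = cover.argmax(axis=0)
            best_cover = cover.max(axis=0)
            # strict majority of the window span; 50/50 splits are ties
            is_majority = best_cover > span / 2.0 + 1e-12
            labels[h, in_chrom] = np.where(is_majority, best, -2)
    return labels


@dataclass
class MisassignmentReport:
    """Validation of hard calls against simulator truth."""

    misassignment_rate: float  # wrong calls among called windows
    unassigned_fraction: float
    n_called: int
    n_windows: int
    by_ancestry: pd.DataFrame


def validate_calls(calls: AncestryCalls, truth: TractSet) -> MisassignmentReport:
    """Compare hard calls with majority-span truth labels.

    A window whose truth is an exact tie counts as misassigned for any
    call (conservative). Rates are reported among called windows, plus
    the unassigned fraction, stratified by called ancestry.
    """
    missing_ids = set(calls.hap_ids) - set(truth.table["hap_id"])
    if missing_ids:
        raise ValueError(f"truth tracts missing for {len(missing_ids)} haplotypes")
    labels = _true_window_labels(truth, calls.hap_ids, calls.grid, calls.ancestries)
    called = calls.calls != UNASSIGNED
    wrong = called & (calls.calls != labels)
    n_called = int(called.sum())
    rows = []
    for a, anc in enumerate(calls.ancestries):
        mask = called & (calls.calls == a)
        rows.append(
            (anc, int(mask.sum()), int((mask & wrong).sum()),
             float((mask & wrong).sum() / mask.sum()) if mask.any() else 0.0)
        )
    return MisassignmentReport(
        misassignment_rate=float(wrong.sum() / n_called) if n_called else 0.0,
        unassigned_fraction=float(1.0 - called.mean()),
        n_called=n_called,
        n_windows=calls.calls.size,
        by_ancestry=pd.DataFrame(rows, columns=["ancestry", "n_called", "n_wrong", "rate"]),
    )
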