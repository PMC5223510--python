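"""Allele-frequency statistics: FST, drift-based split-time dating,
f3/f4 admixture statistics with block-jackknife errors, and the
weighted-LD amplitude Z-score classification rule.

Split times follow the pure-drift relation 1 - FST = (1 - 1/(2*Ne))**t
with t in generations and Ne the diploid effective size, converted to
years at a configurable generation time (default 29 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypePanel, HaplotypeSet

DEFAULT_GENERATION_TIME = 29.0


# ---------------------------------------------------------------- frequencies

def allele_frequencies(data, groups=None) -> pd.DataFrame:
    """Per-group alternate-allele frequency and allele count.

    ``data`` may be a GenotypePanel (dosage 0/1/2, allele count = 2 x
    typed samples) or a HaplotypeSet (0/1). Groups default to the
    population labels. Returns columns ``<group>_freq``/``<group>_n``.
    """
    if isinstance(data, GenotypePanel):
        mat = data.genotypes
        pops = np.asarray(data.populations)
        ploidy = 2
    elif isinstance(data, HaplotypeSet):
        mat = data.alleles
        pops = np.asarray(data.populations)
        ploidy = 1
    else:
        raise TypeError("expected GenotypePanel or HaplotypeSet")
    if groups is None:
        groups = list(pd.unique(pops))
    out = {}
    for g in groups:
        sub = mat[pops == g].astype(float)
        sub[sub == MISSING] = np.nan
        n = ploidy * np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(sub, axis=0) / n
        out[f"{g}_freq"] = freq
        out[f"{g}_n"] = n
    return pd.DataFrame(out)


# ------------------------------------------------------------------------ FST

@dataclass(frozen=True)
class FstResult:
    pop1: str
    pop2: str
    fst: float
    n_markers: int
    estimator: str


def hudson_fst(p1, p2, n1, n2, pops=("pop1", "pop2")) -> FstResult:
    """Hudson's FST estimator, ratio of averages over markers.

    Per marker: numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1); n are allele counts (>= 2). Markers
    monomorphic in both populations contribute zero to both sums; if all
    markers are, the estimate is undefined and an error is raised.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, float), p2.shape)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("allele counts must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        raise ValueError("FST undefined: all markers monomorphic in both populations")
    return FstResult(pops[0], pops[1], float(num.mean() / den.mean()), p1.size, "hudson")


def component_fst(p1, p2, pops=("comp1", "comp2")) -> FstResult:
    """FST between ancestry-component frequency vectors (no sample-size
    correction): mean (p1-p2)^2 / mean [p1(1-p2) + p2(1-p1)]."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        raise ValueError("FST undefined: components identical and fixed")
    return FstResult(pops[0], pops[1], float(((p1 - p2) ** 2).mean() / den.mean()),
                     p1.size, "component")


# ----------------------------------------------------------------- split time

@dataclass(frozen=True)
class SplitTimeResult:
    fst: float
    ne: float
    generations: float
    years: float
    generation_time: float


def split_time(
    fst: float, ne: float, generation_time: float = DEFAULT_GENERATION_TIME
) -> SplitTimeResult:
    """Invert 1 - FST = (1 - 1/(2*Ne))**t for the separation time t.

    t = ln(1 - FST) / ln(1 - 1/(2*Ne)) generations, then years at the
    configured generation time. FST must lie in [0, 1).
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("FST must be in [0, 1)")
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    t = math.log(1.0 - fst) / math.log(1.0 - 1.0 / (2.0 * ne))
    return SplitTimeResult(fst, ne, t, t * generation_time, generation_time)


def years_from_generations(
    generations: float, generation_time: float = DEFAULT_GENERATION_TIME
) -> float:
    """Date conversion: years = generations x generation time."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return generations * generation_time


# -------------------------------------------------------------- f-statistics

@dataclass(frozen=True)
class FStatResult:
    statistic: str
    populations: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int


def contiguous_blocks(n_markers: int, block_size: int = 500) -> np.ndarray:
    """Block assignment of consecutive markers (jackknife units)."""
    return np.arange(n_markers) // block_size


def _block_jackknife(values: np.ndarray, blocks: np.ndarray) -> tuple:
    """Delete-one-block jackknife mean and SE of mean(values)."""
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError("need at least 2 jackknife blocks")
    total = values.sum()
    n = values.size
    est = total / n
    loo = np.array([(total - values[blocks == b].sum()) / (n - (blocks == b).sum())
                    for b in uniq])
    g = uniq.size
    se = math.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
    return float(est), float(se)


def f3_statistic(
    t_freqs, a_freqs, b_freqs,
    block_assignments,
    t_counts=None,
    pops=("target", "a", "b"),
) -> FStatResult:
    """f3(target; A, B) = mean (t - a)(t - b) with block-jackknife SE.

    When ``t_counts`` (target allele counts per marker) is given, the
    finite-sample heterozygosity correction t(1-t)/(n_t - 1) is
    subtracted per marker, removing the upward bias from sampling noise
    in the target. Significantly negative Z indicates the target is
    admixed between sources related to A and B.
    """
    t = np.asarray(t_freqs, float)
    a = np.asarray(a_freqs, float)
    b = np.asarray(b_freqs, float)
    vals = (t - a) * (t - b)
    if t_counts is not None:
        n_t = np.broadcast_to(np.asarray(t_counts, float), t.shape)
        if (n_t < 2).any():
            raise ValueError("target allele counts must be >= 2 for the correction")
        vals = vals - t * (1 - t) / (n_t - 1)
    est, se = _block_jackknife(vals, block_assignments)
    z = est / se if se > 0 else np.nan
    return FStatResult("f3", tuple(pops), est, se, float(z), len(np.unique(block_assignments)))


def f4_statistic(
    a_freqs, b_freqs, c_freqs, d_freqs,
    block_assignments,
    pops=("a", "b", "c", "d"),
) -> FStatResult:
    """f4(A, B; C, D) = mean (a - b)(c - d) with block-jackknife SE.

    Antisymmetric in each pair; zero in expectation when the unrooted
    tree (AB)(CD) holds without gene flow. The outgroup, when used, is
    simply the fourth frequency vector.
    """
    a = np.asarray(a_freqs, float)
    b = np.asarray(b_freqs, float)
    c = np.asarray(c_freqs, float)
    d = np.asarray(d_freqs, float)
    vals = (a - b) * (c - d)
    est, se = _block_jackknife(vals, block_assignments)
    z = est / se if se > 0 else np.nan
    return FStatResult("f4", tuple(pops), est, se, float(z), len(np.unique(block_assignments)))


# ------------------------------------------------- weighted-LD amplitude rule

@dataclass
class AdmixtureAmplitudeSet:
    """Candidate source-pair amplitudes for one admixture event.

    ``table`` columns: ``pop1``, ``pop2``, ``amplitude``, ``se``. After
    classification it gains ``z`` (vs the maximal pair) and ``retained``.
    """

    event_id: str
    table: pd.DataFrame


def malder_source_classification(
    amplitudes: AdmixtureAmplitudeSet, macro_groups: dict
) -> tuple:
    """Retain source pairs statistically indistinguishable from the best.

    Z = (C_max - C) / sqrt(se_max^2 + se^2) for each candidate pair
    against the maximal amplitude; pairs with Z < 2 are retained and
    their populations mapped to macro-groups, whose frequency of
    appearance among retained pairs is reported.

    Returns ``(classified AdmixtureAmplitudeSet, macro-group frequency
    Series)``. Pairs where both SEs are zero (undefined Z) are flagged
    NaN and not retained unless they equal the maximum exactly.
    """
    tab = amplitudes.table.copy()
    if tab.empty or not np.isfinite(tab["se"]).any():
        raise ValueError("need at least one amplitude with finite SE")
    imax = tab["amplitude"].idxmax()
    c_max, se_max = tab.loc[imax, "amplitude"], tab.loc[imax, "se"]
    denom = np.sqrt(se_max**2 + tab["se"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (c_max - tab["amplitude"]) / denom
    z[(denom == 0) & (tab["amplitude"] == c_max)] = 0.0
    tab["z"] = z
    tab["retained"] = tab["z"] < 2.0
    tab.loc[~np.isfinite(tab["z"]), "retained"] = False
    retained = tab[tab["retained"]]
    counts: dict = {}
    for _, row in retained.iterrows():
        for pop in (row["pop1"], row["pop2"]):
            grp = macro_groups.get(pop, pop)
            counts[grp] = counts.get(grp, 0) + 1
    freq = pd.Series(counts, dtype=float)
    freq = freq / freq.sum() if len(freq) else freq
    return AdmixtureAmplitudeSet(amplitudes.event_id, tab), freq.sort_values(ascending=False)


def read_amplitudes(path) -> list:
    """Amplitude input contract: CSV with event_id, pop1, pop2, C, se."""
    df = pd.read_csv(path)
    out = []
    for event_id, sub in df.groupby("event_id", sort=False):
        tab = sub.rename(columns={"C": "amplitude"})[
            ["pop1", "pop2", "amplitude", "se"]
        ].reset_index(drop=True)
        out.append(AdmixtureAmplitudeSet(str(event_id), tab))
    return out
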