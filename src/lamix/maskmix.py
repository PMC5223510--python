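"""Ancestry-specific fragment extraction ("masking").

Each phased chromosome copy of an individual is treated as an
independent haploid analysis unit; markers outside windows confidently
called as the target ancestry are set to missing. Survivor filters keep
only haploids with more than a minimum fraction of the target ancestry
and at least a minimum fraction of the platform-overlap SNPs retained,
and the two platform datasets are intersected on shared masked markers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ancestry_windows import UNASSIGNED, AncestryCalls
from .core import MISSING, GenotypePanel, HaplotypeSet, MaskedHaplotypeSet

log = logging.getLogger(__name__)


def haploidize(haplotypes: HaplotypeSet) -> HaplotypeSet:
    """Treat each phased chromosome copy as a haploid sample.

    Input haplotypes must come in ``__0``/``__1`` pairs per individual;
    allele content is preserved unchanged.
    """
    ids = list(haplotypes.hap_ids)
    individuals = {}
    for hid in ids:
        base, _, copy = hid.rpartition("__")
        if not base or copy not in ("0", "1"):
            raise ValueError(f"haplotype id {hid!r} is not a phased '__0/__1' pair member")
        individuals.setdefault(base, []).append(copy)
    for base, copies in individuals.items():
        if sorted(copies) != ["0", "1"]:
            raise ValueError(f"individual {base!r} does not have exactly two phased copies")
    return HaplotypeSet(
        ids, list(haplotypes.populations), haplotypes.markers, haplotypes.alleles.copy()
    )


def rediploidize(haploids: HaplotypeSet) -> GenotypePanel:
    """Re-pair ``__0``/``__1`` haploids into diploid genotypes (round-trip)."""
    index = {hid: i for i, hid in enumerate(haploids.hap_ids)}
    individuals = sorted({hid.rpartition("__")[0] for hid in haploids.hap_ids})
    geno = np.empty((len(individuals), haploids.n_markers), dtype=np.int8)
    pops = []
    for k, ind in enumerate(individuals):
        i0, i1 = index[f"{ind}__0"], index[f"{ind}__1"]
        geno[k] = haploids.alleles[i0] + haploids.alleles[i1]
        pops.append(haploids.populations[i0])
    return GenotypePanel(individuals, pops, haploids.markers, geno)


def extract_fragments(
    haploids: HaplotypeSet, calls: AncestryCalls, target_ancestry: str
) -> MaskedHaplotypeSet:
    """Mask every site outside windows called as ``target_ancestry``.

    Sites in unassigned or other-ancestry windows (and sites outside any
    window) become missing. The per-sample ancestry fraction is the
    fraction of all windows called as the target.
    """
    if target_ancestry not in calls.ancestries:
        raise KeyError(f"{target_ancestry!r} not among call labels {calls.ancestries}")
    order = [calls.hap_ids.index(hid) for hid in haploids.hap_ids]
    target = calls.target_mask(target_ancestry)[order]
    keep = np.zeros((haploids.n_haplotypes, haploids.n_markers), dtype=bool)
    for w, members in enumerate(calls.grid.marker_index):
        keep[:, members] = target[:, [w]]
    alleles = np.where(keep, haploids.alleles, MISSING).astype(np.int8)
    masked = MaskedHaplotypeSet(
        HaplotypeSet(
            list(haploids.hap_ids), list(haploids.populations), haploids.markers, alleles
        ),
        target_ancestry,
    )
    masked.stats["ancestry_fraction"] = target.mean(axis=1)
    fully_masked = masked.stats["retained_snps"] == 0
    if fully_masked.any():
        log.warning("%d haploids have zero target-ancestry windows", int(fully_masked.sum()))
    return masked


def filter_samples(
    masked: MaskedHaplotypeSet,
    min_ancestry_fraction: float = 0.20,
    min_snp_retention: float = 0.10,
    overlap_marker_index: np.ndarray | None = None,
    external_ancestry_fractions: dict | None = None,
) -> MaskedHaplotypeSet:
    """Keep haploids with > ``min_ancestry_fraction`` target ancestry and
    >= ``min_snp_retention`` of the overlap SNPs retained.

    The ancestry fraction defaults to the call-based per-sample fraction;
    ``external_ancestry_fractions`` (hap_id -> fraction, e.g. from a
    genome-wide clustering estimate) overrides it when supplied. SNP
    retention is measured on ``overlap_marker_index`` (positional indices
    of the cross-platform overlap), or all markers when None.
    """
    stats = masked.stats
    frac = stats["ancestry_fraction"].to_numpy(float)
    if external_ancestry_fractions is not None:
        frac = np.array([external_ancestry_fractions[h] for h in stats["hap_id"]])
    if overlap_marker_index is None:
        overlap_marker_index = np.arange(masked.haplotypes.n_markers)
    overlap_marker_index = np.asarray(overlap_marker_index)
    if overlap_marker_index.size == 0:
        raise ValueError("overlap marker set is empty")
    retained = (masked.alleles[:, overlap_marker_index] != MISSING).sum(axis=1)
    retention = retained / overlap_marker_index.size
    keep = (frac > min_ancestry_fraction) & (retention >= min_snp_retention)
    if not keep.any():
        raise ValueError("sample filters removed every haploid")
    idx = np.flatnonzero(keep)
    out = MaskedHaplotypeSet(
        masked.haplotypes.subset_haplotypes(idx), masked.target_ancestry
    )
    out.stats["ancestry_fraction"] = frac[idx]
    log.info("filter_samples: kept %d/%d haploids", len(idx), len(keep))
    return out


def intersect_platforms(
    masked_a: MaskedHaplotypeSet, masked_b: MaskedHaplotypeSet
) -> MaskedHaplotypeSet:
    """Combine two platform-specific masked sets on their shared markers.

    Markers are matched by (chromosome, bp); samples are the union; the
    per-sample retention statistics are recomputed on the intersection.
    """
    if masked_a.target_ancestry != masked_b.target_ancestry:
        raise ValueError("masked sets target different ancestries")
    key_a = masked_a.markers.position_key()
    key_b = masked_b.markers.position_key()
    shared = key_a.intersection(key_b)
    if len(shared) == 0:
        raise ValueError("platform marker sets do not intersect")
    idx_a = np.flatnonzero(key_a.isin(shared))
    idx_b_lookup = pd.Series(np.arange(len(key_b)), index=key_b)
    idx_b = idx_b_lookup.loc[key_a[idx_a]].to_numpy()
    sub_a = masked_a.haplotypes.subset_markers(idx_a)
    sub_b = masked_b.haplotypes.subset_markers(idx_b)
    combined = MaskedHaplotypeSet(
        HaplotypeSet(
            list(sub_a.hap_ids) + list(sub_b.hap_ids),
            list(sub_a.populations) + list(sub_b.populations),
            sub_a.markers,
            np.vstack([sub_a.alleles, sub_b.alleles]),
        ),
        masked_a.target_ancestry,
    )
    combined.stats["ancestry_fraction"] = np.concatenate(
        [
            masked_a.stats["ancestry_fraction"].to_numpy(float),
            masked_b.stats["ancestry_fraction"].to_numpy(float),
        ]
    )
    return combined


def tract_length_distribution(calls: AncestryCalls, target_ancestry: str) -> pd.DataFrame:
    """Lengths (cM) of maximal runs of consecutive target-called windows.

    One row per run: hap_id, chrom, length_cm. Summary quantiles are a
    ``describe()`` away; used to compare platforms' fragment-length
    behaviour.
    """
    code = calls.ancestries.index(target_ancestry)
    wins = calls.grid.windows
    starts = wins["start_cm"].to_numpy(float)
    ends = wins["end_cm"].to_numpy(float)
    rows = []
    for h, hid in enumerate(calls.hap_ids):
        for block in calls.grid.chrom_blocks():
            chrom = wins["chrom"].iloc[block[0]]
            run_start = None
            prev_end = None
            for w in block:
                if calls.calls[h, w] == code:
                    if run_start is None:
                        run_start = starts[w]
                    prev_end = ends[w]
                else:
                    if run_start is not None:
                        rows.append((hid, chrom, prev_end - run_start))
                        run_start = None
            if run_start is not None:
                rows.append((hid, chrom, prev_end - run_start))
    return pd.DataFrame(rows, columns=["hap_id", "chrom", "length_cm"])
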