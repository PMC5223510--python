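"""Readers and writers for the package's on-disk interchange formats.

PLINK BED/BIM/FAM is the primary genotype format (the 2-bit SNP-major
.bed layout, written with the alternate allele as A1). Haplotypes, tract
sets, population metadata and distance matrices use plain tab/CSV text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypePanel, HaplotypeSet, MarkerMap, PopMeta, TractSet

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode

# 2-bit codes per PLINK spec: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# With A1 = alternate allele, dosage 2 -> 00, 1 -> 10, 0 -> 11.
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a genotype panel as PLINK .bed/.bim/.fam triplet."""
    prefix = Path(prefix)
    bim = panel.markers.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in bim.iterrows():
            fh.write(
                f"{row.chrom}\t{row.marker_id}\t{row.cm:.6f}\t{row.pos}\t{row.a2}\t{row.a1}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, pop in zip(panel.sample_ids, panel.populations):
            fh.write(f"{pop}\t{sid}\t0\t0\t0\t-9\n")

    g = panel.genotypes
    n = panel.n_samples
    codes = np.empty_like(g, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g == dosage] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, panel.n_markers), dtype=np.uint8)
    padded[:n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    by_byte = padded.reshape(n_bytes, 4, panel.n_markers)
    packed = (by_byte << shifts[None, :, None]).sum(axis=1).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # SNP-major: all samples for SNP 1, then SNP 2, ...


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK .bed/.bim/.fam triplet written in SNP-major mode."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1_bim", "a2_bim"],
    )
    markers = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": bim["marker_id"],
                "chrom": bim["chrom"],
                "pos": bim["pos"],
                "cm": bim["cm"],
                "a1": bim["a2_bim"],  # reference allele stored as PLINK A2
                "a2": bim["a1_bim"],
            }
        )
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep="\t",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n = len(fam)
    m = len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    genotypes = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypePanel(list(fam["iid"]), list(fam["fid"]), markers, genotypes)


def write_haplotypes(haps: HaplotypeSet, path, map_path=None) -> None:
    """Transposed haplotype matrix: one row per marker, one column per
    haplotype; missing written as '.'. A sidecar marker map goes to
    ``map_path`` when given."""
    mat = haps.alleles.T.astype(object)
    mat[mat == MISSING] = "."
    pd.DataFrame(mat, columns=haps.hap_ids).to_csv(path, sep="\t", index=False)
    if map_path is not None:
        haps.markers.table.to_csv(map_path, sep="\t", index=False)


def read_haplotypes(path, map_path, populations=None) -> HaplotypeSet:
    mat = pd.read_csv(path, sep="\t", dtype=str)
    markers = MarkerMap(pd.read_csv(map_path, sep="\t"))
    alleles = mat.replace(".", str(MISSING)).to_numpy(dtype=np.int8).T
    ids = list(mat.columns)
    pops = populations if populations is not None else [""] * len(ids)
    return HaplotypeSet(ids, pops, markers, alleles)


def write_tracts(tracts: TractSet, path) -> None:
    """BED-like tab file: chrom, start_cM, end_cM, hap_id, ancestry."""
    tracts.table[["chrom", "start_cm", "end_cm", "hap_id", "ancestry"]].to_csv(
        path, sep="\t", index=False
    )


def read_tracts(path) -> TractSet:
    return TractSet(pd.read_csv(path, sep="\t"))


def write_popmeta(meta: PopMeta, path) -> None:
    meta.table.to_csv(path, index=False)


def read_popmeta(path) -> PopMeta:
    return PopMeta(pd.read_csv(path))


def write_distance_matrix(ids, matrix: np.ndarray, path, pair_counts=None) -> None:
    """Square tab-delimited matrix with header ids; optional sidecar of
    per-pair marker counts at ``<path>.counts``."""
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")
    if pair_counts is not None:
        pd.DataFrame(pair_counts, index=ids, columns=ids).to_csv(
            str(path) + ".counts", sep="\t"
        )


def read_distance_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(float)
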