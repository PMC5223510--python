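"""Core data containers shared across the pipeline.

All genotype/haplotype matrices are small integer numpy arrays with an
explicit missing code (:data:`MISSING`). Diploid genotypes are coded as
alternate-allele dosage 0/1/2; haplotypes as 0/1. Marker metadata travels
with the matrices in a :class:`MarkerMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Missing-genotype code used in every integer matrix in the package.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class MarkerMap:
    """Per-marker metadata: chromosome, physical bp, genetic cM, alleles.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker_id``, ``chrom``, ``pos`` (bp, 1-based), ``cm``
        (genetic position), ``a1`` (reference allele), ``a2`` (alternate).

    Invariants: bp strictly increasing within a chromosome, cM monotone
    non-decreasing within a chromosome, alleles in {A, C, G, T}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos", "cm", "a1", "a2"}
        missing_cols = required - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"MarkerMap missing columns: {sorted(missing_cols)}")
        for col in ("a1", "a2"):
            bad = ~self.table[col].isin(list(_VALID_ALLELES))
            if bad.any():
                raise ValueError(f"invalid alleles in column {col!r}")
        for _, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("bp positions must be strictly increasing within a chromosome")
            cm = sub["cm"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise ValueError("cM positions must be non-decreasing within a chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def subset(self, index: np.ndarray) -> "MarkerMap":
        """Row subset preserving order; `index` is positional."""
        return MarkerMap(self.table.iloc[np.asarray(index)].reset_index(drop=True))

    def position_key(self) -> pd.Index:
        """(chrom, pos) tuples usable as a merge key."""
        return pd.MultiIndex.from_frame(self.table[["chrom", "pos"]])


@dataclass
class GenotypePanel:
    """Diploid genotype panel: samples x markers dosage matrix plus metadata.

    ``genotypes`` holds 0/1/2 alternate-allele dosage with :data:`MISSING`
    for no-calls, one row per sample.
    """

    sample_ids: list
    populations: list
    markers: MarkerMap
    genotypes: np.ndarray
    platform: str = ""

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("populations must align with sample_ids")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype codes must be 0/1/2 or the missing code")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            [self.sample_ids[i] for i in index],
            [self.populations[i] for i in index],
            self.markers,
            self.genotypes[index],
            self.platform,
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            list(self.sample_ids),
            list(self.populations),
            self.markers.subset(index),
            self.genotypes[:, index],
            self.platform,
        )


@dataclass
class HaplotypeSet:
    """Phased haploid alleles: haplotypes x markers 0/1 matrix.

    Haplotype ids follow the ``<individual>__0`` / ``<individual>__1``
    convention so the two chromosome copies of an individual can be
    re-paired. ``populations`` aligns with ``hap_ids``.
    """

    hap_ids: list
    populations: list
    markers: MarkerMap
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.hap_ids), len(self.markers)):
            raise ValueError("allele matrix does not match hap_ids x markers")
        if len(self.populations) != len(self.hap_ids):
            raise ValueError("populations must align with hap_ids")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            list(self.hap_ids),
            list(self.populations),
            self.markers.subset(index),
            self.alleles[:, index],
        )

    def subset_haplotypes(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            [self.hap_ids[i] for i in index],
            [self.populations[i] for i in index],
            self.markers,
            self.alleles[index],
        )


def hap_id(individual: str, copy: int) -> str:
    """Canonical haploid sample id for one chromosome copy of an individual."""
    return f"{individual}__{copy}"


@dataclass
class TractSet:
    """Ground-truth ancestry segments per haplotype (simulator output).

    ``table`` columns: ``hap_id``, ``chrom``, ``start_cm``, ``end_cm``,
    ``ancestry``. Tracts tile each chromosome without gaps or overlaps.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hap_id", "chrom", "start_cm", "end_cm", "ancestry"}
        if required - set(self.table.columns):
            raise ValueError("TractSet table missing required columns")

    def validate_tiling(self, chrom_lengths_cm: dict, atol: float = 1e-9) -> None:
        """Check that tracts tile every (haplotype, chromosome) exactly."""
        for (hid, chrom), sub in self.table.groupby(["hap_id", "chrom"], sort=False):
            sub = sub.sort_values("start_cm")
            starts = sub["start_cm"].to_numpy(float)
            ends = sub["end_cm"].to_numpy(float)
            if abs(starts[0]) > atol or abs(ends[-1] - chrom_lengths_cm[chrom]) > atol:
                raise ValueError(f"tracts of {hid} do not span chromosome {chrom}")
            if np.any(np.abs(starts[1:] - ends[:-1]) > atol):
                raise ValueError(f"tracts of {hid} on {chrom} have gaps or overlaps")

    def ancestry_at(self, hid: str, chrom, cm: float) -> str:
        """True ancestry label at a genetic position (start-inclusive)."""
        sub = self.table[(self.table["hap_id"] == hid) & (self.table["chrom"] == chrom)]
        hit = sub[(sub["start_cm"] <= cm) & (cm < sub["end_cm"])]
        if hit.empty:  # right chromosome end
            hit = sub[sub["end_cm"] >= cm]
        return str(hit.iloc[0]["ancestry"])

    def genome_fraction(self, hid: str, ancestry: str) -> float:
        sub = self.table[self.table["hap_id"] == hid]
        lengths = (sub["end_cm"] - sub["start_cm"]).to_numpy(float)
        target = sub["ancestry"].to_numpy() == ancestry
        return float(lengths[target].sum() / lengths.sum())


@dataclass
class MaskedHaplotypeSet:
    """Haploid alleles with non-target-ancestry sites masked to missing.

    Wraps a :class:`HaplotypeSet` whose ``alleles`` may contain
    :data:`MISSING`, together with per-sample bookkeeping: retained SNP
    count, total markers, and the fraction of windows called as the
    target ancestry.
    """

    haplotypes: HaplotypeSet
    target_ancestry: str
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.stats.empty:
            self.stats = self.recompute_stats()

    def recompute_stats(self) -> pd.DataFrame:
        retained = (self.haplotypes.alleles != MISSING).sum(axis=1)
        total = self.haplotypes.n_markers
        frac = self.stats["ancestry_fraction"] if "ancestry_fraction" in self.stats else np.nan
        return pd.DataFrame(
            {
                "hap_id": self.haplotypes.hap_ids,
                "population": self.haplotypes.populations,
                "retained_snps": retained,
                "total_snps": total,
                "snp_retention": retained / max(total, 1),
                "ancestry_fraction": frac,
            }
        )

    @property
    def hap_ids(self) -> list:
        return self.haplotypes.hap_ids

    @property
    def alleles(self) -> np.ndarray:
        return self.haplotypes.alleles

    @property
    def markers(self) -> MarkerMap:
        return self.haplotypes.markers


@dataclass(frozen=True)
class PopMeta:
    """Population-level covariates: coordinates, language, subsistence.

    ``table`` columns: ``population``, ``lat``, ``lon``, ``language``,
    ``subsistence1``, ``subsistence2`` (two alternative subsistence
    classification schemes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"population", "lat", "lon", "language", "subsistence1", "subsistence2"}
        if required - set(self.table.columns):
            raise ValueError("PopMeta table missing required columns")
        if (self.table["lat"].abs() > 90).any() or (self.table["lon"].abs() > 180).any():
            raise ValueError("coordinates out of range")
        if self.table[["subsistence1", "subsistence2"]].isna().any().any():
            raise ValueError("both subsistence schemes must be present for every population")

    def for_population(self, population: str) -> pd.Series:
        hit = self.table[self.table["population"] == population]
        if hit.empty:
            raise KeyError(population)
        return hit.iloc[0]


def complement_allele(a: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[a]


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs cannot be strand-reconciled between platforms."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})
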