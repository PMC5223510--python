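"""End-to-end workflows on the standard synthetic study design.

The "tripartite" scenario mirrors the structure the analyses are built
for: three Khoesan-like sources at pairwise FST ~ 0.05 nested under a
deeper Khoesan ancestor, plus Bantu-like and European-like sources, and
admixed populations each drawing their Khoesan ancestry from exactly one
of the three sources. The full pipeline is: windowed deconvolution into
the three ancestry groups, masking to Khoesan-specific fragments,
corrected-IBS distances with classical MDS, and Gaussian-mixture
clustering of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthio
from .ancestry_windows import (
    AncestryCalls,
    MisassignmentReport,
    ReferencePanelSet,
    call_ancestry,
    deconvolve,
    validate_calls,
)
from .core import HaplotypeSet, TractSet
from .geo_culture import ClusterModel, gmm_cluster
from .lamds import (
    CorrectedDistanceMatrix,
    MDSConfiguration,
    classical_mds,
    corrected_ibs_matrix,
    flag_outlier_samples,
)
from .maskmix import MaskedHaplotypeSet, extract_fragments, filter_samples, haploidize

#: Khoesan sources sit under a shared Khoesan ancestor; branch drifts are
#: chosen so pairwise FST is ~0.05 within the Khoesan trio and >= 0.15
#: between the deconvolution donor groups.
KHOESAN_SOURCES = ("Khoesan_N", "Khoesan_C", "Khoesan_S")
ANCESTRY_GROUPS = ("Khoesan", "Bantu", "European")


def tripartite_model(
    khoesan_pairwise_fst: float = 0.05,
    khoesan_stem_drift: float = 0.20,
    bantu_drift: float = 0.20,
    european_drift: float = 0.30,
) -> synthio.AncestralModel:
    """Trifurcating Khoesan clade under a deeper three-way split.

    Two populations whose branches carry drifts F1 and F2 from their
    common ancestor show pairwise Hudson FST ~ (F1 + F2) / 2, so each
    Khoesan branch gets drift equal to the desired pairwise FST.
    """
    pops = [
        synthio.Population("Khoesan_anc", khoesan_stem_drift),
        synthio.Population("Bantu", bantu_drift),
        synthio.Population("European", european_drift),
    ]
    pops += [
        synthio.Population(name, khoesan_pairwise_fst, parent="Khoesan_anc")
        for name in KHOESAN_SOURCES
    ]
    return synthio.AncestralModel(tuple(pops))


def source_to_group(source: str) -> str:
    return "Khoesan" if source.startswith("Khoesan") else source


def remap_tract_ancestries(tracts: TractSet, mapping=None) -> TractSet:
    """Collapse tract source labels to deconvolution ancestry groups."""
    table = tracts.table.copy()
    if mapping is None:
        table["ancestry"] = table["ancestry"].map(source_to_group)
    else:
        table["ancestry"] = table["ancestry"].map(mapping)
    return TractSet(table)


@dataclass
class TripartiteCohort:
    """Synthetic cohort plus everything the pipeline and its validation need."""

    targets: HaplotypeSet
    tracts: TractSet  # source-level truth labels
    donors: ReferencePanelSet  # grouped Khoesan/Bantu/European donors
    khoesan_source_of_pop: dict  # population -> Khoesan source label
    khoesan_fraction_of_pop: dict  # population -> recipe Khoesan proportion
    marker_map: synthio.MarkerMap
    frequencies: pd.DataFrame

    def group_tracts(self) -> TractSet:
        return remap_tract_ancestries(self.tracts)

    def true_source_labels(self, hap_ids) -> np.ndarray:
        pop_of = dict(zip(self.targets.hap_ids, self.targets.populations))
        return np.array([self.khoesan_source_of_pop[pop_of[h]] for h in hap_ids])


def simulate_tripartite_cohort(
    seed: int = 0,
    n_markers: int = 20_000,
    n_chromosomes: int = 10,
    chrom_length_cm: float = 100.0,
    n_populations: int = 8,
    n_per_pop: int = 20,
    generations: int = 20,
    donors_per_source: int = 8,
    donors_per_outgroup: int = 25,
    source_pool_haplotypes: int = 60,
) -> TripartiteCohort:
    """Simulate the standard study cohort.

    ``n_populations`` admixed populations of ``n_per_pop`` individuals;
    population i draws its Khoesan ancestry entirely from source i mod 3,
    with Khoesan proportions cycling through 30-80% and the remainder
    split 70/30 between Bantu and European sources (a single admixture
    pulse ``generations`` ago). Donor panels hold pure haplotypes:
    ``donors_per_source`` per Khoesan source (pooled under the "Khoesan"
    label) and ``donors_per_outgroup`` each for Bantu and European.
    """
    rng = np.random.default_rng(seed)
    model = tripartite_model()
    marker_map = synthio.uniform_marker_map(
        n_markers, n_chromosomes, chrom_length_cm, seed=rng.integers(2**31)
    )
    freqs = synthio.simulate_source_frequencies(model, n_markers, seed=rng.integers(2**31))

    source_pools = {
        name: synthio.simulate_haplotypes(
            freqs, name, source_pool_haplotypes, marker_map, seed=rng.integers(2**31)
        )
        for name in (*KHOESAN_SOURCES, "Bantu", "European")
    }

    khoesan_fracs = [0.8, 0.6, 0.4, 0.3, 0.7, 0.5, 0.8, 0.6]
    targets_parts, tract_parts = [], []
    source_of_pop, frac_of_pop = {}, {}
    for i in range(n_populations):
        pop = f"Pop{i+1}"
        ks = KHOESAN_SOURCES[i % len(KHOESAN_SOURCES)]
        frac = khoesan_fracs[i % len(khoesan_fracs)]
        source_of_pop[pop] = ks
        frac_of_pop[pop] = frac
        recipe = synthio.AdmixtureRecipe(
            pop,
            {ks: frac, "Bantu": 0.7 * (1 - frac), "European": 0.3 * (1 - frac)},
            generations,
            n_per_pop,
        )
        _, haps, tracts = synthio.simulate_admixed(
            recipe, source_pools, marker_map, seed=rng.integers(2**31)
        )
        targets_parts.append(haps)
        tract_parts.append(tracts.table)

    targets = HaplotypeSet(
        [h for part in targets_parts for h in part.hap_ids],
        [p for part in targets_parts for p in part.populations],
        marker_map,
        np.vstack([part.alleles for part in targets_parts]),
    )
    tracts = TractSet(pd.concat(tract_parts, ignore_index=True))

    donor_parts, donor_labels = [], []
    for name in KHOESAN_SOURCES:
        part = synthio.simulate_haplotypes(
            freqs, name, donors_per_source, marker_map,
            seed=rng.integers(2**31), id_prefix=f"donor_{name}",
        )
        donor_parts.append(part)
        donor_labels += ["Khoesan"] * donors_per_source
    for name in ("Bantu", "European"):
        part = synthio.simulate_haplotypes(
            freqs, name, donors_per_outgroup, marker_map,
            seed=rng.integers(2**31), id_prefix=f"donor_{name}",
        )
        donor_parts.append(part)
        donor_labels += [name] * donors_per_outgroup
    donor_haps = HaplotypeSet(
        [h for part in donor_parts for h in part.hap_ids],
        [p for part in donor_parts for p in part.populations],
        marker_map,
        np.vstack([part.alleles for part in donor_parts]),
    )
    donors = ReferencePanelSet.select_donors(donor_haps, donor_labels)
    return TripartiteCohort(
        targets, tracts, donors, source_of_pop, frac_of_pop, marker_map, freqs
    )


def masking_fidelity_check(
    seed: int = 0,
    markers_per_cm: float = 50.0,
    n_chromosomes: int = 5,
    chrom_length_cm: float = 60.0,
    n_per_group: int = 10,
    donors_per_outgroup: int = 25,
    confidence: float = 0.99,
) -> MisassignmentReport:
    """Deconvolution accuracy on pure-ancestry haplotypes at realistic
    marker density.

    SNP arrays carry on the order of 50-70 markers per cM genome-wide,
    which is the regime in which high-confidence local-ancestry calls on
    well-differentiated panels (pairwise FST >= 0.15) are essentially
    error-free; this check simulates donor panels and fresh single-
    ancestry haplotypes at that density, deconvolves, and reports the
    misassignment among windows called above ``confidence`` and the
    unassigned fraction.
    """
    rng = np.random.default_rng(seed)
    n_markers = int(markers_per_cm * n_chromosomes * chrom_length_cm)
    model = tripartite_model()
    marker_map = synthio.uniform_marker_map(
        n_markers, n_chromosomes, chrom_length_cm, seed=rng.integers(2**31)
    )
    freqs = synthio.simulate_source_frequencies(model, n_markers, seed=rng.integers(2**31))
    parts, labels = [], []
    per_source = donors_per_outgroup // len(KHOESAN_SOURCES) + 1
    for name in KHOESAN_SOURCES:
        part = synthio.simulate_haplotypes(
            freqs, name, per_source, marker_map,
            seed=rng.integers(2**31), id_prefix=f"donor_{name}",
        )
        parts.append(part)
        labels += ["Khoesan"] * per_source
    for name in ("Bantu", "European"):
        part = synthio.simulate_haplotypes(
            freqs, name, donors_per_outgroup, marker_map,
            seed=rng.integers(2**31), id_prefix=f"donor_{name}",
        )
        parts.append(part)
        labels += [name] * donors_per_outgroup
    donor_haps = HaplotypeSet(
        [h for p in parts for h in p.hap_ids],
        [q for p in parts for q in p.populations],
        marker_map,
        np.vstack([p.alleles for p in parts]),
    )
    donors = ReferencePanelSet.select_donors(donor_haps, labels)
    cohort = TripartiteCohort(
        donor_haps, TractSet(pd.DataFrame(
            columns=["hap_id", "chrom", "start_cm", "end_cm", "ancestry"])),
        donors, {}, {}, marker_map, freqs,
    )
    return validate_on_pure_haplotypes(
        cohort, n_per_group=n_per_group, confidence=confidence,
        seed=int(rng.integers(2**31)),
    )


def validate_on_pure_haplotypes(
    cohort: TripartiteCohort,
    n_per_group: int = 10,
    window_cm: float = 1.0,
    confidence: float = 0.99,
    switch_rate_per_cm: float = 0.1,
    seed: int = 7,
) -> MisassignmentReport:
    """Donor-panel accuracy check on haplotypes of known single ancestry.

    Fresh (non-donor) haplotypes are drawn from every source, deconvolved
    against the cohort's donor panels, and every window's truth is the
    haplotype's single genome-wide ancestry group — the design under
    which raw misassignments exist but the high-confidence filter should
    discard all of them.
    """
    rng = np.random.default_rng(seed)
    parts, groups = [], []
    for name in (*KHOESAN_SOURCES, "Bantu", "European"):
        part = synthio.simulate_haplotypes(
            cohort.frequencies, name, n_per_group, cohort.marker_map,
            seed=rng.integers(2**31), id_prefix=f"val_{name}",
        )
        parts.append(part)
        groups += [source_to_group(name)] * n_per_group
    pure = HaplotypeSet(
        [h for p in parts for h in p.hap_ids],
        [p for part in parts for p in part.populations],
        cohort.marker_map,
        np.vstack([p.alleles for p in parts]),
    )
    posterior = deconvolve(pure, cohort.donors, window_cm, switch_rate_per_cm)
    calls = call_ancestry(posterior, confidence)
    # single whole-genome tract per chromosome: truth is unambiguous
    chrom_lengths = {
        c: float(np.ceil(cohort.marker_map.table.loc[
            cohort.marker_map.table["chrom"] == c, "cm"].max()))
        for c in cohort.marker_map.chroms
    }
    rows = [
        (hid, c, 0.0, chrom_lengths[c], grp)
        for hid, grp in zip(pure.hap_ids, groups)
        for c in chrom_lengths
    ]
    truth = TractSet(
        pd.DataFrame(rows, columns=["hap_id", "chrom", "start_cm", "end_cm", "ancestry"])
    )
    return validate_calls(calls, truth)


@dataclass
class PipelineResult:
    """Everything the masking pipeline produces on one cohort."""

    calls: AncestryCalls
    validation: MisassignmentReport
    masked: MaskedHaplotypeSet
    distances: CorrectedDistanceMatrix
    mds: MDSConfiguration
    clusters: ClusterModel
    retained_hap_ids: list


def run_masking_pipeline(
    cohort: TripartiteCohort,
    window_cm: float = 1.0,
    confidence: float = 0.99,
    switch_rate_per_cm: float = 0.1,
    min_ancestry_fraction: float = 0.20,
    min_snp_retention: float = 0.10,
    min_shared_markers: int = 100,
    mds_dims: int = 10,
    cluster_dims: int = 2,
    k_range=range(1, 10),
    seed: int = 0,
) -> PipelineResult:
    """Deconvolve, mask to Khoesan fragments, embed, and cluster.

    Clustering runs on the first ``cluster_dims`` MDS dimensions (the
    embedding's leading components, as the structure analyses use).
    """
    posterior = deconvolve(
        cohort.targets, cohort.donors, window_cm, switch_rate_per_cm
    )
    calls = call_ancestry(posterior, confidence)
    validation = validate_calls(calls, cohort.group_tracts())

    haploids = haploidize(cohort.targets)
    masked = extract_fragments(haploids, calls, "Khoesan")
    masked = filter_samples(masked, min_ancestry_fraction, min_snp_retention)

    dmat = corrected_ibs_matrix(masked, min_shared=min_shared_markers).drop_incomplete_samples()
    mds = classical_mds(dmat, k=mds_dims)
    retained = flag_outlier_samples(mds)
    if len(retained) < len(mds.hap_ids):
        keep = np.array([hid in set(retained) for hid in dmat.hap_ids])
        idx = np.flatnonzero(keep)
        dmat = CorrectedDistanceMatrix(
            [dmat.hap_ids[i] for i in idx],
            [dmat.populations[i] for i in idx],
            dmat.distances[np.ix_(idx, idx)],
            dmat.pair_counts[np.ix_(idx, idx)],
        )
        mds = classical_mds(dmat, k=mds_dims)
    clusters = gmm_cluster(
        mds.coords[:, :cluster_dims],
        k_range=k_range,
        seed=seed,
        populations=mds.populations,
    )
    return PipelineResult(calls, validation, masked, dmat, mds, clusters, list(mds.hap_ids))
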