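"""Synthetic admixed-cohort generator.

Emulates the data structure the downstream analyses assume: several
divergent source populations (Balding–Nichols drift around a shared
ancestral frequency), phased haplotypes, per-individual admixture mosaics
with known tract structure, two partially overlapping genotyping-platform
marker panels with random missingness, and population metadata
(coordinates, language, subsistence).

Drift is parameterized by the Balding–Nichols F rather than explicit
Wright–Fisher generations; F and a (t generations, Ne) split are
interconvertible through ``1 - FST = (1 - 1/(2*Ne))**t``, so FST-calibrated
splits can be simulated at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    MISSING,
    GenotypePanel,
    HaplotypeSet,
    MarkerMap,
    PopMeta,
    TractSet,
    hap_id,
)

_BASES = np.array(list("ACGT"))
# allele pairs that survive the strand-ambiguity filter
_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("C", "G")]


def drift_from_split_time(t_generations: float, ne: float) -> float:
    """Balding–Nichols drift F for a population separated t generations
    at constant diploid effective size Ne: F = 1 - (1 - 1/(2*Ne))**t."""
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    if t_generations < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t_generations


@dataclass(frozen=True)
class Population:
    """One branch of the ancestral model.

    ``drift`` is the Balding–Nichols F of the branch leading to this
    population from its parent (``parent=None`` means the root ancestral
    pool). Supply either ``drift`` directly or a ``split_generations``
    that is converted using the population's ``ne``.
    """

    name: str
    drift: float
    ne: float = 10_000.0
    parent: str | None = None


@dataclass(frozen=True)
class AncestralModel:
    """Tree of source populations with per-branch drift parameters.

    The default construction is a star (clean multifurcation): every
    population drifts independently from one shared ancestral frequency.
    Serial splits are expressed by chaining ``parent`` references.
    """

    populations: tuple
    freq_low: float = 0.05
    freq_high: float = 0.95

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for p in self.populations:
            if not (0.0 <= p.drift < 1.0):
                raise ValueError(f"drift F must be in [0, 1) for {p.name}")
            if p.ne < 2:
                raise ValueError(f"Ne must be >= 2 for {p.name}")
            if p.parent is not None and p.parent not in names:
                raise ValueError(f"unknown parent {p.parent!r} for {p.name}")

    @property
    def names(self) -> list:
        return [p.name for p in self.populations]

    @classmethod
    def star(cls, drifts: dict, ne: float = 10_000.0, **kw) -> "AncestralModel":
        """Star phylogeny: each population with its own drift from the root."""
        pops = tuple(Population(name, f, ne=ne) for name, f in drifts.items())
        return cls(pops, **kw)

    @classmethod
    def from_split_times(cls, splits: dict, ne: float, **kw) -> "AncestralModel":
        """Star phylogeny with branch lengths in generations at size Ne."""
        drifts = {name: drift_from_split_time(t, ne) for name, t in splits.items()}
        return cls.star(drifts, ne=ne, **kw)


@dataclass(frozen=True)
class AdmixtureRecipe:
    """Admixture pulse: source proportions, depth in generations, cohort size."""

    name: str
    proportions: dict
    generations: int
    n_individuals: int

    def __post_init__(self) -> None:
        props = np.array(list(self.proportions.values()), dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if self.generations < 1:
            raise ValueError("generations since admixture must be >= 1")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def uniform_marker_map(
    n_markers: int,
    n_chromosomes: int = 1,
    chrom_length_cm: float = 100.0,
    seed: int | np.random.Generator = 0,
    ambiguous_fraction: float = 0.0,
    bp_per_cm: float = 1_000_000.0,
) -> MarkerMap:
    """Evenly spaced markers on equal-length chromosomes, linear cM map.

    ``ambiguous_fraction`` > 0 injects A/T and C/G allele pairs for QC
    tests; by default all pairs are strand-unambiguous.
    """
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_markers // n_chromosomes)
    per_chrom[: n_markers % n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(n_chromosomes):
        m = per_chrom[c]
        # offset by half a step so no marker sits at exactly 0 or the end
        cm = (np.arange(m) + 0.5) * (chrom_length_cm / m)
        for x in cm:
            if rng.random() < ambiguous_fraction:
                a1, a2 = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
            else:
                a1, a2 = _UNAMBIGUOUS_PAIRS[rng.integers(len(_UNAMBIGUOUS_PAIRS))]
            rows.append((f"rs{k}", c + 1, int(round(x * bp_per_cm)) + 1, x, a1, a2))
            k += 1
    return MarkerMap(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "cm", "a1", "a2"])
    )


def simulate_source_frequencies(
    model: AncestralModel, n_markers: int, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw per-population allele frequencies under Balding–Nichols drift.

    Ancestral frequencies are Uniform(freq_low, freq_high); each branch
    with drift F draws the child frequency from
    Beta(p*(1-F)/F, (1-p)*(1-F)/F), so E[p_child] = p and
    Var[p_child] = F * p * (1 - p). F = 0 copies the parent exactly.

    Returns a DataFrame with one column per population plus ``ancestral``.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(model.freq_low, model.freq_high, size=n_markers)
    freqs = {"ancestral": p_anc}
    # resolve parents before children
    pending = list(model.populations)
    while pending:
        progressed = False
        for pop in list(pending):
            parent = "ancestral" if pop.parent is None else pop.parent
            if parent not in freqs:
                continue
            p = freqs[parent]
            if pop.drift == 0.0:
                freqs[pop.name] = p.copy()
            else:
                # drifted parents can be numerically fixed; keep Beta valid
                p = np.clip(p, 1e-9, 1.0 - 1e-9)
                scale = (1.0 - pop.drift) / pop.drift
                freqs[pop.name] = rng.beta(p * scale, (1.0 - p) * scale)
            pending.remove(pop)
            progressed = True
        if not progressed:
            raise ValueError("cyclic parent structure in AncestralModel")
    return pd.DataFrame(freqs)


def simulate_haplotypes(
    freqs: pd.DataFrame,
    population: str,
    n_haplotypes: int,
    marker_map: MarkerMap,
    seed: int | np.random.Generator = 0,
    id_prefix: str | None = None,
) -> HaplotypeSet:
    """Phased haploid draws: allele ~ Bernoulli(p) independently per marker."""
    if population not in freqs.columns:
        raise KeyError(f"no frequencies for population {population!r}")
    if len(freqs) != len(marker_map):
        raise ValueError("frequency table and marker map lengths differ")
    rng = np.random.default_rng(seed)
    p = freqs[population].to_numpy(float)
    alleles = (rng.random((n_haplotypes, len(p))) < p).astype(np.int8)
    prefix = id_prefix or population
    ids = [f"{prefix}_h{i}" for i in range(n_haplotypes)]
    return HaplotypeSet(ids, [population] * n_haplotypes, marker_map, alleles)


def _sample_tracts(
    chrom_length_cm: float, g: int, proportions: dict, rng: np.random.Generator
) -> list:
    """Tracts on one chromosome: breakpoints Poisson(g per Morgan), labels i.i.d."""
    ancestries = list(proportions)
    probs = np.array([proportions[a] for a in ancestries], dtype=float)
    rate_per_cm = g / 100.0  # g per Morgan
    breaks = []
    x = 0.0
    while True:
        x += rng.exponential(1.0 / rate_per_cm) if rate_per_cm > 0 else np.inf
        if x >= chrom_length_cm:
            break
        breaks.append(x)
    edges = [0.0, *breaks, chrom_length_cm]
    labels = rng.choice(ancestries, size=len(edges) - 1, p=probs)
    return [(edges[i], edges[i + 1], labels[i]) for i in range(len(edges) - 1)]


def simulate_admixed(
    recipe: AdmixtureRecipe,
    source_haplotypes: dict,
    marker_map: MarkerMap,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Build admixed diploid individuals as recombination mosaics of source
    haplotypes.

    Per haplotype and chromosome, breakpoints follow a Poisson process of
    rate g per Morgan (g = generations since the admixture pulse) and each
    tract's ancestry is drawn i.i.d. from the recipe proportions — the
    standard pulse-admixture approximation. Alleles within a tract are
    copied from one randomly chosen source haplotype of that ancestry.

    Returns ``(GenotypePanel, HaplotypeSet, TractSet)``.
    """
    for anc, frac in recipe.proportions.items():
        if frac > 0 and anc not in source_haplotypes:
            raise KeyError(f"no source haplotypes for ancestry {anc!r}")
        if frac > 0 and source_haplotypes[anc].n_haplotypes == 0:
            raise ValueError(f"empty source pool for ancestry {anc!r}")
    rng = np.random.default_rng(seed)
    active = {a: f for a, f in recipe.proportions.items() if f > 0}

    chrom_col = marker_map.table["chrom"].to_numpy()
    cm_col = marker_map.table["cm"].to_numpy(float)
    chrom_lengths = {}
    for c in marker_map.chroms:
        # nominal chromosome length: ceiling of the last marker's cM position
        chrom_lengths[c] = float(np.ceil(cm_col[chrom_col == c].max()))

    n = recipe.n_individuals
    hap_alleles = np.empty((2 * n, len(marker_map)), dtype=np.int8)
    hap_ids, tract_rows = [], []
    for ind in range(n):
        ind_id = f"{recipe.name}_{ind}"
        for copy in (0, 1):
            hid = hap_id(ind_id, copy)
            hap_ids.append(hid)
            row = 2 * ind + copy
            for c in marker_map.chroms:
                in_chrom = chrom_col == c
                cms = cm_col[in_chrom]
                idx = np.flatnonzero(in_chrom)
                for start, end, anc in _sample_tracts(
                    chrom_lengths[c], recipe.generations, active, rng
                ):
                    tract_rows.append((hid, c, start, end, anc))
                    pool = source_haplotypes[anc]
                    donor = rng.integers(pool.n_haplotypes)
                    # terminal tract is end-inclusive so a marker at the
                    # chromosome end is always covered
                    in_tract = (cms >= start) & (
                        (cms < end) if end < chrom_lengths[c] else (cms <= end)
                    )
                    hap_alleles[row, idx[in_tract]] = pool.alleles[donor, idx[in_tract]]
    tracts = TractSet(
        pd.DataFrame(
            tract_rows, columns=["hap_id", "chrom", "start_cm", "end_cm", "ancestry"]
        )
    )
    ind_ids = [f"{recipe.name}_{i}" for i in range(n)]
    haps = HaplotypeSet(hap_ids, [recipe.name] * 2 * n, marker_map, hap_alleles)
    genotypes = hap_alleles[0::2] + hap_alleles[1::2]
    panel = GenotypePanel(ind_ids, [recipe.name] * n, marker_map, genotypes)
    return panel, haps, tracts


def make_platform_panels(
    marker_map: MarkerMap, overlap_fraction: float, seed: int | np.random.Generator = 0
) -> tuple:
    """Split the marker set into two platform panels sharing a stated
    overlap fraction of all markers; the rest is divided evenly."""
    if not (0.0 < overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    perm = rng.permutation(m)
    n_shared = int(round(overlap_fraction * m))
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    half = len(rest) // 2
    idx_a = np.sort(np.concatenate([shared, rest[:half]]))
    idx_b = np.sort(np.concatenate([shared, rest[half:]]))
    return idx_a, idx_b


def apply_platforms(
    panel: GenotypePanel,
    panel_specs: tuple,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    platform_names: tuple = ("arrayA", "arrayB"),
) -> tuple:
    """Restrict a genotype panel to two platform marker subsets and inject
    i.i.d. missingness at ``missing_rate``.

    Returns ``(GenotypePanel, GenotypePanel, overlap_positions)`` where
    the overlap is the set of (chrom, pos) keys shared by the panels.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    idx_a, idx_b = (np.asarray(ix) for ix in panel_specs)
    overlap = sorted(
        set(map(tuple, panel.markers.table.iloc[idx_a][["chrom", "pos"]].to_numpy()))
        & set(map(tuple, panel.markers.table.iloc[idx_b][["chrom", "pos"]].to_numpy()))
    )
    if not overlap:
        raise ValueError("platform panels share no markers")
    rng = np.random.default_rng(seed)
    out = []
    for idx, name in zip((idx_a, idx_b), platform_names):
        sub = panel.subset_markers(idx)
        geno = sub.genotypes.copy()
        if missing_rate > 0:
            geno[rng.random(geno.shape) < missing_rate] = MISSING
        out.append(
            GenotypePanel(sub.sample_ids, sub.populations, sub.markers, geno, name)
        )
    return out[0], out[1], overlap


_LANGUAGE_FAMILIES = ["Kx'a", "Tuu", "Khoe-Kwadi", "Bantu", "Indo-European"]
_SUBSISTENCE_1 = ["forager", "herder", "farmer"]
_SUBSISTENCE_2 = ["forager-herder", "farmer"]


def assign_metadata(
    ancestry_proportions: pd.DataFrame,
    strength: float = 1.0,
    seed: int | np.random.Generator = 0,
    lat_range: tuple = (-34.0, -17.0),
    lon_range: tuple = (12.0, 32.0),
) -> PopMeta:
    """Assign coordinates and cultural covariates to populations.

    ``ancestry_proportions`` is a populations x ancestries table of mean
    ancestry fractions. At ``strength`` 1 the coordinates are a
    similarity transform (rotation + uniform scale + translation) of the
    proportions' 2-D principal-coordinate image, so genetics and
    geography superpose exactly; at 0 coordinates are independent noise;
    in between the two parts are mixed. Language and subsistence labels
    are drawn at random per population under the seed.
    """
    rng = np.random.default_rng(seed)
    pops = list(ancestry_proportions.index)
    props = ancestry_proportions.to_numpy(float)
    centered = props - props.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    signal = u[:, :2] * s[:2]
    noise = rng.normal(size=(len(pops), 2))

    def _unit_norm(x: np.ndarray) -> np.ndarray:
        x = x - x.mean(axis=0)
        norm = np.linalg.norm(x)
        return x / (norm if norm > 0 else 1.0)

    raw = strength * _unit_norm(signal) + (1.0 - strength) * _unit_norm(noise)
    q, _ = np.linalg.qr(rng.normal(size=(2, 2)))  # random rotation/reflection
    raw = raw @ q
    # uniform scale + translation into the configured lat/lon box
    half_span = np.abs(raw - raw.mean(axis=0)).max(axis=0)
    half_span = np.where(half_span > 0, half_span, 1.0)
    box_half = np.array(
        [(lat_range[1] - lat_range[0]) / 2.0, (lon_range[1] - lon_range[0]) / 2.0]
    )
    scale = (box_half / half_span).min()
    fitted = (raw - raw.mean(axis=0)) * scale
    lat = (lat_range[0] + lat_range[1]) / 2.0 + fitted[:, 0]
    lon = (lon_range[0] + lon_range[1]) / 2.0 + fitted[:, 1]
    table = pd.DataFrame(
        {
            "population": pops,
            "lat": lat,
            "lon": lon,
            "language": rng.choice(_LANGUAGE_FAMILIES, size=len(pops)),
            "subsistence1": rng.choice(_SUBSISTENCE_1, size=len(pops)),
            "subsistence2": rng.choice(_SUBSISTENCE_2, size=len(pops)),
        }
    )
    return PopMeta(table)


@dataclass
class CohortConfig:
    """Structured configuration for a full synthetic cohort."""

    model: AncestralModel
    recipes: tuple
    n_markers: int
    n_chromosomes: int
    chrom_length_cm: float
    donor_haplotypes_per_source: int = 25
    platform_overlap: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = tuple(
            Population(
                p["name"],
                drift=(
                    p["drift"]
                    if "drift" in p
                    else drift_from_split_time(p["split_generations"], p.get("ne", 10_000))
                ),
                ne=p.get("ne", 10_000.0),
                parent=p.get("parent"),
            )
            for p in raw["populations"]
        )
        recipes = tuple(
            AdmixtureRecipe(
                r["name"], r["proportions"], r["generations"], r["n_individuals"]
            )
            for r in raw.get("recipes", ())
        )
        return cls(
            model=AncestralModel(pops),
            recipes=recipes,
            n_markers=raw["n_markers"],
            n_chromosomes=raw.get("n_chromosomes", 1),
            chrom_length_cm=raw.get("chrom_length_cm", 100.0),
            donor_haplotypes_per_source=raw.get("donor_haplotypes_per_source", 25),
            platform_overlap=raw.get("platform_overlap", 0.5),
            missing_rate=raw.get("missing_rate", 0.0),
            seed=raw.get("seed", 0),
        )
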