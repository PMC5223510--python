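"""Synthetic-cohort generator: drift moments, mosaic structure, platforms."""

import numpy as np
import pandas as pd
import pytest

from lamix import synthio
from lamix.core import MISSING, TractSet
from lamix.popgen_stats import hudson_fst


def star_model(f, names=("p1", "p2")):
    return synthio.AncestralModel.star({n: f for n in names})


class TestAncestralModel:
    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError):
            synthio.AncestralModel.star({"a": 1.0, "b": 0.1})

    def test_duplicate_names_rejected(self):
        pops = (synthio.Population("a", 0.1), synthio.Population("a", 0.2))
        with pytest.raises(ValueError):
            synthio.AncestralModel(pops)

    def test_drift_from_split_time_matches_formula(self):
        # 1 - F = (1 - 1/(2 Ne))^t, evaluated directly
        f = synthio.drift_from_split_time(850, 12_302)
        assert f == pytest.approx(1 - (1 - 1 / (2 * 12_302)) ** 850, rel=1e-12)


class TestSourceFrequencies:
    def test_zero_drift_copies_ancestral(self):
        freqs = synthio.simulate_source_frequencies(star_model(0.0), 500, seed=0)
        np.testing.assert_array_equal(freqs["p1"], freqs["ancestral"])

    def test_balding_nichols_variance(self):
        # Var[p_child | p_anc] = F * p * (1-p); at p=0.5, F=0.05 -> 0.0125
        model = synthio.AncestralModel.star({"p1": 0.05}, **{})
        model = synthio.AncestralModel(
            (synthio.Population("p1", 0.05),), freq_low=0.5, freq_high=0.5
        )
        freqs = synthio.simulate_source_frequencies(model, 50_000, seed=2)
        var = freqs["p1"].var()
        assert var == pytest.approx(0.0125, rel=0.10)
        assert freqs["p1"].mean() == pytest.approx(0.5, abs=0.01)

    def test_frequencies_in_unit_interval(self):
        freqs = synthio.simulate_source_frequencies(star_model(0.3), 2_000, seed=3)
        assert ((freqs >= 0) & (freqs <= 1)).all().all()

    def test_hudson_fst_recovers_drift(self):
        # two children of an F=0.05 split show pairwise Hudson FST ~ F
        freqs = synthio.simulate_source_frequencies(star_model(0.05), 100_000, seed=4)
        res = hudson_fst(freqs["p1"], freqs["p2"], 1_000_000, 1_000_000)
        assert res.fst == pytest.approx(0.05, rel=0.05)


class TestHaplotypes:
    def test_fixed_marker_all_alternate(self, small_map):
        freqs = pd.DataFrame({"p": np.ones(50)})
        haps = synthio.simulate_haplotypes(freqs, "p", 20, small_map, seed=0)
        assert (haps.alleles == 1).all()

    def test_allele_frequency_matches_binomial(self, small_map):
        freqs = pd.DataFrame({"p": np.full(50, 0.5)})
        haps = synthio.simulate_haplotypes(freqs, "p", 1000, small_map, seed=1)
        np.testing.assert_allclose(haps.alleles.mean(axis=0), 0.5, atol=0.05)

    def test_unknown_population_raises(self, small_map):
        with pytest.raises(KeyError):
            synthio.simulate_haplotypes(pd.DataFrame({"p": [0.5]}), "q", 1, small_map)

    def test_same_frequencies_same_ibs_distribution(self, small_map):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        freqs = pd.DataFrame({"x": rng.uniform(0.1, 0.9, 50)})
        a = synthio.simulate_haplotypes(freqs, "x", 60, small_map, seed=6)
        b = synthio.simulate_haplotypes(freqs, "x", 60, small_map, seed=7)

        def pair_ibs(h):
            m = h.alleles
            eq = (m[:, None, :] == m[None, :, :]).mean(axis=2)
            return eq[np.triu_indices(len(m), k=1)]

        stat = ks_2samp(pair_ibs(a), pair_ibs(b))
        assert stat.pvalue > 0.01


class TestAdmixed:
    @pytest.fixture()
    def sources(self, small_map):
        freqs = synthio.simulate_source_frequencies(star_model(0.2), 50, seed=8)
        return {
            name: synthio.simulate_haplotypes(freqs, name, 30, small_map, seed=i)
            for i, name in enumerate(("p1", "p2"))
        }

    def test_single_source_recipe_gives_single_tracts(self, small_map, sources):
        recipe = synthio.AdmixtureRecipe("t", {"p1": 1.0, "p2": 0.0}, 10, 4)
        _, _, tracts = synthio.simulate_admixed(recipe, sources, small_map, seed=0)
        assert set(tracts.table["ancestry"]) == {"p1"}

    def test_tract_tiling_exact(self, small_map, sources):
        recipe = synthio.AdmixtureRecipe("t", {"p1": 0.5, "p2": 0.5}, 8, 5)
        _, _, tracts = synthio.simulate_admixed(recipe, sources, small_map, seed=1)
        tracts.validate_tiling({1: 10.0, 2: 10.0})

    def test_breakpoint_process_moments(self):
        # g=10 over 10 Morgans: ~100 breakpoints, mean tract 10 cM
        mm = synthio.uniform_marker_map(1000, 10, 100.0, seed=2)
        freqs = synthio.simulate_source_frequencies(star_model(0.2), 1000, seed=3)
        pools = {
            n: synthio.simulate_haplotypes(freqs, n, 20, mm, seed=i)
            for i, n in enumerate(("p1", "p2"))
        }
        recipe = synthio.AdmixtureRecipe("t", {"p1": 0.5, "p2": 0.5}, 10, 30)
        _, _, tracts = synthio.simulate_admixed(recipe, pools, mm, seed=4)
        tab = tracts.table
        n_hap = 60
        breakpoints = (len(tab) - 10 * n_hap) / n_hap  # tracts minus one per chrom
        assert breakpoints == pytest.approx(100, rel=0.15)
        mean_len = (tab["end_cm"] - tab["start_cm"]).mean()
        assert mean_len == pytest.approx(10.0, rel=0.15)

    def test_cohort_mean_ancestry_fraction(self):
        # 20% mixture recipe, 25 individuals -> cohort mean 0.20 +- 0.03
        mm = synthio.uniform_marker_map(500, 10, 100.0, seed=5)
        freqs = synthio.simulate_source_frequencies(star_model(0.2), 500, seed=6)
        pools = {
            n: synthio.simulate_haplotypes(freqs, n, 20, mm, seed=i)
            for i, n in enumerate(("p1", "p2"))
        }
        recipe = synthio.AdmixtureRecipe("t", {"p1": 0.2, "p2": 0.8}, 10, 25)
        _, _, tracts = synthio.simulate_admixed(recipe, pools, mm, seed=7)
        fracs = [tracts.genome_fraction(h, "p1") for h in set(tracts.table["hap_id"])]
        assert np.mean(fracs) == pytest.approx(0.20, abs=0.03)

    def test_missing_source_pool_raises(self, small_map, sources):
        recipe = synthio.AdmixtureRecipe("t", {"p1": 0.5, "p3": 0.5}, 5, 2)
        with pytest.raises(KeyError):
            synthio.simulate_admixed(recipe, sources, small_map, seed=0)


class TestPlatforms:
    def test_overlap_arithmetic(self):
        mm = synthio.uniform_marker_map(40_000, 4, 100.0, seed=0)
        idx_a, idx_b = synthio.make_platform_panels(mm, 0.25, seed=1)
        assert len(set(idx_a) & set(idx_b)) == 10_000

    def test_no_missing_is_exact_subset(self, small_panel):
        idx_a, idx_b = synthio.make_platform_panels(small_panel.markers, 0.5, seed=2)
        pa, pb, overlap = synthio.apply_platforms(small_panel, (idx_a, idx_b), 0.0, seed=3)
        np.testing.assert_array_equal(pa.genotypes, small_panel.genotypes[:, idx_a])
        np.testing.assert_array_equal(pb.genotypes, small_panel.genotypes[:, idx_b])
        assert len(overlap) == len(set(idx_a) & set(idx_b))

    def test_missing_rate_binomial(self):
        mm = synthio.uniform_marker_map(4000, 2, 100.0, seed=4)
        rng = np.random.default_rng(5)
        from lamix.core import GenotypePanel

        panel = GenotypePanel(
            [f"s{i}" for i in range(10)], ["p"] * 10, mm,
            rng.integers(0, 3, size=(10, 4000)).astype(np.int8),
        )
        idx_a, idx_b = synthio.make_platform_panels(mm, 0.5, seed=6)
        pa, _, _ = synthio.apply_platforms(panel, (idx_a, idx_b), 0.05, seed=7)
        per_sample = (pa.genotypes == MISSING).mean(axis=1)
        np.testing.assert_allclose(per_sample, 0.05, atol=0.01)


class TestMetadata:
    @staticmethod
    def proportions():
        rng = np.random.default_rng(9)
        props = rng.dirichlet(np.ones(3), size=8)
        return pd.DataFrame(props, index=[f"P{i}" for i in range(8)])

    def test_full_strength_is_affine_image(self):
        from lamix.geo_culture import procrustes_correlation

        props = self.proportions()
        meta = synthio.assign_metadata(props, strength=1.0, seed=0)
        # proportions live in a 2-simplex: compare against their 2-D PCA image
        x = props.to_numpy() - props.to_numpy().mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        coords = meta.table[["lat", "lon"]].to_numpy()
        assert procrustes_correlation(u[:, :2] * s[:2], coords) > 0.99

    def test_deterministic_under_seed(self):
        props = self.proportions()
        a = synthio.assign_metadata(props, strength=0.5, seed=42)
        b = synthio.assign_metadata(props, strength=0.5, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_strength_null_calibration(self):
        from scipy.stats import kstest

        from lamix.geo_culture import procrustes_test

        props = self.proportions()
        pvals = []
        for seed in range(200):
            meta = synthio.assign_metadata(props, strength=0.0, seed=seed)
            coords = meta.table[["lat", "lon"]].to_numpy()
            rng = np.random.default_rng(seed + 1000)
            other = rng.normal(size=coords.shape)
            _, p = procrustes_test(coords, other, n_iter=99, seed=seed)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestDeterminism:
    def test_generators_bit_reproducible(self, small_map):
        model = star_model(0.1)
        f1 = synthio.simulate_source_frequencies(model, 50, seed=3)
        f2 = synthio.simulate_source_frequencies(model, 50, seed=3)
        pd.testing.assert_frame_equal(f1, f2)
        h1 = synthio.simulate_haplotypes(f1, "p1", 10, small_map, seed=4)
        h2 = synthio.simulate_haplotypes(f2, "p1", 10, small_map, seed=4)
        np.testing.assert_array_equal(h1.alleles, h2.alleles)
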