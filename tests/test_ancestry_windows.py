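"""Window grid, PCA scoring, Gaussian emissions, HMM smoothing, calls."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_marker_map
from lamix import ancestry_windows as aw
from lamix.core import HaplotypeSet, TractSet


class TestWindowGrid:
    def test_integer_extent(self):
        mm = make_marker_map(np.arange(100) * 0.1 + 0.05)  # extent 9.95 -> 10 windows
        grid = aw.build_window_grid(mm, 1.0)
        assert grid.n_windows == 10

    def test_fractional_extent_short_last_window(self):
        cms = list(np.arange(0.2, 10.4, 0.2)) + [10.4]
        grid = aw.build_window_grid(make_marker_map(cms), 1.0)
        assert grid.n_windows == 11
        last = grid.windows.iloc[-1]
        assert last["end_cm"] - last["start_cm"] == pytest.approx(0.4)

    def test_boundary_marker_in_right_window(self):
        grid = aw.build_window_grid(make_marker_map([0.5, 1.0, 1.5, 2.5]), 1.0)
        w1_members = grid.marker_index[1]
        assert 1 in w1_members  # marker at exactly 1.0 cM -> window [1, 2)

    def test_every_marker_in_exactly_one_window(self):
        mm = make_marker_map(np.sort(np.random.default_rng(0).uniform(0, 25, 200)))
        grid = aw.build_window_grid(mm, 1.0)
        all_members = np.concatenate(grid.marker_index)
        assert sorted(all_members) == list(range(200))


def two_group_donors(n_markers=20, n_donors=10, delta=1.0, seed=0):
    """Donor haplotypes from two groups with allele-frequency offset delta."""
    rng = np.random.default_rng(seed)
    mm = make_marker_map(np.arange(n_markers) * 0.04 + 0.02)
    pa = np.full(n_markers, 0.5 - delta / 2)
    pb = np.full(n_markers, 0.5 + delta / 2)
    alleles = np.vstack(
        [
            rng.binomial(1, pa, size=(n_donors, n_markers)),
            rng.binomial(1, pb, size=(n_donors, n_markers)),
        ]
    ).astype(np.int8)
    ids = [f"d{i}" for i in range(2 * n_donors)]
    labels = ["A"] * n_donors + ["B"] * n_donors
    return HaplotypeSet(ids, labels, mm, alleles), np.array(labels)


class TestWindowScores:
    def test_fixed_difference_groups_separate_on_pc1(self):
        haps, labels = two_group_donors(delta=1.0)
        d, _, ok = aw.window_scores(haps.alleles, haps.alleles[:1], 1)
        assert ok
        a, b = d[labels == "A", 0], d[labels == "B", 0]
        within_sd = max(a.std(), b.std(), 1e-9)
        assert abs(a.mean() - b.mean()) > 10 * within_sd

    def test_target_equal_to_donor_same_score(self):
        haps, _ = two_group_donors(delta=0.6, seed=1)
        d, t, ok = aw.window_scores(haps.alleles, haps.alleles[:3], 1)
        np.testing.assert_allclose(t, d[:3])

    def test_monomorphic_window_uninformative(self):
        alleles = np.ones((10, 8), dtype=np.int8)
        _, _, ok = aw.window_scores(alleles, alleles[:2], 1)
        assert not ok

    def test_too_few_markers_uninformative(self):
        haps, _ = two_group_donors()
        _, _, ok = aw.window_scores(haps.alleles[:, :3], haps.alleles[:1, :3], 1)
        assert not ok


class TestWindowLikelihoods:
    def test_target_at_centroid_strongly_favored(self):
        rng = np.random.default_rng(2)
        d = np.vstack([rng.normal(-5, 0.3, (20, 1)), rng.normal(5, 0.3, (20, 1))])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        lik = aw.window_likelihoods(d, labels, np.array([[-5.0]]), ["A", "B"],
                                    emission_floor=0.0)
        assert lik[0, 0] / lik[0, 1] > 100

    def test_equidistant_target_symmetric(self):
        d = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        labels = np.array(["A", "A", "B", "B"])
        lik = aw.window_likelihoods(d, labels, np.array([[0.0]]), ["A", "B"])
        np.testing.assert_allclose(lik[0], [0.5, 0.5])


def uniform_grid(n_windows, chrom=1):
    cms = np.arange(n_windows) + 0.5
    return aw.build_window_grid(make_marker_map(cms), 1.0)


class TestHmmSmooth:
    def test_large_switch_rate_recovers_likelihoods(self):
        rng = np.random.default_rng(3)
        lik = rng.dirichlet(np.ones(3), size=(4, 6))
        grid = uniform_grid(6)
        post = aw.hmm_smooth(lik, grid, [f"h{i}" for i in range(4)], list("ABC"),
                             switch_rate_per_cm=1e6)
        np.testing.assert_allclose(post.posteriors, lik, atol=1e-6)

    def test_uniform_likelihoods_stay_uniform(self):
        lik = np.full((2, 5, 2), 0.5)
        grid = uniform_grid(5)
        post = aw.hmm_smooth(lik, grid, ["h0", "h1"], ["A", "B"], 0.1)
        np.testing.assert_allclose(post.posteriors, 0.5)

    def test_ambiguous_middle_window_pulled_to_neighbours(self):
        # hand forward-backward on a 2-state, 3-window chain; the trailing
        # marker at 3.0 cM makes all three windows full 1 cM (midpoint gaps 1)
        lik = np.array([[[0.9, 0.1], [0.5, 0.5], [0.9, 0.1]]])
        grid = aw.build_window_grid(make_marker_map([0.5, 1.5, 2.5, 3.0]), 1.0)
        post = aw.hmm_smooth(lik, grid, ["h0"], ["A", "B"], 0.1)
        assert post.posteriors[0, 1, 0] > 0.5
        # independent oracle: brute-force sum over the 8 state paths
        stay = np.exp(-0.1 * 1.0)
        trans = stay * np.eye(2) + (1 - stay) * np.full((2, 2), 0.5)
        joint = np.zeros((2, 2, 2))
        for s0 in (0, 1):
            for s1 in (0, 1):
                for s2 in (0, 1):
                    joint[s0, s1, s2] = (
                        0.5 * lik[0, 0, s0] * trans[s0, s1] * lik[0, 1, s1]
                        * trans[s1, s2] * lik[0, 2, s2]
                    )
        marg1 = joint.sum(axis=(0, 2))
        np.testing.assert_allclose(
            post.posteriors[0, 1], marg1 / marg1.sum(), atol=1e-12
        )

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(4)
        lik = rng.dirichlet(np.ones(3), size=(5, 12))
        grid = uniform_grid(12)
        post = aw.hmm_smooth(lik, grid, [f"h{i}" for i in range(5)], list("ABC"), 0.2)
        np.testing.assert_allclose(post.posteriors.sum(axis=2), 1.0, atol=1e-9)


class TestCalls:
    @staticmethod
    def posterior_from(p):
        p = np.asarray(p)[None, :, :]
        grid = uniform_grid(p.shape[1])
        return aw.AncestryPosterior(["h0"], grid, ["A", "B"], p.copy(), p)

    def test_confident_window_called(self):
        post = self.posterior_from([[0.995, 0.005]])
        calls = aw.call_ancestry(post, 0.99)
        assert calls.calls[0, 0] == 0

    def test_below_threshold_unassigned(self):
        post = self.posterior_from([[0.98, 0.02]])
        calls = aw.call_ancestry(post, 0.99)
        assert calls.calls[0, 0] == aw.UNASSIGNED

    def test_zero_threshold_calls_everything(self):
        post = self.posterior_from([[0.6, 0.4], [0.51, 0.49]])
        calls = aw.call_ancestry(post, 0.0)
        assert (calls.calls != aw.UNASSIGNED).all()


class TestValidateCalls:
    @staticmethod
    def calls_and_truth(call_codes, truth_label="A", n_windows=None):
        call_codes = np.asarray(call_codes)[None, :]
        n_windows = n_windows or call_codes.shape[1]
        grid = uniform_grid(n_windows)
        calls = aw.AncestryCalls(["h0"], grid, ["A", "B"], call_codes, 0.99)
        extent = grid.windows["end_cm"].max()
        truth = TractSet(
            pd.DataFrame(
                {
                    "hap_id": ["h0"],
                    "chrom": [1],
                    "start_cm": [0.0],
                    "end_cm": [extent],
                    "ancestry": [truth_label],
                }
            )
        )
        return calls, truth

    def test_perfect_calls_zero_misassignment(self):
        calls, truth = self.calls_and_truth([0, 0, 0, 0])
        rep = aw.validate_calls(calls, truth)
        assert rep.misassignment_rate == 0.0
        assert rep.unassigned_fraction == 0.0

    def test_one_wrong_in_two_hundred(self):
        codes = np.zeros(200, dtype=int)
        codes[17] = 1
        calls, truth = self.calls_and_truth(codes)
        rep = aw.validate_calls(calls, truth)
        assert rep.misassignment_rate == pytest.approx(0.005)

    def test_unassigned_fraction_counted(self):
        calls, truth = self.calls_and_truth([0, aw.UNASSIGNED, 0, aw.UNASSIGNED])
        rep = aw.validate_calls(calls, truth)
        assert rep.unassigned_fraction == pytest.approx(0.5)

    def test_fifty_fifty_window_misassigned_for_either_call(self):
        # truth split exactly 50/50 inside the single [0, 1) window
        grid = aw.build_window_grid(make_marker_map([0.5, 1.0]), 1.0)
        calls = aw.AncestryCalls(["h0"], grid, ["A", "B"], np.array([[0]]), 0.99)
        truth = TractSet(
            pd.DataFrame(
                {
                    "hap_id": ["h0", "h0"],
                    "chrom": [1, 1],
                    "start_cm": [0.0, 0.5],
                    "end_cm": [0.5, 1.0],
                    "ancestry": ["A", "B"],
                }
            )
        )
        rep = aw.validate_calls(calls, truth)
        assert rep.misassignment_rate == 1.0


class TestConfidenceMonotonicity:
    def test_raising_threshold_never_raises_misassignment(self, tripartite_cohort):
        from lamix import workflows
        from lamix.ancestry_windows import call_ancestry, deconvolve, validate_calls

        sub = tripartite_cohort.targets.subset_haplotypes(np.arange(10))
        posterior = deconvolve(sub, tripartite_cohort.donors)
        truth = tripartite_cohort.group_tracts()
        rates = []
        for conf in (0.0, 0.5, 0.9, 0.99):
            rep = validate_calls(call_ancestry(posterior, conf), truth)
            rates.append(rep.misassignment_rate)
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))
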