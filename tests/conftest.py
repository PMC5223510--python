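"""Shared fixtures: small synthetic panels and the session-scoped
acceptance-scale cohort (simulated once, reused by the heavy tests)."""

import numpy as np
import pandas as pd
import pytest

from lamix import synthio, workflows
from lamix.core import GenotypePanel, HaplotypeSet, MarkerMap


@pytest.fixture()
def small_map():
    return synthio.uniform_marker_map(50, n_chromosomes=2, chrom_length_cm=10.0, seed=0)


@pytest.fixture()
def small_panel(small_map):
    rng = np.random.default_rng(1)
    geno = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
    return GenotypePanel(
        [f"s{i}" for i in range(6)], ["popA"] * 3 + ["popB"] * 3, small_map, geno, "arrayA"
    )


@pytest.fixture(scope="session")
def tripartite_cohort():
    """Acceptance-scale cohort: 8 populations x 20 individuals, 20k markers,
    10 chromosomes x 100 cM, 30-80% Khoesan ancestry."""
    return workflows.simulate_tripartite_cohort(seed=11)


@pytest.fixture(scope="session")
def pipeline_result(tripartite_cohort):
    """Full deconvolve -> mask -> embed -> cluster run on the cohort."""
    return workflows.run_masking_pipeline(tripartite_cohort, seed=11)


def make_marker_map(cms, chrom=1, alleles=("A", "G")):
    """Hand-built marker map at explicit cM positions (single chromosome)."""
    cms = list(cms)
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(cms))],
                "chrom": chrom,
                "pos": [int(c * 1e6) + 1 for c in cms],
                "cm": cms,
                "a1": alleles[0],
                "a2": alleles[1],
            }
        )
    )
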