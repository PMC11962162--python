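import numpy as np
import pandas as pd
import pytest

from tetherscan import (BinnedGenome, ContactMatrix, FeatureSet,
                        LibraryStats, standard_scenario)


@pytest.fixture
def toy_genome():
    """One 4-bin host chromosome plus a 1-bin plasmid contig."""
    return BinnedGenome(
        names=("chrI", "plasmid"), lengths=(8000, 2000), bin_size=2000,
        plasmids=frozenset({"plasmid"}),
    )


@pytest.fixture
def two_chrom_genome():
    return BinnedGenome(
        names=("chrI", "chrII", "plasmid"), lengths=(20000, 12000, 2000),
        bin_size=2000, plasmids=frozenset({"plasmid"}),
    )


@pytest.fixture
def toy_features():
    return FeatureSet(pd.DataFrame({
        "chrom": ["chrI", "chrI"],
        "start": [0, 4000],
        "end": [2000, 6000],
        "name": ["geneA", "geneB"],
        "feat_class": ["gene", "gene"],
    }))


def make_matrix(genome, triplets):
    """Build a ContactMatrix from (chrom, bin, chrom, bin, count) tuples."""
    i = [genome.flat_index(c1, b1) for c1, b1, _, _, _ in triplets]
    j = [genome.flat_index(c2, b2) for _, _, c2, b2, _ in triplets]
    c = [t[4] for t in triplets]
    return ContactMatrix(genome, i, j, c)


@pytest.fixture(scope="session")
def mini_scenario():
    """Scaled-down tether scenario for fast integration tests."""
    return standard_scenario(
        seed=7, n_sites=8, fold=5.0, depth=1_000_000,
        n_chromosomes=4, total_size=2_000_000, n_genes=400,
    )


@pytest.fixture(scope="session")
def scenario_runs():
    """Ten independent realisations of the reference scenario, each scored
    and peak-called once (shared by the recovery and enrichment checks)."""
    from tetherscan import call_peaks, compute_contact_profile, \
        interpolate_profile

    runs = []
    for seed in range(10):
        sc = standard_scenario(seed=seed)
        plasmid = next(iter(sc["genome"].plasmids))
        profile = compute_contact_profile(sc["matrix"], plasmid,
                                          sc["stats"])
        peaks = call_peaks(interpolate_profile(profile))
        runs.append({**sc, "profile": profile, "peaks": peaks})
    return runs
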