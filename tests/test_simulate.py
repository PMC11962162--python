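"""The synthetic-data generator: determinism, declared structure, truth."""

import numpy as np
import pandas as pd
import pytest

from tetherscan import (FeatureSet, GeneParams, SyntheticTruth,
                        call_peaks, compute_contact_profile,
                        interpolate_profile, recovery_metrics,
                        retention_proportion, simulate_contact_data,
                        simulate_genome, simulate_stability_assay,
                        simulate_tracks, standard_scenario, verify_truth)


SMALL = dict(n_chromosomes=4, total_size=2_000_000)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        gp = GeneParams(n_genes=300, n_long=5)
        g1, f1, e1 = simulate_genome(gene_params=gp, seed=3, **SMALL)
        g2, f2, e2 = simulate_genome(gene_params=gp, seed=3, **SMALL)
        assert g1 == g2
        pd.testing.assert_frame_equal(f1.table, f2.table)

    def test_requested_long_gene_count_exact(self):
        gp = GeneParams(n_genes=500, n_long=20)
        _, features, _ = simulate_genome(gene_params=gp, seed=1, **SMALL)
        genes = features.of_class("gene").table
        assert (genes["length"] > 7000).sum() == 20

    def test_degenerate_length_distribution(self):
        gp = GeneParams(n_genes=200, n_long=0, length_sigma=0.0)
        _, features, _ = simulate_genome(gene_params=gp, seed=0, **SMALL)
        genes = features.of_class("gene").table
        assert float(genes["length"].median()) == 1000.0

    def test_median_length_near_one_kb(self):
        _, features, _ = simulate_genome(seed=5)
        genes = features.of_class("gene").table
        assert 800 <= genes["length"].median() <= 1250

    def test_genes_do_not_overlap(self):
        gp = GeneParams(n_genes=400, n_long=10)
        _, features, _ = simulate_genome(gene_params=gp, seed=2, **SMALL)
        genes = features.of_class("gene").table
        for _, grp in genes.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] >=
                    grp["end"].to_numpy()[:-1]).all()

    def test_one_centromere_per_chromosome(self):
        genome, features, _ = simulate_genome(
            gene_params=GeneParams(n_genes=100, n_long=0), seed=0, **SMALL)
        cen = features.of_class("centromere").table
        assert sorted(cen["chrom"]) == sorted(genome.host_chromosomes)

    def test_infeasible_packing_errors(self):
        gp = GeneParams(n_genes=5000, n_long=100)
        with pytest.raises(ValueError, match="packing"):
            simulate_genome(gene_params=gp, seed=0, **SMALL)

    def test_long_genes_mostly_lowly_expressed(self):
        gp = GeneParams(n_genes=1000, n_long=40)
        _, features, expr = simulate_genome(gene_params=gp, seed=4,
                                            total_size=6_000_000,
                                            n_chromosomes=8)
        genes = features.of_class("gene").table
        long_expr = genes.loc[genes["length"] > 7000, "expression"]
        short_med = genes.loc[genes["length"] <= 7000,
                              "expression"].median()
        assert (long_expr < short_med).mean() >= 0.6


class TestSimulateContacts:
    def test_truth_round_trips_through_verify(self, mini_scenario):
        report = verify_truth(mini_scenario["matrix"],
                              mini_scenario["stats"],
                              mini_scenario["truth"])
        assert report["plasmid_fraction_ok"]
        assert report["ok"]

    def test_top_scoring_bin_is_an_implanted_site(self, mini_scenario):
        sc = mini_scenario
        prof = compute_contact_profile(sc["matrix"], "plasmid_2micron",
                                       sc["stats"])
        top = int(np.nanargmax(prof.scores))
        sites = sc["truth"].site_host_positions(sc["genome"])
        assert np.abs(sites - top).min() <= 1

    def test_recovery_on_mini_scenario(self, mini_scenario):
        sc = mini_scenario
        prof = compute_contact_profile(sc["matrix"], "plasmid_2micron",
                                       sc["stats"])
        peaks = call_peaks(interpolate_profile(prof))
        sens, prec, _ = recovery_metrics(peaks, sc["truth"], sc["genome"])
        assert sens >= 0.85
        assert prec >= 0.8

    def test_site_off_genome_errors(self):
        genome, _, _ = simulate_genome(
            gene_params=GeneParams(n_genes=100, n_long=0), seed=0, **SMALL)
        truth = SyntheticTruth(sites=[("chr01", 10**9)], folds=[3.0],
                               depth=10_000)
        with pytest.raises(ValueError, match="off the chromosome"):
            simulate_contact_data(genome, truth, seed=0)

    def test_folds_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(sites=[("chr01", 0)], folds=[0.5])

    def test_sites_in_standard_scenario_lie_in_long_genes(self,
                                                          mini_scenario):
        sc = mini_scenario
        genes = sc["features"].of_class("gene").table
        long_genes = genes[genes["length"] > 7000]
        for chrom, pos in sc["truth"].sites:
            inside = ((long_genes["chrom"] == chrom) &
                      (long_genes["start"] <= pos) &
                      (long_genes["end"] > pos))
            assert inside.any()


@pytest.fixture(scope="module")
def small_sim():
    gp = GeneParams(n_genes=150, n_long=4)
    genome, features, expr = simulate_genome(gene_params=gp, seed=9,
                                             **SMALL)
    return genome, features, expr


class TestSimulateTracks:
    def test_rna_track_cpm_normalised(self, small_sim):
        genome, features, expr = small_sim
        tracks, _ = simulate_tracks(genome, features, expr, seed=0)
        assert tracks["rna"].values.sum() == pytest.approx(1e6)

    def test_zero_noise_rna_constant_in_gene_body(self):
        from tetherscan import BinnedGenome

        genome = BinnedGenome(("chrI", "p"), (20_000, 2_000), 2000,
                              frozenset({"p"}))
        features = FeatureSet(pd.DataFrame(
            [("chrI", 4000, 10_000, "g1", "gene", 100.0)],
            columns=["chrom", "start", "end", "name", "feat_class",
                     "expression"],
        ))
        expr = pd.Series([100.0], index=["g1"])
        tracks, _ = simulate_tracks(genome, features, expr, seed=0,
                                    noise=0.0)
        v = tracks["rna"].values
        assert v[0] == 0.0 and v[9] == 0.0
        inner = v[2:5]
        assert np.allclose(inner, inner[0]) and inner[0] > 0

    def test_phase_shift_round_trip(self, small_sim):
        """Generated nucleosome/binding tracks close the loop with the
        phase estimator."""
        from tetherscan import tss_phase

        genome, features, expr = small_sim
        tracks, tss = simulate_tracks(genome, features, expr, seed=1,
                                      phase_deg=90.0, noise=0.02)
        _, phase = tss_phase(tracks["nucleosome"], tracks["binding"],
                             tss, flank=1500)
        assert phase == pytest.approx(90.0, abs=10)

    def test_screen_tracks_enriched_and_depleted_at_sites(self,
                                                          mini_scenario):
        sc = mini_scenario
        tracks, _ = simulate_tracks(sc["genome"], sc["features"],
                                    sc["expression"], truth=sc["truth"],
                                    seed=3)
        sites = sc["truth"].site_host_positions(sc["genome"])
        enr = tracks["screen_enriched"].values
        dep = tracks["screen_depleted"].values
        assert enr[sites].mean() > 1.5 * np.median(enr)
        assert dep[sites].mean() < 0.7 * np.median(dep)


class TestStabilitySimulation:
    def test_extreme_probabilities(self):
        a1 = simulate_stability_assay(5, 100, 1.0, seed=0)
        assert (a1.positives == a1.totals).all()
        a0 = simulate_stability_assay(5, 100, 0.0, seed=0)
        assert (a0.positives == 0).all()

    def test_pooled_estimate_within_binomial_ci(self):
        a = simulate_stability_assay(5, 200, 0.4, seed=123)
        p, _ = retention_proportion(a)
        half = 1.96 * np.sqrt(0.4 * 0.6 / 1000)
        assert abs(p - 0.4) <= half

    def test_truth_frame_serialisation(self):
        truth = SyntheticTruth(sites=[("chr01", 2000), ("chr02", 8000)],
                               folds=[3.0, 4.0])
        df = truth.to_frame()
        assert df.shape[0] == 2
        assert {"chrom", "pos", "fold", "depth"} <= set(df.columns)
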