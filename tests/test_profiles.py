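"""Window stacks, mean profiles, heatmaps, pile-ups, gene stats, GC, phase."""

import numpy as np
import pandas as pd
import pytest

from tetherscan import (BinnedGenome, ContactMatrix, ContactProfile,
                        LibraryStats, PeakSet, SignalTrack,
                        gc_windows, gene_contact_stats, mean_profile,
                        pileup_pairs, sorted_heatmap, tss_phase,
                        window_stack)
from tetherscan.profiles import gc_fraction
from conftest import make_matrix


BS = 2000


def track(genome, values):
    return SignalTrack(genome, np.asarray(values, dtype=float))


def peakset(genome, positions):
    return PeakSet(
        genome=genome,
        table=pd.DataFrame([(c, p, 1.0) for c, p in positions],
                           columns=["chrom", "pos", "score"]),
        height=0.8, distance=2,
    )


@pytest.fixture
def line_genome():
    return BinnedGenome(("chrI",), (100 * BS,), BS)


class TestWindowStack:
    def test_mid_chromosome_row_is_raw_slice(self, line_genome):
        v = np.arange(100, dtype=float)
        st = window_stack(track(line_genome, v), [("chrI", 50 * BS)],
                          flank=10 * BS)
        np.testing.assert_array_equal(st.data[0], v[40:61])
        assert st.data.shape == (1, 21)
        assert st.offsets_bp[st.center] == 0

    def test_bin_zero_locus_left_missing(self, line_genome):
        st = window_stack(track(line_genome, np.ones(100)),
                          [("chrI", 0)], flank=10 * BS)
        assert np.isnan(st.data[0, :10]).all()
        assert (st.data[0, 10:] == 1).all()

    def test_right_end_missing(self, line_genome):
        st = window_stack(track(line_genome, np.ones(100)),
                          [("chrI", 99 * BS)], flank=10 * BS)
        assert np.isnan(st.data[0, 11:]).all()

    def test_constant_track_column_means_one(self, line_genome):
        st = window_stack(track(line_genome, np.ones(100)),
                          [("chrI", 30 * BS), ("chrI", 60 * BS)],
                          flank=5 * BS)
        mean, half, nval = mean_profile(st)
        np.testing.assert_array_equal(mean, 1.0)
        np.testing.assert_array_equal(half, 0.0)

    def test_unknown_chromosome_rejected(self, line_genome):
        with pytest.raises(ValueError):
            window_stack(track(line_genome, np.ones(100)),
                         [("chrZZ", 0)], flank=2 * BS)


class TestMeanProfile:
    def test_two_point_column_hand_ci(self, line_genome):
        v = np.zeros(100)
        v[40] = 0.0
        v[60] = 2.0
        st = window_stack(track(line_genome, v),
                          [("chrI", 40 * BS), ("chrI", 60 * BS)], flank=0)
        mean, half, nval = mean_profile(st)
        sd = np.std([0.0, 2.0], ddof=1)  # sample sd oracle
        assert mean[0] == pytest.approx(1.0)
        assert half[0] == pytest.approx(1.96 * sd / np.sqrt(2))
        assert nval[0] == 2

    def test_entirely_missing_column(self, line_genome):
        st = window_stack(track(line_genome, np.ones(100)),
                          [("chrI", 0)], flank=3 * BS)
        mean, half, nval = mean_profile(st)
        assert np.isnan(mean[0]) and nval[0] == 0


class TestSortedHeatmap:
    def test_descending_central_means(self, line_genome):
        v = np.zeros(100)
        v[20:25] = 1.0
        v[60:65] = 2.0
        st = window_stack(track(line_genome, v),
                          [("chrI", 22 * BS), ("chrI", 62 * BS)],
                          flank=4 * BS)
        order, mat = sorted_heatmap(st, score_flank=2 * BS)
        assert order.tolist() == [1, 0]

    def test_stable_tie_preserves_input_order(self, line_genome):
        st = window_stack(track(line_genome, np.ones(100)),
                          [("chrI", 30 * BS), ("chrI", 50 * BS),
                           ("chrI", 70 * BS)], flank=2 * BS)
        order, _ = sorted_heatmap(st, score_flank=2 * BS)
        assert order.tolist() == [0, 1, 2]

    def test_three_rows_exact_permutation(self, line_genome):
        v = np.zeros(100)
        for c, h in ((20, 1.0), (50, 3.0), (80, 2.0)):
            v[c] = h
        st = window_stack(track(line_genome, v),
                          [("chrI", 20 * BS), ("chrI", 50 * BS),
                           ("chrI", 80 * BS)], flank=BS)
        keys = np.nanmean(st.data[:, np.abs(st.offsets_bp) <= BS], axis=1)
        expect = np.argsort(-keys, kind="stable")  # brute-force oracle
        order, _ = sorted_heatmap(st, score_flank=BS)
        assert order.tolist() == expect.tolist()


class TestPileup:
    def uniform_inter_genome(self):
        return BinnedGenome(("a", "b"), (20 * BS, 20 * BS), BS)

    def test_uniform_inter_matrix_pileup_one(self):
        g = self.uniform_inter_genome()
        i, j, c = [], [], []
        for x in range(20):
            for y in range(20):
                i.append(x)
                j.append(20 + y)
                c.append(3)
        m = ContactMatrix(g, i, j, c)
        pk = peakset(g, [("a", 10 * BS), ("b", 10 * BS)])
        pu = pileup_pairs(m, pk, mode="inter", window=4)
        np.testing.assert_allclose(pu, 1.0, atol=1e-9)

    def test_bright_pixel_two_pairs(self):
        g = BinnedGenome(("a", "b", "c"), (20 * BS, 20 * BS, 20 * BS), BS)
        i, j, c = [], [], []
        for x in range(60):
            for y in range(x + 1, 60):
                if x // 20 != y // 20:  # uniform inter background = 1
                    i.append(x)
                    j.append(y)
                    c.append(1)
        bright = 25
        i.append(10)
        j.append(30)
        c.append(bright - 1)  # cell (a:10, b:10) now holds `bright`
        m = ContactMatrix(g, i, j, c)
        pk = peakset(g, [("a", 10 * BS), ("b", 10 * BS), ("c", 10 * BS)])
        pu = pileup_pairs(m, pk, mode="inter", window=3)
        # expected value per cell from the matrix itself
        total_inter = sum(c)
        n_cells = (60 ** 2 - 3 * 20 ** 2) / 2
        e = total_inter / n_cells
        center = pu[3, 3]
        assert center == pytest.approx((bright / e + 1 / e + 1 / e) / 3,
                                       rel=1e-9)

    def test_intra_all_different_chromosomes_warns(self, caplog):
        g = BinnedGenome(("a", "b"), (20 * BS, 20 * BS), BS)
        m = ContactMatrix(g, [0], [21], [1])
        pk = peakset(g, [("a", 10 * BS), ("b", 10 * BS)])
        with caplog.at_level("WARNING", logger="tetherscan"):
            assert pileup_pairs(m, pk, mode="intra") is None
        assert "no intra" in caplog.text

    def test_exact_decay_matrix_pileup_one(self):
        """A matrix whose counts equal the distance-decay model exactly
        pile-ups to 1 everywhere."""
        g = BinnedGenome(("a", "b"), (30 * BS, 30 * BS), BS)
        i, j, c = [], [], []
        for sl in (range(0, 30), range(30, 60)):
            for x in sl:
                for y in sl:
                    if y >= x:
                        i.append(x)
                        j.append(y)
                        c.append(100 - 3 * (y - x))  # exact decay law
        m = ContactMatrix(g, i, j, c)
        pk = peakset(g, [("a", 10 * BS), ("a", 20 * BS), ("b", 15 * BS)])
        pu = pileup_pairs(m, pk, mode="intra", window=4)
        np.testing.assert_allclose(pu, 1.0, atol=1e-6)

    def test_needs_two_peaks(self):
        g = self.uniform_inter_genome()
        m = ContactMatrix(g, [0], [21], [1])
        with pytest.raises(ValueError):
            pileup_pairs(m, peakset(g, [("a", 0)]), mode="inter")


class TestGeneContactStats:
    def make_profile(self, genome, scores):
        return ContactProfile(genome=genome,
                              scores=np.asarray(scores, dtype=float),
                              plasmid="p", stats=LibraryStats(1, 10))

    @pytest.fixture
    def gene_genome(self):
        return BinnedGenome(("chrI", "p"), (20 * BS, BS), BS,
                            frozenset({"p"}))

    def genes(self, rows):
        return type(self)._features(rows)

    @staticmethod
    def _features(rows):
        from tetherscan import FeatureSet
        return FeatureSet(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "feat_class",
                           "expression"]
        ))

    def test_constant_scores_rho_zero_by_tie_convention(self, gene_genome):
        prof = self.make_profile(gene_genome, np.ones(20))
        genes = self._features([
            ("chrI", 0, 2000, "a", "gene", 1.0),
            ("chrI", 4000, 8000, "b", "gene", 10.0),
            ("chrI", 10_000, 20_000, "c", "gene", 100.0),
        ])
        table, corr = gene_contact_stats(prof, genes)
        assert corr["score_vs_length"][0] == 0.0
        assert corr["score_vs_log_expression"][0] == 0.0

    def test_score_equals_length_gives_rho_one(self, gene_genome):
        scores = np.zeros(20)
        genes = []
        for k, (b0, nb) in enumerate([(0, 1), (4, 2), (8, 3), (13, 4)]):
            scores[b0:b0 + nb] = nb  # score proportional to gene length
            genes.append(("chrI", b0 * BS, (b0 + nb) * BS, f"g{k}",
                          "gene", 1.0))
        prof = self.make_profile(gene_genome, scores)
        _, corr = gene_contact_stats(prof, self._features(genes))
        assert corr["score_vs_length"][0] == pytest.approx(1.0)

    def test_five_gene_rank_oracle(self, gene_genome):
        from scipy.stats import rankdata

        scores = np.zeros(20)
        vals = [0.3, 0.9, 0.1, 0.7, 0.5]
        lens = [1, 2, 3, 2, 1]
        genes = []
        b0 = 0
        for k, (v, nb) in enumerate(zip(vals, lens)):
            scores[b0:b0 + nb] = v
            genes.append(("chrI", b0 * BS, (b0 + nb) * BS, f"g{k}",
                          "gene", np.nan))
            b0 += nb + 1
        prof = self.make_profile(gene_genome, scores)
        _, corr = gene_contact_stats(prof, self._features(genes))
        # direct rank-correlation computation
        rs = rankdata(vals)
        rl = rankdata(lens)
        rho = np.corrcoef(rs, rl)[0, 1]
        assert corr["score_vs_length"][0] == pytest.approx(rho)

    def test_gene_with_no_valid_bin_excluded(self, gene_genome, caplog):
        scores = np.ones(20)
        scores[0] = np.nan
        prof = self.make_profile(gene_genome, scores)
        genes = self._features([
            ("chrI", 0, 2000, "masked", "gene", 1.0),
            ("chrI", 4000, 6000, "ok", "gene", 1.0),
        ])
        with caplog.at_level("INFO", logger="tetherscan"):
            table, _ = gene_contact_stats(prof, genes)
        assert table["name"].tolist() == ["ok"]
        assert "excluded" in caplog.text


class TestGC:
    def test_pure_windows(self):
        assert gc_fraction("GCGC") == 1.0
        assert gc_fraction("ATAT") == 0.0
        assert gc_fraction("NNNN") is None

    def test_direct_count_with_ambiguous_bases(self):
        seq = "ATGCNATGGC"
        # brute-force base counting oracle
        gc = sum(b in "GC" for b in seq)
        acgt = sum(b in "ACGT" for b in seq)
        assert gc_fraction(seq) == pytest.approx(gc / acgt)

    def test_gc_plus_at_is_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        at = sum(b in "AT" for b in seq) / len(seq)
        assert gc_fraction(seq) + at == pytest.approx(1.0)

    def test_hotspot_and_genome_windows(self):
        g = BinnedGenome(("chrI",), (10 * BS,), BS)
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 10 * BS))
        fasta = {"chrI": seq}
        pk = peakset(g, [("chrI", 4 * BS)])
        hot, gen = gc_windows(fasta, pk, window=4000)
        lo = 4 * BS + BS // 2 - 2000
        assert hot[0] == pytest.approx(gc_fraction(seq[lo:lo + 4000]))
        assert len(gen) == 5  # non-overlapping same-size windows


class TestTssPhase:
    def fine_track(self, genome, fn, noise=0.0, seed=0):
        bs = genome.bin_size
        rng = np.random.default_rng(seed)
        xs = np.arange(genome.n_genome) * bs + bs / 2
        v = fn(xs) + (rng.normal(0, noise, xs.size) if noise else 0.0)
        return SignalTrack(genome, v)

    @pytest.fixture
    def fine_genome(self):
        return BinnedGenome(("chrI",), (60_000,), 10)

    def test_identical_sinusoids_zero_phase(self, fine_genome):
        period = 165.0
        fn = lambda x: np.cos(2 * np.pi * x / period)
        a = self.fine_track(fine_genome, fn)
        lag, phase = tss_phase(a, a, [("chrI", 20_000), ("chrI", 40_000)],
                               flank=1500)
        assert abs(lag) < 10
        assert phase == pytest.approx(0.0, abs=2)

    def test_quarter_period_shift_is_90_degrees(self, fine_genome):
        period = 165.0
        a = self.fine_track(fine_genome,
                            lambda x: np.cos(2 * np.pi * x / period))
        b = self.fine_track(
            fine_genome,
            lambda x: np.cos(2 * np.pi * (x - period / 4) / period))
        _, phase = tss_phase(a, b, [("chrI", 20_000), ("chrI", 40_000)],
                             flank=1500)
        assert phase == pytest.approx(90.0, abs=5)

    def test_noisy_shift_recovered(self, fine_genome):
        period = 165.0
        a = self.fine_track(fine_genome,
                            lambda x: np.cos(2 * np.pi * x / period),
                            noise=0.3, seed=11)
        b = self.fine_track(
            fine_genome,
            lambda x: np.cos(2 * np.pi * (x - period / 4) / period),
            noise=0.3, seed=12)
        # loci phase-locked to the global sinusoid (spacing = 10 periods)
        loci = [("chrI", p) for p in range(5_000, 55_000, 1_650)]
        _, phase = tss_phase(a, b, loci, flank=1500)
        assert phase == pytest.approx(90.0, abs=10)

    def test_flat_track_errors(self, fine_genome):
        a = self.fine_track(fine_genome, lambda x: np.zeros_like(x))
        b = self.fine_track(fine_genome, lambda x: np.cos(x / 20))
        with pytest.raises(ValueError):
            tss_phase(a, b, [("chrI", 20_000)], flank=1000)
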