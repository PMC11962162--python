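"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a small fungal-like host: a ~12 Mb genome split over
16 chromosomes binned at 2 kb, carrying a ~6 kb episome whose trans contacts
concentrate at implanted tether sites placed inside long, lowly expressed
genes.  Every dataset ships with its :class:`SyntheticTruth` so recovery can
be scored exactly.

Model
-----
* per-bin contact coverage is a gamma-perturbed uniform (shape ``40`` by
  default, i.e. ~16% coverage CV between 2 kb bins);
* plasmid-host contacts are Poisson with mean proportional to coverage times
  ``1 + (fold - 1) * k(i)``, ``k`` a triangular kernel (half-width 2 bins)
  around each tether site;
* a fixed share of the plasmid's read pairs is intra-plasmid (default
  ``0.47``), as in real proximity-ligation libraries of a small high-copy
  episome where ligation within and between plasmid copies dominates.  This
  share sets the background contact score: with reads-based library totals
  the background sits near ``(1 - c) / (1 + c)`` (~0.36 at the default), so
  a 3-fold tether site scores ~1.1 and the conventional height threshold of
  0.8 separates the two regimes;
* remaining pairs are host-host with independently drawn coverage-weighted
  ends (no cis distance decay - see the methods note for what this leaves
  untested);
* stability assays are per-replicate binomial colony counts.

All randomness flows from a single seed: entry points draw sub-seeds from
``numpy.random.default_rng(seed)`` in a fixed order, so any stage can be
reproduced independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import BinnedGenome, ContactMatrix, FeatureSet, LibraryStats, \
    PeakSet, SignalTrack

logger = logging.getLogger("tetherscan")

DEFAULT_PLASMID_NAME = "plasmid_2micron"
DEFAULT_PLASMID_SIZE = 6_300


@dataclass
class GeneParams:
    """Parameters of the synthetic gene annotation.

    Lengths of ordinary genes are log-normal with median
    ``length_median_bp`` (1 kb, the genome-wide median of the emulated
    host) and are kept below ``long_threshold_bp``; exactly ``n_long``
    additional long genes are drawn uniformly from ``long_length_range``.
    Expression is log-normal CPM; each long gene is assigned to the lowly
    expressed regime with probability ``p_long_low``.
    """

    n_genes: int = 3_000
    length_median_bp: float = 1_000.0
    length_sigma: float = 0.65
    n_long: int = 19
    long_length_range: tuple = (8_000, 15_000)
    long_threshold_bp: int = 7_000
    expression_median_cpm: float = 50.0
    expression_sigma: float = 1.2
    low_expression_median_cpm: float = 3.0
    low_expression_sigma: float = 0.8
    p_long_low: float = 0.8


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated contact dataset."""

    sites: list                       # [(chrom, bin-start bp), ...]
    folds: np.ndarray                 # per-site fold enrichment, >= 1
    kernel_halfwidth: int = 2
    plasmid_read_fraction: float = 0.02
    intra_plasmid_fraction: float = 0.47
    coverage_gamma_shape: float = 40.0
    depth: int = 5_000_000
    seed: int = 0

    def __post_init__(self):
        self.folds = np.asarray(self.folds, dtype=float)
        if len(self.sites) != self.folds.size:
            raise ValueError("one fold per site required")
        if self.folds.size and self.folds.min() < 1:
            raise ValueError("fold enrichments must be >= 1")
        if not 0 <= self.intra_plasmid_fraction < 1:
            raise ValueError("intra_plasmid_fraction must be in [0, 1)")

    def site_host_positions(self, genome: BinnedGenome) -> np.ndarray:
        return np.array(
            [genome.host_index(c, p // genome.bin_size)
             for c, p in self.sites],
            dtype=np.int64,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sites, columns=["chrom", "pos"])
        df["fold"] = self.folds
        for k, v in asdict(self).items():
            if k not in ("sites", "folds"):
                df[k] = v
        return df


def _split_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic sub-seeds for the documented splitting scheme."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chromosomes: int = 16,
    total_size: int = 12_000_000,
    bin_size: int = 2_000,
    gene_params: GeneParams | None = None,
    seed: int = 0,
    plasmid_name: str = DEFAULT_PLASMID_NAME,
    plasmid_size: int = DEFAULT_PLASMID_SIZE,
):
    """Generate a host genome, gene/centromere annotation and expression.

    Returns ``(BinnedGenome, FeatureSet, expression)`` where the genome
    includes one episomal contig, the FeatureSet carries genes and one
    centromere per chromosome, and expression is a pandas Series of CPM per
    gene name.
    """
    if total_size < n_chromosomes * bin_size * 10:
        raise ValueError("total_size too small for the requested binning")
    gp = gene_params or GeneParams()
    seeds = _split_seeds(seed, 3)
    rng = np.random.default_rng(seeds[0])

    # chromosome lengths: gamma weights, floor at a quarter of the mean
    min_len = total_size // (n_chromosomes * 4)
    for _ in range(200):
        w = rng.gamma(8.0, 1.0, n_chromosomes)
        lengths = np.floor(total_size * w / w.sum()).astype(np.int64)
        lengths[-1] += total_size - lengths.sum()
        if lengths.min() >= min_len:
            break
    else:
        raise RuntimeError("could not draw chromosome lengths")

    # gene lengths: ordinary genes capped below the long threshold,
    # exactly n_long long genes
    rng_g = np.random.default_rng(seeds[1])
    n_reg = gp.n_genes - gp.n_long
    if n_reg < 0:
        raise ValueError("n_long exceeds n_genes")
    reg_len = np.empty(0, dtype=np.int64)
    while reg_len.size < n_reg:
        draw = rng_g.lognormal(np.log(gp.length_median_bp), gp.length_sigma,
                               2 * (n_reg - reg_len.size))
        draw = draw[(draw >= 100) & (draw <= gp.long_threshold_bp)]
        reg_len = np.concatenate([reg_len, np.rint(draw).astype(np.int64)])
    reg_len = reg_len[:n_reg]
    long_len = rng_g.integers(gp.long_length_range[0],
                              gp.long_length_range[1] + 1, gp.n_long)
    gene_len = np.concatenate([reg_len, long_len])
    is_long = np.concatenate([np.zeros(n_reg, bool), np.ones(gp.n_long, bool)])

    # expression: long genes lowly expressed with probability p_long_low
    expr = rng_g.lognormal(np.log(gp.expression_median_cpm),
                           gp.expression_sigma, gp.n_genes)
    low = is_long & (rng_g.random(gp.n_genes) < gp.p_long_low)
    expr[low] = rng_g.lognormal(np.log(gp.low_expression_median_cpm),
                                gp.low_expression_sigma, low.sum())

    if gene_len.sum() > 0.85 * total_size:
        raise ValueError("infeasible packing: genes exceed genome capacity")

    # placement: greedy assignment to the chromosome with most free space,
    # then random gaps within each chromosome
    rng_p = np.random.default_rng(seeds[2])
    order = rng_p.permutation(gp.n_genes)
    free = lengths.astype(float).copy()
    assigned = [[] for _ in range(n_chromosomes)]
    for g_idx in order:
        c = int(np.argmax(free))
        if free[c] < gene_len[g_idx] + bin_size:
            raise ValueError("infeasible packing: genes exceed genome")
        assigned[c].append(g_idx)
        free[c] -= gene_len[g_idx]
    rows = []
    for c in range(n_chromosomes):
        ids = assigned[c]
        if not ids:
            continue
        glens = gene_len[ids]
        slack = lengths[c] - glens.sum()
        gaps = rng_p.dirichlet(np.ones(len(ids) + 1)) * slack
        pos = 0
        for k, g_idx in enumerate(ids):
            start = int(pos + gaps[k])
            rows.append((f"chr{c + 1:02d}", start, start + int(gene_len[g_idx]),
                         f"gene_{g_idx:05d}", "gene",
                         float(expr[g_idx])))
            pos = start + gene_len[g_idx]
    # one centromere per chromosome, mid-chromosome
    for c in range(n_chromosomes):
        cen = int(lengths[c] * rng_p.uniform(0.35, 0.65))
        rows.append((f"chr{c + 1:02d}", cen, cen + 120,
                     f"CEN{c + 1}", "centromere", np.nan))

    names = tuple(f"chr{c + 1:02d}" for c in range(n_chromosomes)) + \
        (plasmid_name,)
    genome = BinnedGenome(
        names=names, lengths=tuple(lengths) + (plasmid_size,),
        bin_size=bin_size, plasmids=frozenset({plasmid_name}),
    )
    features = FeatureSet(pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "feat_class", "expression"],
    ))
    genes = features.of_class("gene")
    expression = pd.Series(
        genes.table["expression"].to_numpy(), index=genes.table["name"]
    )
    return genome, features, expression


# ---------------------------------------------------------------------------
# contact data
# ---------------------------------------------------------------------------

def _site_kernel(genome: BinnedGenome, truth: SyntheticTruth) -> np.ndarray:
    """Per-host-bin enrichment factor 1 + (fold-1) * triangular kernel."""
    e = np.ones(genome.n_genome)
    hw = truth.kernel_halfwidth
    slices = genome.host_vector_slices()
    for (chrom, pos), fold in zip(truth.sites, truth.folds):
        if chrom not in slices:
            raise ValueError(f"tether site on non-host contig {chrom!r}")
        sl = slices[chrom]
        b = pos // genome.bin_size
        if not 0 <= b < sl.stop - sl.start:
            raise ValueError(f"tether site {chrom}:{pos} off the chromosome")
        for off in range(-hw, hw + 1):
            t = b + off
            if 0 <= t < sl.stop - sl.start:
                k = max(0.0, 1.0 - abs(off) / hw) if hw > 0 else \
                    (1.0 if off == 0 else 0.0)
                e[sl.start + t] += (fold - 1.0) * k
    return e


def simulate_contact_data(
    genome: BinnedGenome,
    truth: SyntheticTruth,
    depth: int | None = None,
    seed: int | None = None,
):
    """Draw a contact matrix and library totals under the generator model.

    Returns ``(ContactMatrix, LibraryStats)``; the stats are the realised
    read totals of the drawn matrix (reads basis: an intra-plasmid pair
    contributes two plasmid reads, a trans pair one).
    """
    depth = int(depth if depth is not None else truth.depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    g = genome
    n = g.n_genome
    plasmid = next(iter(g.plasmids))
    m = g.n_bins(plasmid)

    w = rng.gamma(truth.coverage_gamma_shape,
                  1.0 / truth.coverage_gamma_shape, n)
    e = _site_kernel(g, truth)

    ci = truth.intra_plasmid_fraction
    rho = truth.plasmid_read_fraction
    plasmid_pairs = 2.0 * rho * depth / (1.0 + ci)
    trans_expected = (1.0 - ci) * plasmid_pairs
    intra_expected = ci * plasmid_pairs

    weights = w * e
    cp = rng.poisson(trans_expected * weights / weights.sum())
    n_intra = int(rng.poisson(intra_expected))
    n_hh = depth - int(cp.sum()) - n_intra
    if n_hh <= 0:
        raise ValueError("depth too small for the requested plasmid fraction")

    host_flat = g.host_to_flat()
    p = w / w.sum()
    e1 = rng.choice(n, size=n_hh, p=p)
    e2 = rng.choice(n, size=n_hh, p=p)

    # assemble triplets: host-host singletons, plasmid-host aggregated,
    # intra-plasmid spread over plasmid bin pairs
    p0 = g.flat_index(plasmid, 0)
    nz = np.flatnonzero(cp)
    ph_i = host_flat[nz]
    ph_j = p0 + (nz % m)
    pp_cells = [(a, b) for a in range(m) for b in range(a, m)]
    pp_counts = rng.multinomial(n_intra, np.full(len(pp_cells),
                                                 1.0 / len(pp_cells)))
    i_all = np.concatenate([
        host_flat[e1], ph_i, p0 + np.array([a for a, _ in pp_cells]),
    ])
    j_all = np.concatenate([
        host_flat[e2], ph_j, p0 + np.array([b for _, b in pp_cells]),
    ])
    c_all = np.concatenate([
        np.ones(n_hh, dtype=np.int64), cp[nz], pp_counts,
    ])
    matrix = ContactMatrix(g, i_all, j_all, c_all)
    stats = matrix.library_stats(plasmid)
    logger.info(
        "simulated %d pairs: %d plasmid-host, %d intra-plasmid "
        "(read fraction %.4f)",
        matrix.total(), int(cp.sum()), n_intra, stats.plasmid_fraction,
    )
    return matrix, stats


def verify_truth(matrix: ContactMatrix, stats: LibraryStats,
                 truth: SyntheticTruth,
                 fraction_rtol: float = 0.1,
                 enrichment_rtol: float = 0.5) -> dict:
    """Re-derive realised plasmid read fraction and per-site enrichment.

    The per-site enrichment is the site bin's contact-proportion ratio over
    the median of non-site bins; with Poisson counting noise a relative
    tolerance of ~0.5 at typical depths is appropriate.
    """
    g = matrix.genome
    plasmid = next(iter(g.plasmids))
    cp = matrix.plasmid_contacts(plasmid)
    totals = matrix.marginals()[g.host_to_flat()]
    ratio = np.divide(cp, totals, out=np.full(cp.shape, np.nan),
                      where=totals > 0)
    site_pos = truth.site_host_positions(g)
    bg = np.ones(g.n_genome, dtype=bool)
    hw = truth.kernel_halfwidth
    for s in site_pos:
        bg[max(0, s - hw): s + hw + 1] = False
    baseline = np.nanmedian(ratio[bg])
    realized = ratio[site_pos] / baseline
    frac_ok = abs(stats.plasmid_fraction - truth.plasmid_read_fraction) <= \
        fraction_rtol * truth.plasmid_read_fraction
    enr_ok = np.abs(realized - truth.folds) <= enrichment_rtol * truth.folds
    return {
        "plasmid_fraction": stats.plasmid_fraction,
        "plasmid_fraction_ok": bool(frac_ok),
        "site_enrichment": realized,
        "site_enrichment_ok": enr_ok,
        "ok": bool(frac_ok and enr_ok.all()),
    }


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    genome: BinnedGenome,
    features: FeatureSet,
    expression: pd.Series,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    fine_bin: int = 10,
    nucleosome_period: int = 165,
    phase_deg: float = 90.0,
    screen_enrichment: float = 2.0,
    noise: float = 0.05,
):
    """Generate companion signal tracks.

    Returns ``(tracks, tss)`` where ``tracks`` maps name -> SignalTrack:

    * ``rna``: CPM expression spread over gene bodies (host bin size);
    * ``nucleosome``: damped ``nucleosome_period`` bp cosine downstream of
      each TSS, on a ``fine_bin`` bp binning of the host chromosomes;
    * ``binding``: the nucleosome pattern shifted by ``phase_deg`` degrees;
    * ``screen_enriched`` / ``screen_depleted``: flat tracks multiplied /
      divided by ``screen_enrichment`` at tether-site bins (host bin size).

    ``tss`` is a list of ``(chrom, position)`` gene starts.
    """
    rng = np.random.default_rng(seed)
    genes = features.of_class("gene").table
    tss = list(zip(genes["chrom"], genes["start"].astype(int)))

    # RNA-seq CPM at the analysis binning
    rna = np.zeros(genome.n_genome)
    slices = genome.host_vector_slices()
    bs = genome.bin_size
    for _, rec in genes.iterrows():
        sl = slices[rec["chrom"]]
        b0 = rec["start"] // bs
        b1 = min(-(-rec["end"] // bs), sl.stop - sl.start)
        expr = expression.get(rec["name"], 0.0)
        for b in range(b0, b1):
            lo = max(rec["start"], b * bs)
            hi = min(rec["end"], (b + 1) * bs)
            rna[sl.start + b] += expr * (hi - lo) / bs
    if noise > 0:
        rna *= np.exp(rng.normal(0.0, noise, rna.size))
    rna = rna * 1e6 / rna.sum()

    # fine-binned periodic tracks
    host_names = tuple(genome.host_chromosomes)
    host_lengths = tuple(genome.chrom_length(c) for c in host_names)
    fine = BinnedGenome(host_names, host_lengths, fine_bin)
    nuc = np.zeros(fine.n_genome)
    shift = phase_deg / 360.0 * nucleosome_period
    span = 2_000
    fslices = fine.host_vector_slices()
    for chrom, t in tss:
        sl = fslices[chrom]
        nb = sl.stop - sl.start
        b0 = t // fine_bin
        b1 = min(nb, (t + span) // fine_bin)
        if b1 <= b0:
            continue
        x = (np.arange(b0, b1) * fine_bin + fine_bin / 2.0) - t
        damp = np.exp(-x / 1_500.0)
        nuc[sl.start + b0: sl.start + b1] += \
            np.cos(2 * np.pi * x / nucleosome_period) * damp
    bind = np.zeros(fine.n_genome)
    for chrom, t in tss:
        sl = fslices[chrom]
        nb = sl.stop - sl.start
        b0 = t // fine_bin
        b1 = min(nb, (t + span) // fine_bin)
        if b1 <= b0:
            continue
        x = (np.arange(b0, b1) * fine_bin + fine_bin / 2.0) - t
        damp = np.exp(-x / 1_500.0)
        bind[sl.start + b0: sl.start + b1] += \
            np.cos(2 * np.pi * (x - shift) / nucleosome_period) * damp
    if noise > 0:
        nuc = nuc + rng.normal(0.0, noise, nuc.size)
        bind = bind + rng.normal(0.0, noise, bind.size)

    # hotspot screen tracks
    base = np.ones(genome.n_genome)
    if truth is not None and len(truth.sites):
        kern = _site_kernel(genome, SyntheticTruth(
            sites=truth.sites,
            folds=np.full(len(truth.sites), screen_enrichment),
            kernel_halfwidth=truth.kernel_halfwidth,
        ))
    else:
        kern = base
    enr = base * kern
    dep = base / kern
    if noise > 0:
        enr = enr * np.exp(rng.normal(0.0, noise, enr.size))
        dep = dep * np.exp(rng.normal(0.0, noise, dep.size))

    tracks = {
        "rna": SignalTrack(genome, rna, units="CPM"),
        "nucleosome": SignalTrack(fine, nuc, units="occupancy"),
        "binding": SignalTrack(fine, bind, units="occupancy"),
        "screen_enriched": SignalTrack(genome, enr, units="ratio"),
        "screen_depleted": SignalTrack(genome, dep, units="ratio"),
    }
    return tracks, tss


# ---------------------------------------------------------------------------
# stability assays
# ---------------------------------------------------------------------------

def simulate_stability_assay(
    n_replicates: int,
    colonies_per_replicate: int,
    retention_prob: float,
    seed: int = 0,
    condition: str = "synthetic",
):
    """Binomial colony counts for a plating assay."""
    from .stability import StabilityAssay

    if not 0 <= retention_prob <= 1:
        raise ValueError("retention_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    totals = np.full(n_replicates, colonies_per_replicate, dtype=np.int64)
    positives = rng.binomial(totals, retention_prob)
    return StabilityAssay(condition=condition, totals=totals,
                          positives=positives)


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

def standard_scenario(
    seed: int = 0,
    n_sites: int = 30,
    fold: float = 3.0,
    depth: int = 5_000_000,
    plasmid_read_fraction: float = 0.02,
    n_chromosomes: int = 16,
    total_size: int = 12_000_000,
    bin_size: int = 2_000,
    n_genes: int = 3_000,
):
    """The reference simulation: tether sites inside long, low-expression
    genes of a 12 Mb / 16-chromosome host.

    One long gene per tether site is generated (lowest-expression long genes
    are used first) and each site sits at the gene's central bin.  Returns a
    dict with genome, features, expression, truth, matrix and stats.
    """
    seeds = _split_seeds(seed, 2)
    gp = GeneParams(n_genes=n_genes, n_long=n_sites)
    genome, features, expression = simulate_genome(
        n_chromosomes=n_chromosomes, total_size=total_size,
        bin_size=bin_size, gene_params=gp, seed=int(seeds[0]),
    )
    genes = features.of_class("gene").table
    long_genes = genes[genes["length"] > gp.long_threshold_bp]
    long_genes = long_genes.sort_values("expression").head(n_sites)
    sites = [
        (rec["chrom"], ((rec["start"] + rec["end"]) // 2 // bin_size)
         * bin_size)
        for _, rec in long_genes.iterrows()
    ]
    truth = SyntheticTruth(
        sites=sites, folds=np.full(n_sites, fold),
        plasmid_read_fraction=plasmid_read_fraction,
        depth=depth, seed=int(seeds[1]),
    )
    matrix, stats = simulate_contact_data(genome, truth)
    return {
        "genome": genome, "features": features, "expression": expression,
        "truth": truth, "matrix": matrix, "stats": stats,
    }


def calibration_scenario(seed: int = 0, depth: int = 5_000_000, **kw):
    """Fold-1 configuration with plasmid contacts proportional to coverage.

    All fold enrichments equal 1 and no intra-plasmid pairs are drawn, i.e.
    the plasmid's reads are spread over host bins proportionally to their
    coverage - the configuration under which the score's expectation
    calibration (mean S_i -> 1) is defined.
    """
    seeds = _split_seeds(seed, 2)
    genome, features, expression = simulate_genome(seed=int(seeds[0]), **kw)
    truth = SyntheticTruth(
        sites=[], folds=np.empty(0), intra_plasmid_fraction=0.0,
        depth=depth, seed=int(seeds[1]),
    )
    matrix, stats = simulate_contact_data(genome, truth)
    return {
        "genome": genome, "features": features, "expression": expression,
        "truth": truth, "matrix": matrix, "stats": stats,
    }


def recovery_metrics(peaks: PeakSet, truth: SyntheticTruth,
                     genome: BinnedGenome, tol_bins: int = 2):
    """Sensitivity and precision of called peaks against implanted sites.

    A site is recovered when a called peak lies within ``tol_bins`` bins of
    it; a peak is a true positive when it lies within ``tol_bins`` bins of
    any site.  Returns ``(sensitivity, precision, n_peaks)``.
    """
    site_pos = truth.site_host_positions(genome)
    peak_pos = peaks.host_positions()
    if site_pos.size == 0:
        return np.nan, np.nan, len(peaks)
    if peak_pos.size == 0:
        return 0.0, np.nan, 0
    chrom_of = genome.host_chrom_of()
    d = np.abs(site_pos[:, None] - peak_pos[None, :])
    d[chrom_of[site_pos][:, None] != chrom_of[peak_pos][None, :]] = \
        np.iinfo(np.int64).max
    sens = float((d.min(axis=1) <= tol_bins).mean())
    prec = float((d.min(axis=0) <= tol_bins).mean())
    return sens, prec, len(peaks)
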