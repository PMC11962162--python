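"""Locus-aggregated views of binned signals and contact matrices.

Implements the aggregate views used to characterise tether hotspots:
averaged +/-40 kb profiles with confidence intervals, score-sorted window
heatmaps, observed/expected pile-ups over hotspot pairs, per-gene contact
statistics, GC-content windows, and TSS-anchored phase comparison between
two periodic tracks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BinnedGenome, ContactMatrix, ContactProfile, FeatureSet, \
    PeakSet, SignalTrack

logger = logging.getLogger("tetherscan")

DEFAULT_PROFILE_FLANK = 40_000
DEFAULT_SORT_FLANK = 20_000
DEFAULT_PILEUP_WINDOW = 10
DEFAULT_GC_WINDOW = 10_000


@dataclass
class LocusWindowStack:
    """Rows = loci, columns = positions centred on each locus.

    ``data[r, c]`` is the signal at offset ``offsets_bp[c]`` from locus ``r``;
    NaN marks positions beyond a chromosome end or masked bins (windows are
    never wrapped or truncated).
    """

    data: np.ndarray
    labels: list
    offsets_bp: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] % 2 == 0:
            raise ValueError("stack must be 2-D with an odd column count")

    @property
    def n_loci(self) -> int:
        return self.data.shape[0]

    @property
    def center(self) -> int:
        return self.data.shape[1] // 2


def _loci_list(loci, genome: BinnedGenome):
    """Normalise loci input to ``[(label, chrom, pos_bp), ...]``."""
    if isinstance(loci, PeakSet):
        return [
            (f"{c}:{p}", c, int(p))
            for c, p in zip(loci.table["chrom"], loci.table["pos"])
        ]
    out = []
    for k, item in enumerate(loci):
        if len(item) == 3:
            label, chrom, pos = item
        else:
            chrom, pos = item
            label = f"{chrom}:{pos}"
        if chrom not in genome.names:
            raise ValueError(f"locus on unknown chromosome {chrom!r}")
        out.append((label, chrom, int(pos)))
    return out


def window_stack(track_or_profile, loci, flank: int = DEFAULT_PROFILE_FLANK
                 ) -> LocusWindowStack:
    """Extract per-locus windows of +/- ``flank`` bp around each locus bin.

    Accepts a :class:`SignalTrack` or :class:`ContactProfile`; locus order is
    preserved.  Windows crossing chromosome ends carry NaN, never truncated
    or wrapped values.
    """
    genome = track_or_profile.genome
    values = (
        track_or_profile.scores
        if isinstance(track_or_profile, ContactProfile)
        else track_or_profile.values
    )
    bs = genome.bin_size
    w = flank // bs
    ncol = 2 * w + 1
    slices = genome.host_vector_slices()
    entries = _loci_list(loci, genome)
    data = np.full((len(entries), ncol), np.nan)
    labels = []
    for r, (label, chrom, pos) in enumerate(entries):
        if chrom not in slices:
            raise ValueError(f"locus on non-host chromosome {chrom!r}")
        sl = slices[chrom]
        nb = sl.stop - sl.start
        b = pos // bs
        if not 0 <= b < nb:
            raise ValueError(f"locus {chrom}:{pos} beyond chromosome end")
        lo = max(0, b - w)
        hi = min(nb, b + w + 1)
        data[r, (lo - (b - w)):(hi - (b - w))] = values[sl.start + lo:
                                                        sl.start + hi]
        labels.append(label)
    offsets = (np.arange(ncol) - w) * bs
    return LocusWindowStack(data=data, labels=labels, offsets_bp=offsets)


def mean_profile(stack: LocusWindowStack, ci_z: float = 1.96):
    """Column-wise mean curve with normal-approximation CI half-widths.

    Returns ``(mean, ci_half_width, n_valid)`` per column; missing values are
    ignored, columns with no valid value are NaN.  The CI half-width is
    ``ci_z * sd / sqrt(n_valid)`` (sample sd, ddof=1; 0 when n_valid == 1).
    """
    if stack.n_loci < 1:
        raise ValueError("stack has no rows")
    d = stack.data
    n_valid = (~np.isnan(d)).sum(axis=0)
    mean = np.full(d.shape[1], np.nan)
    half = np.full(d.shape[1], np.nan)
    cols = n_valid > 0
    with np.errstate(invalid="ignore"):
        mean[cols] = np.nanmean(d[:, cols], axis=0)
    for c in np.flatnonzero(cols):
        col = d[:, c]
        col = col[~np.isnan(col)]
        sd = col.std(ddof=1) if col.size > 1 else 0.0
        half[c] = ci_z * sd / np.sqrt(col.size)
    return mean, half, n_valid


def sorted_heatmap(stack: LocusWindowStack,
                   score_flank: int = DEFAULT_SORT_FLANK):
    """Row order and matrix sorted by descending central window mean.

    The sort key is the missing-ignoring mean over the central
    +/- ``score_flank`` columns; the sort is stable (input order breaks
    ties).  Returns ``(order, sorted_matrix)``.
    """
    offs = stack.offsets_bp
    if score_flank > offs[-1]:
        raise ValueError("score_flank exceeds the stack flank")
    central = np.abs(offs) <= score_flank
    with np.errstate(invalid="ignore"):
        keys = np.nanmean(stack.data[:, central], axis=1)
    keys = np.where(np.isnan(keys), -np.inf, keys)
    order = np.argsort(-keys, kind="stable")
    return order, stack.data[order]


# ---------------------------------------------------------------------------
# pair pile-ups
# ---------------------------------------------------------------------------

def _distance_decay(matrix: ContactMatrix, max_linear: int = 100,
                    geom_ratio: float = 1.12):
    """Empirical mean count per intra-chromosomal bin-pair distance.

    Linear distance bins up to ``max_linear``, geometric beyond (stable in
    sparse tails).  Returns a function d -> expected count per cell.
    """
    g = matrix.genome
    i, j, c = matrix.triplets()
    flat2host = np.full(g.total_bins, -1, dtype=np.int64)
    flat2host[g.host_to_flat()] = np.arange(g.n_genome)
    hi, hj = flat2host[i], flat2host[j]
    host = (hi >= 0) & (hj >= 0)
    chrom_of = g.host_chrom_of()
    same = host.copy()
    same[host] = chrom_of[hi[host]] == chrom_of[hj[host]]
    d = np.abs(hj[same] - hi[same])
    # pair-count denominator per distance over all host chromosomes
    nbins = np.array([g.n_bins(c_) for c_ in g.host_chromosomes])
    max_d = int(nbins.max()) - 1
    denom = np.zeros(max_d + 1)
    for nb in nbins:
        dd = np.arange(nb)
        denom[:nb] += nb - dd
    sums = np.bincount(d, weights=c[same], minlength=max_d + 1)
    # group distances into linear + geometric bins
    edges = list(range(0, min(max_linear, max_d) + 1))
    x = float(max_linear)
    while x < max_d:
        x *= geom_ratio
        edges.append(min(int(np.ceil(x)), max_d))
    edges = np.unique(edges)
    exp_at = np.zeros(max_d + 1)
    for lo, hi_ in zip(edges, list(edges[1:]) + [max_d + 1]):
        hi_ = max(hi_, lo + 1)
        dsum = sums[lo:hi_].sum()
        dden = denom[lo:hi_].sum()
        exp_at[lo:hi_] = dsum / dden if dden > 0 else np.nan
    return lambda dist: exp_at[np.clip(dist, 0, max_d)]


def pileup_pairs(matrix: ContactMatrix, peaks: PeakSet, mode: str = "inter",
                 window: int = DEFAULT_PILEUP_WINDOW):
    """Averaged observed/expected contact submatrix over all peak pairs.

    For every unordered peak pair in the requested configuration (``intra``:
    same chromosome, ``inter``: different chromosomes) the
    ``(2*window+1)^2`` submatrix centred on the pair is divided by its
    expectation - the genome-wide mean inter-chromosomal count per cell for
    inter pairs, the empirical distance-decay mean for intra pairs - and the
    ratios are averaged element-wise, ignoring out-of-range cells.

    Returns the averaged matrix, or None (with a warning) when the requested
    configuration has no pair.
    """
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    g = matrix.genome
    host_pos = peaks.host_positions()
    chrom_of = g.host_chrom_of()
    pairs = [
        (a, b)
        for a, b in itertools.combinations(range(len(host_pos)), 2)
        if (chrom_of[host_pos[a]] == chrom_of[host_pos[b]]) == (mode == "intra")
    ]
    if not pairs:
        logger.warning("pileup: no %s-chromosomal peak pair", mode)
        return None

    sym = matrix.symmetric()
    host_flat = g.host_to_flat()
    # chromosome bounds of every host position, in host-vector coordinates
    slices = list(g.host_vector_slices().values())
    starts = np.array([s.start for s in slices])
    stops = np.array([s.stop for s in slices])

    if mode == "inter":
        i, j, c = matrix.triplets()
        flat2host = np.full(g.total_bins, -1, dtype=np.int64)
        flat2host[host_flat] = np.arange(g.n_genome)
        hi, hj = flat2host[i], flat2host[j]
        host = (hi >= 0) & (hj >= 0)
        inter = host.copy()
        inter[host] = chrom_of[hi[host]] != chrom_of[hj[host]]
        total_inter = c[inter].sum()
        nb = stops - starts
        n_cells = (nb.sum() ** 2 - (nb ** 2).sum()) / 2  # unordered pairs
        expected = lambda da, db: np.full(da.shape, total_inter / n_cells)
    else:
        decay = _distance_decay(matrix)

    k = 2 * window + 1
    acc = np.zeros((k, k))
    nobs = np.zeros((k, k))
    offs = np.arange(-window, window + 1)
    for a, b in pairs:
        pa, pb = int(host_pos[a]), int(host_pos[b])
        ca, cb = chrom_of[pa], chrom_of[pb]
        rows = pa + offs
        cols = pb + offs
        rok = (rows >= starts[ca]) & (rows < stops[ca])
        cok = (cols >= starts[cb]) & (cols < stops[cb])
        sub = np.full((k, k), np.nan)
        rsel = np.flatnonzero(rok)
        csel = np.flatnonzero(cok)
        block = sym[np.ix_(host_flat[rows[rsel]], host_flat[cols[csel]])]
        sub[np.ix_(rsel, csel)] = np.asarray(block.todense())
        if mode == "inter":
            exp = expected(*np.meshgrid(rows, cols, indexing="ij"))
        else:
            dist = np.abs(rows[:, None] - cols[None, :])
            exp = decay(dist)
        ratio = sub / exp
        ok = ~np.isnan(ratio)
        acc[ok] += ratio[ok]
        nobs[ok] += 1
    out = np.full((k, k), np.nan)
    seen = nobs > 0
    out[seen] = acc[seen] / nobs[seen]
    return out


# ---------------------------------------------------------------------------
# per-gene contact statistics
# ---------------------------------------------------------------------------

def gene_contact_stats(profile: ContactProfile, genes: FeatureSet,
                       expression=None):
    """Per-gene mean contact score plus rank correlations.

    ``expression`` maps gene name -> CPM; when omitted the FeatureSet's own
    expression attribute is used.  Returns ``(table, correlations)`` where
    correlations holds Spearman rho/p for score vs log1p(expression) and
    score vs gene length (average-rank ties).  Genes with no valid bin are
    excluded and counted in a log line.
    """
    g = profile.genome
    bs = g.bin_size
    slices = g.host_vector_slices()
    rows = []
    skipped = 0
    for _, rec in genes.table.iterrows():
        if rec["chrom"] not in slices:
            continue
        sl = slices[rec["chrom"]]
        b0 = rec["start"] // bs
        b1 = min(-(-rec["end"] // bs), sl.stop - sl.start)
        vals = profile.scores[sl.start + b0: sl.start + b1]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            skipped += 1
            continue
        expr = (
            expression.get(rec["name"], np.nan)
            if expression is not None else rec["expression"]
        )
        rows.append((rec["name"], rec["chrom"], rec["start"], rec["end"],
                     rec["length"], expr, float(vals.mean())))
    if skipped:
        logger.info("gene_contact_stats: %d gene(s) with no valid bin "
                    "excluded", skipped)
    table = pd.DataFrame(rows, columns=[
        "name", "chrom", "start", "end", "length", "expression", "score"
    ])
    corr = {}
    if len(table) > 1:
        import warnings

        has_expr = ~table["expression"].isna()
        with warnings.catch_warnings():
            # constant input has rho undefined in scipy; reported as 0 here
            warnings.simplefilter("ignore", sps.ConstantInputWarning)
            if has_expr.sum() > 1:
                rho, p = sps.spearmanr(
                    table.loc[has_expr, "score"],
                    np.log1p(table.loc[has_expr, "expression"]),
                )
                corr["score_vs_log_expression"] = (_zero_if_nan(rho), p)
            rho, p = sps.spearmanr(table["score"], table["length"])
            corr["score_vs_length"] = (_zero_if_nan(rho), p)
    return table, corr


def _zero_if_nan(x):
    # constant input yields rho = nan in scipy; the tie convention here is 0
    return 0.0 if np.isnan(x) else float(x)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_fraction(seq: str):
    """(G+C)/(A+C+G+T) of a sequence; ambiguous bases excluded from the
    denominator.  None for a window with no unambiguous base."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def gc_windows(fasta, peaks: PeakSet, window: int = DEFAULT_GC_WINDOW):
    """GC fraction around each peak plus the genome-wide distribution.

    ``fasta`` is a mapping chromosome -> sequence (e.g. a ``pyfaidx.Fasta``).
    Each hotspot window is ``window`` bp centred on the peak bin; the genome
    distribution uses non-overlapping windows of the same size over host
    chromosomes, so the two are comparable.  Returns
    ``(hotspot_gc, genome_gc)`` lists (missing windows dropped).
    """
    g = peaks.genome
    hot = []
    for chrom, pos in zip(peaks.table["chrom"], peaks.table["pos"]):
        center = pos + g.bin_size // 2
        lo = max(0, center - window // 2)
        hi = min(g.chrom_length(chrom), center + window // 2)
        frac = gc_fraction(str(fasta[chrom][lo:hi]))
        if frac is not None:
            hot.append(frac)
    genome_gc = []
    for chrom in g.host_chromosomes:
        L = g.chrom_length(chrom)
        for lo in range(0, L - window + 1, window):
            frac = gc_fraction(str(fasta[chrom][lo:lo + window]))
            if frac is not None:
                genome_gc.append(frac)
    return hot, genome_gc


# ---------------------------------------------------------------------------
# TSS-anchored phase comparison
# ---------------------------------------------------------------------------

def _refined_argmax(y: np.ndarray, k: int) -> float:
    """Sub-sample argmax by quadratic interpolation around index k."""
    if 0 < k < y.size - 1:
        a, b, c = y[k - 1], y[k], y[k + 1]
        denom = a - 2 * b + c
        if denom < 0:
            return k + 0.5 * (a - c) / denom
    return float(k)


def tss_phase(track_a: SignalTrack, track_b: SignalTrack, tss_loci,
              flank: int = 1_000):
    """Phase shift between two periodic tracks averaged over TSS windows.

    Both tracks are averaged over +/- ``flank`` bp windows centred on the TSS
    positions; the dominant period of ``track_a`` is taken from the first
    local maximum of its autocorrelation beyond lag 0, the lag from the
    maximum of the cross-correlation of the two mean curves (both refined to
    sub-bin precision by quadratic interpolation).  Returns
    ``(lag_bp, phase_deg)`` with the phase folded into [0, 180].

    Meant for high-resolution binning (<= 50 bp); raises on a flat track
    (undefined period).
    """
    if track_a.genome is not track_b.genome and \
            track_a.genome != track_b.genome:
        raise ValueError("tracks are on different genomes")
    bs = track_a.genome.bin_size
    ma, _, _ = mean_profile(window_stack(track_a, tss_loci, flank=flank))
    mb, _, _ = mean_profile(window_stack(track_b, tss_loci, flank=flank))
    ok = ~np.isnan(ma) & ~np.isnan(mb)
    a = ma[ok] - np.nanmean(ma[ok])
    b = mb[ok] - np.nanmean(mb[ok])
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("flat track: period undefined")
    # dominant period of track_a from its autocorrelation
    ac = np.correlate(a, a, mode="full")[a.size - 1:]
    cand = [
        k for k in range(1, ac.size - 1)
        if ac[k] >= ac[k - 1] and ac[k] > ac[k + 1]
    ]
    if not cand:
        raise ValueError("no periodicity detected in track_a")
    k0 = max(cand, key=lambda k: ac[k])
    period = _refined_argmax(ac, k0) * bs
    # lag of maximal cross-correlation, restricted to +/- one period
    xc = np.correlate(b, a, mode="full")
    lags = np.arange(-(a.size - 1), a.size)
    span = np.abs(lags * bs) <= period
    kbest = int(np.flatnonzero(span)[np.argmax(xc[span])])
    lag = (_refined_argmax(xc, kbest) - (a.size - 1)) * bs
    phase = (lag / period) * 360.0
    phase = abs((phase + 180.0) % 360.0 - 180.0)
    return lag, phase
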