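"""Core domain types: binned genomes, sparse contact matrices, tracks, features.

Coordinates are 0-based, half-open everywhere.  A :class:`BinnedGenome` fixes a
chromosome order and a fixed-width binning; every other container indexes into
it, either through *global* flat bin indices (all contigs, plasmids included)
or through the *host vector* (host-chromosome bins only, in chromosome order),
which is the coordinate system of scores and signal tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("tetherscan")

FEATURE_CLASSES = ("gene", "subtelomere", "centromere", "other")


@dataclass(frozen=True)
class BinnedGenome:
    """Chromosome names/lengths plus a fixed-width binning.

    Parameters
    ----------
    names
        Ordered chromosome (contig) names, plasmid contigs included.
    lengths
        Lengths in bp, same order as ``names``.
    bin_size
        Bin width in bp (default 2000).  Every chromosome is tiled by
        ``ceil(length / bin_size)`` bins; only the last bin may be short.
    plasmids
        Subset of ``names`` flagged as episomal contigs.
    """

    names: tuple
    lengths: tuple
    bin_size: int = 2000
    plasmids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        unknown = set(self.plasmids) - set(self.names)
        if unknown:
            raise ValueError(f"plasmid contigs not in genome: {sorted(unknown)}")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))
        object.__setattr__(self, "plasmids", frozenset(self.plasmids))

    # -- derived tables (computed lazily, cached on the instance) ----------
    def _tables(self):
        cached = getattr(self, "_cache", None)
        if cached is not None:
            return cached
        nbins = np.array(
            [-(-l // self.bin_size) for l in self.lengths], dtype=np.int64
        )
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        is_host = np.array([n not in self.plasmids for n in self.names])
        # host vector: concatenation of host chromosomes in order
        host_nbins = nbins[is_host]
        host_offsets = np.concatenate([[0], np.cumsum(host_nbins)])
        # global flat index of each host-vector position
        host_flat = np.concatenate(
            [
                np.arange(offsets[c], offsets[c] + nbins[c])
                for c in range(len(self.names))
                if is_host[c]
            ]
        ) if is_host.any() else np.array([], dtype=np.int64)
        cache = {
            "nbins": nbins,
            "offsets": offsets,
            "is_host": is_host,
            "host_nbins": host_nbins,
            "host_offsets": host_offsets,
            "host_flat": host_flat,
            "index": {n: c for c, n in enumerate(self.names)},
        }
        object.__setattr__(self, "_cache", cache)
        return cache

    # -- basic accessors ----------------------------------------------------
    @property
    def total_bins(self) -> int:
        t = self._tables()
        return int(t["offsets"][-1])

    @property
    def n_genome(self) -> int:
        """Number of host (non-plasmid) bins."""
        return int(self._tables()["host_nbins"].sum())

    @property
    def host_chromosomes(self) -> tuple:
        t = self._tables()
        return tuple(n for n, h in zip(self.names, t["is_host"]) if h)

    def chrom_index(self, name: str) -> int:
        try:
            return self._tables()["index"][name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chrom_length(self, name: str) -> int:
        return self.lengths[self.chrom_index(name)]

    def n_bins(self, name: str) -> int:
        return int(self._tables()["nbins"][self.chrom_index(name)])

    def is_plasmid(self, name: str) -> bool:
        return name in self.plasmids

    def bin_of(self, pos: int) -> int:
        """Bin ordinal of a bp position: ``floor(pos / bin_size)``."""
        return int(pos) // self.bin_size

    # -- global flat indexing ------------------------------------------------
    def flat_index(self, chrom: str, bin_ordinal: int) -> int:
        t = self._tables()
        c = self.chrom_index(chrom)
        if not 0 <= bin_ordinal < t["nbins"][c]:
            raise IndexError(
                f"bin {bin_ordinal} out of range for {chrom} "
                f"({t['nbins'][c]} bins)"
            )
        return int(t["offsets"][c] + bin_ordinal)

    def locate(self, flat: int):
        """Invert a global flat index to ``(chrom, bin_ordinal)``."""
        t = self._tables()
        if not 0 <= flat < t["offsets"][-1]:
            raise IndexError(f"flat index {flat} out of range")
        c = int(np.searchsorted(t["offsets"], flat, side="right") - 1)
        return self.names[c], int(flat - t["offsets"][c])

    # -- host-vector indexing ------------------------------------------------
    def host_vector_slices(self):
        """``{chrom: slice}`` of each host chromosome in the host vector."""
        t = self._tables()
        out = {}
        k = 0
        for n, h in zip(self.names, t["is_host"]):
            if h:
                nb = self.n_bins(n)
                out[n] = slice(int(t["host_offsets"][k]),
                               int(t["host_offsets"][k] + nb))
                k += 1
        return out

    def host_index(self, chrom: str, bin_ordinal: int) -> int:
        """Host-vector position of a bin of a host chromosome."""
        if self.is_plasmid(chrom):
            raise ValueError(f"{chrom!r} is a plasmid contig")
        sl = self.host_vector_slices()[chrom]
        if not 0 <= bin_ordinal < sl.stop - sl.start:
            raise IndexError(f"bin {bin_ordinal} out of range for {chrom}")
        return sl.start + bin_ordinal

    def host_to_flat(self) -> np.ndarray:
        """Global flat index of every host-vector position."""
        return self._tables()["host_flat"].copy()

    def host_chrom_of(self) -> np.ndarray:
        """Host-chromosome index (into host_chromosomes) per host position."""
        t = self._tables()
        return np.repeat(np.arange(len(t["host_nbins"])), t["host_nbins"])


@dataclass(frozen=True)
class LibraryStats:
    """Library-level read totals used to normalise the contact score.

    ``n_plasmid`` is the number of aligned reads on the plasmid contig (an
    intra-plasmid pair contributes two, a plasmid-host pair one);
    ``n_total`` is the total number of aligned reads, i.e. twice the number
    of informative pairs.
    """

    n_plasmid: int
    n_total: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_plasmid <= self.n_total:
            raise ValueError("require 0 <= n_plasmid <= n_total")

    @property
    def plasmid_fraction(self) -> float:
        return self.n_plasmid / self.n_total


class ContactMatrix:
    """Sparse symmetric contact counts, stored upper-triangular (i <= j)."""

    def __init__(self, genome: BinnedGenome, i, j, counts):
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        n = genome.total_bins
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValueError("bin index out of range")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        m = sp.coo_matrix((counts, (lo, hi)), shape=(n, n))
        m.sum_duplicates()
        self.genome = genome
        self._upper = m.tocsr()
        self._sym = None

    # -- queries -------------------------------------------------------------
    def query(self, i: int, j: int) -> int:
        lo, hi = min(i, j), max(i, j)
        return int(self._upper[lo, hi])

    def total(self) -> int:
        """Total number of pair counts (each unordered pair once)."""
        return int(self._upper.sum())

    @property
    def upper(self) -> sp.csr_matrix:
        return self._upper

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix; the diagonal keeps its stored value."""
        if self._sym is None:
            u = self._upper
            d = u.diagonal()
            nz = np.flatnonzero(d)
            dm = sp.csr_matrix((d[nz], (nz, nz)), shape=u.shape)
            self._sym = (u + u.T - dm).tocsr()
        return self._sym

    def triplets(self):
        """Upper-triangular ``(i, j, count)`` arrays with count > 0."""
        c = self._upper.tocoo()
        keep = c.data > 0
        return c.row[keep], c.col[keep], c.data[keep]

    def marginals(self) -> np.ndarray:
        """Total contacts per bin; a pair touching the bin counts once,
        including on-diagonal pairs."""
        i, j, c = self.triplets()
        n = self.genome.total_bins
        t = np.bincount(i, weights=c, minlength=n)
        off = i != j
        t += np.bincount(j[off], weights=c[off], minlength=n)
        return t

    def plasmid_contacts(self, plasmid: str) -> np.ndarray:
        """Per-host-bin contacts with ``plasmid`` (the host vector cp_i)."""
        g = self.genome
        if not g.is_plasmid(plasmid):
            raise ValueError(f"{plasmid!r} is not flagged as a plasmid contig")
        sym = self.symmetric()
        c0 = g.flat_index(plasmid, 0)
        cols = np.arange(c0, c0 + g.n_bins(plasmid))
        cp_all = np.asarray(sym[:, cols].sum(axis=1)).ravel()
        return cp_all[g.host_to_flat()]

    def library_stats(self, plasmid: str) -> LibraryStats:
        """Derive read totals from the matrix itself.

        Reads on the plasmid = trans plasmid-host pairs (one end) plus twice
        the intra-plasmid pairs; total reads = twice the pair total.
        """
        g = self.genome
        if not g.is_plasmid(plasmid):
            raise ValueError(f"{plasmid!r} is not flagged as a plasmid contig")
        i, j, c = self.triplets()
        c0 = g.flat_index(plasmid, 0)
        c1 = c0 + g.n_bins(plasmid)
        on_p_i = (i >= c0) & (i < c1)
        on_p_j = (j >= c0) & (j < c1)
        ends = np.where(on_p_i, 1, 0) + np.where(on_p_j, 1, 0)
        n_plasmid = int((c * ends).sum())
        return LibraryStats(n_plasmid=n_plasmid, n_total=2 * self.total())


class SignalTrack:
    """Per-host-bin real-valued signal (CPM, ratio, or dimensionless).

    Missing bins are NaN; they are carried, never dropped, so window
    extraction stays aligned.
    """

    def __init__(self, genome: BinnedGenome, values, units: str = ""):
        values = np.asarray(values, dtype=float)
        if values.shape != (genome.n_genome,):
            raise ValueError(
                f"track length {values.shape} != host bin count "
                f"({genome.n_genome},)"
            )
        self.genome = genome
        self.values = values
        self.units = units

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def chromosome_values(self, chrom: str) -> np.ndarray:
        return self.values[self.genome.host_vector_slices()[chrom]]


class FeatureSet:
    """Genomic intervals (0-based half-open) with per-interval attributes."""

    COLUMNS = ["chrom", "start", "end", "name", "feat_class", "expression"]

    def __init__(self, table: pd.DataFrame):
        df = table.copy().reset_index(drop=True)
        for col, default in (
            ("name", None), ("feat_class", "other"), ("expression", np.nan)
        ):
            if col not in df.columns:
                df[col] = default
        if df["name"].isna().any():
            df.loc[df["name"].isna(), "name"] = [
                f"feature_{k}" for k in df.index[df["name"].isna()]
            ]
        df = df[self.COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]].tolist()
            raise ValueError(f"start >= end for feature rows {bad}")
        bad_class = set(df["feat_class"]) - set(FEATURE_CLASSES)
        if bad_class:
            raise ValueError(f"unknown feature classes: {sorted(bad_class)}")
        df["length"] = df["end"] - df["start"]
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def validate_against(self, genome: BinnedGenome) -> None:
        for chrom, end in zip(self.table["chrom"], self.table["end"]):
            if chrom not in genome.names:
                raise ValueError(f"feature on unknown chromosome {chrom!r}")
            if end > genome.chrom_length(chrom):
                raise ValueError(
                    f"feature exceeds {chrom} length "
                    f"({end} > {genome.chrom_length(chrom)})"
                )

    def subset(self, mask) -> "FeatureSet":
        return FeatureSet(self.table.loc[mask].drop(columns="length"))

    def of_class(self, feat_class: str) -> "FeatureSet":
        return self.subset(self.table["feat_class"] == feat_class)

    def bin_indicator(self, genome: BinnedGenome) -> np.ndarray:
        """Boolean host-vector: bin overlaps at least one feature."""
        ind = np.zeros(genome.n_genome, dtype=bool)
        slices = genome.host_vector_slices()
        bs = genome.bin_size
        for chrom, start, end in zip(
            self.table["chrom"], self.table["start"], self.table["end"]
        ):
            if chrom not in slices:
                continue
            sl = slices[chrom]
            b0 = start // bs
            b1 = min(-(-end // bs), sl.stop - sl.start)
            ind[sl.start + b0: sl.start + b1] = True
        return ind


@dataclass
class ContactProfile:
    """Normalised plasmid contact score S_i over host bins.

    ``scores`` is the host vector; NaN marks bins with no contact coverage
    (score undefined).  A score of 1 equals the expectation under contacts
    proportional to bin coverage.
    """

    genome: BinnedGenome
    scores: np.ndarray
    plasmid: str
    stats: LibraryStats
    interpolated: bool = False

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.genome.n_genome,):
            raise ValueError("score vector length != host bin count")
        valid = self.scores[~np.isnan(self.scores)]
        if valid.size and valid.min() < 0:
            raise ValueError("scores must be nonnegative")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def chromosome_scores(self, chrom: str) -> np.ndarray:
        return self.scores[self.genome.host_vector_slices()[chrom]]


@dataclass
class PeakSet:
    """Called contact hotspots: one bin apex per peak.

    ``table`` columns: chrom, pos (bp, bin start), score.  Peaks are sorted
    by (chromosome order, position).
    """

    genome: BinnedGenome
    table: pd.DataFrame
    height: float
    distance: int
    source: str = ""

    def __post_init__(self):
        df = self.table.copy().reset_index(drop=True)
        order = {n: k for k, n in enumerate(self.genome.names)}
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
        ).reset_index(drop=True)
        if len(df) and df["score"].min() < self.height:
            raise ValueError("peak below the height threshold")
        bs = self.genome.bin_size
        for chrom, grp in df.groupby("chrom", sort=False):
            gaps = np.diff(grp["pos"].to_numpy()) // bs
            if len(gaps) and gaps.min() < self.distance:
                raise ValueError(f"peaks closer than `distance` on {chrom}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def host_positions(self) -> np.ndarray:
        """Host-vector index of each peak's bin."""
        g = self.genome
        return np.array(
            [
                g.host_index(c, p // g.bin_size)
                for c, p in zip(self.table["chrom"], self.table["pos"])
            ],
            dtype=np.int64,
        )
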