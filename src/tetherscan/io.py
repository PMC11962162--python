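"""Readers and writers: COO contact text, single-resolution cooler (HDF5),
bedGraph tracks, BED4/GFF3 features, TSV outputs.

The COO text dialect is the round-trip format for contact matrices::

    # tetherscan-coo
    # bin_size: 2000
    # chrom: chrI 230000
    # plasmid: plasmid_2micron 6300
    # columns: idx1 idx2 count
    0	3	2

Triplet rows are either global flat indices (``idx1 idx2 count``) or
``chrom1 pos1 chrom2 pos2 count`` with bp positions.
"""

from __future__ import annotations

import io as _io
import logging
import re

import h5py
import numpy as np
import pandas as pd

from .core import BinnedGenome, ContactMatrix, FeatureSet, SignalTrack

logger = logging.getLogger("tetherscan")

TOOL = "tetherscan 0.1.0"


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    g = matrix.genome
    i, j, c = matrix.triplets()
    with open(path, "w") as fh:
        fh.write("# tetherscan-coo\n")
        fh.write(f"# tool: {TOOL}\n")
        fh.write(f"# bin_size: {g.bin_size}\n")
        for name, length in zip(g.names, g.lengths):
            kind = "plasmid" if g.is_plasmid(name) else "chrom"
            fh.write(f"# {kind}: {name} {length}\n")
        fh.write("# columns: idx1 idx2 count\n")
        pd.DataFrame({"i": i, "j": j, "c": c}).to_csv(
            fh, sep="\t", header=False, index=False
        )


def _parse_coo_header(path):
    names, lengths, plasmids = [], [], []
    bin_size = None
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("bin_size:"):
                bin_size = int(body.split(":", 1)[1])
            elif body.startswith(("chrom:", "plasmid:")):
                kind, rest = body.split(":", 1)
                name, length = rest.split()
                names.append(name)
                lengths.append(int(length))
                if kind == "plasmid":
                    plasmids.append(name)
    if bin_size is None or not names:
        raise ValueError(f"{path}: missing bin_size or chromosome header")
    return BinnedGenome(tuple(names), tuple(lengths), bin_size,
                        frozenset(plasmids)), n_header


def _load_coo_text(path, genome=None):
    file_genome, n_header = _parse_coo_header(path)
    genome = genome or file_genome
    body = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, skiprows=n_header,
        dtype=str,
    ) if _has_body(path) else pd.DataFrame()
    if body.empty:
        return genome, ContactMatrix(genome, [], [], [])
    if body.shape[1] == 3:
        i = body[0].astype(np.int64)
        j = body[1].astype(np.int64)
        counts = _int_counts(body[2], path)
    elif body.shape[1] == 5:
        for col in (0, 2):
            unknown = set(body[col]) - set(genome.names)
            if unknown:
                raise ValueError(
                    f"{path}: unknown chromosome name(s) {sorted(unknown)}"
                )
        i = [
            genome.flat_index(c, int(p) // genome.bin_size)
            for c, p in zip(body[0], body[1])
        ]
        j = [
            genome.flat_index(c, int(p) // genome.bin_size)
            for c, p in zip(body[2], body[3])
        ]
        counts = _int_counts(body[4], path)
    else:
        raise ValueError(f"{path}: expected 3 or 5 columns in COO triplets")
    return genome, ContactMatrix(genome, i, j, counts)


def _has_body(path):
    with open(path) as fh:
        return any(not l.startswith("#") and l.strip() for l in fh)


def _int_counts(series, path):
    vals = pd.to_numeric(series)
    if (vals < 0).any():
        raise ValueError(f"{path}: negative contact count")
    if not np.all(vals == np.floor(vals)):
        raise ValueError(f"{path}: non-integer contact count")
    return vals.astype(np.int64).to_numpy()


def _load_cooler(path, plasmids=()):
    """Read a single-resolution cooler file (HDF5 layout) via h5py."""
    with h5py.File(path, "r") as f:
        root = f
        if "pixels" not in f:  # multi-resolution container not supported
            raise ValueError(
                f"{path}: not a single-resolution cooler file"
            )
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in root["chroms/name"][:]
        ]
        lengths = [int(x) for x in root["chroms/length"][:]]
        starts = root["bins/start"][:]
        ends = root["bins/end"][:]
        widths = ends - starts
        bin_size = int(np.bincount(widths.astype(np.int64)).argmax())
        i = root["pixels/bin1_id"][:]
        j = root["pixels/bin2_id"][:]
        c = root["pixels/count"][:]
    genome = BinnedGenome(tuple(names), tuple(lengths), bin_size,
                          frozenset(plasmids))
    return genome, ContactMatrix(genome, i, j, c)


def load_contact_matrix(path, genome=None, plasmids=()):
    """Load a contact matrix from COO text or a single-resolution cooler.

    Returns ``(BinnedGenome, ContactMatrix)``.  ``plasmids`` flags episomal
    contigs when reading cooler files (the COO header carries its own flags);
    ``genome`` overrides the file's genome for the text dialect.
    """
    if h5py.is_hdf5(path):
        return _load_cooler(path, plasmids)
    return _load_coo_text(path, genome)


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "value": float},
    )
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite bedGraph value")
    return df


def bin_track(intervals: pd.DataFrame, genome: BinnedGenome,
              units: str = "") -> SignalTrack:
    """Bin bedGraph intervals onto the genome's host bins.

    Each bin's value is the length-weighted mean of covering interval values,
    averaged over covered bases only; uncovered bins are NaN.  Intervals past
    a chromosome end are truncated (warning); overlapping intervals are
    rejected (the dialect is ambiguous).
    """
    df = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    bs = genome.bin_size
    slices = genome.host_vector_slices()
    weight = np.zeros(genome.n_genome)
    wsum = np.zeros(genome.n_genome)
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in slices:
            raise ValueError(f"bedGraph chromosome {chrom!r} not a host "
                             "chromosome of the genome")
        sl = slices[chrom]
        clen = genome.chrom_length(chrom)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        if (ends > clen).any():
            logger.warning(
                "bedGraph interval(s) beyond end of %s truncated", chrom
            )
            ends = np.minimum(ends, clen)
        for s, e, v in zip(starts, ends, vals):
            if e <= s:
                continue
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                lo = max(s, b * bs)
                hi = min(e, (b + 1) * bs)
                weight[sl.start + b] += hi - lo
                wsum[sl.start + b] += (hi - lo) * v
    values = np.full(genome.n_genome, np.nan)
    covered = weight > 0
    values[covered] = wsum[covered] / weight[covered]
    return SignalTrack(genome, values, units=units)


def write_track_bedgraph(track: SignalTrack, path) -> None:
    g = track.genome
    bs = g.bin_size
    with open(path, "w") as fh:
        fh.write(f"# {TOOL}; bin_size={bs}; units={track.units}\n")
        for chrom, sl in g.host_vector_slices().items():
            vals = track.values[sl]
            clen = g.chrom_length(chrom)
            for b, v in enumerate(vals):
                if np.isnan(v):
                    continue
                fh.write(
                    f"{chrom}\t{b * bs}\t{min((b + 1) * bs, clen)}\t{v:.10g}\n"
                )


# ---------------------------------------------------------------------------
# features (BED4 / GFF3)
# ---------------------------------------------------------------------------

_GFF_ATTR = {
    "gene": "gene", "centromere": "centromere", "telomere": "subtelomere",
}


def load_features(path, feat_class: str = "gene") -> FeatureSet:
    """Load a BED4 or GFF3 annotation into a FeatureSet.

    GFF coordinates (1-based closed) are converted to 0-based half-open.
    Records with start >= end after conversion are rejected with a logged
    line number; the remainder is loaded.
    """
    text = open(path).read()
    is_gff = path_is_gff(path, text)
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if is_gff:
            if len(parts) < 5:
                logger.warning("%s:%d: short GFF record skipped", path, ln)
                continue
            chrom, ftype = parts[0], parts[2]
            start, end = int(parts[3]) - 1, int(parts[4])
            name = _gff_name(parts[8]) if len(parts) > 8 else None
            cls = _GFF_ATTR.get(ftype.lower(), feat_class)
            expr = _gff_expression(parts[8]) if len(parts) > 8 else np.nan
        else:
            if len(parts) < 3:
                logger.warning("%s:%d: short BED record skipped", path, ln)
                continue
            chrom = parts[0]
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            cls = feat_class
            expr = float(parts[4]) if len(parts) > 4 and parts[4] not in (
                ".", "") else np.nan
        if start >= end:
            logger.warning("%s:%d: start >= end, record rejected", path, ln)
            continue
        rows.append((chrom, start, end, name, cls, expr))
    return FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "feat_class",
                       "expression"]
    ))


def path_is_gff(path, text: str) -> bool:
    name = str(path).lower()
    if name.endswith((".gff", ".gff3")):
        return True
    if name.endswith(".bed"):
        return False
    for line in text.splitlines():
        if line.startswith("##gff"):
            return True
        if line.strip() and not line.startswith("#"):
            return len(line.split("\t")) >= 8
    return False


def _gff_name(attrs: str):
    for key in ("ID", "Name", "gene_id"):
        m = re.search(rf"{key}=([^;]+)", attrs)
        if m:
            return m.group(1)
    return None


def _gff_expression(attrs: str) -> float:
    m = re.search(r"expression=([^;]+)", attrs)
    return float(m.group(1)) if m else np.nan


def write_features_bed(features: FeatureSet, path, genome=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL}")
        if genome is not None:
            fh.write(f"; bin_size={genome.bin_size}")
        fh.write("\n")
        features.table[["chrom", "start", "end", "name"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# generic TSV output with provenance header
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, genome=None, extra=()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL}\n")
        if genome is not None:
            fh.write(
                f"# genome: {len(genome.names)} contigs, "
                f"bin_size={genome.bin_size}\n"
            )
        for line in extra:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")
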