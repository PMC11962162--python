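"""Hotspot enrichment screen over many binned genomic signal tracks.

For each library the screen averages the signal over every hotspot bin plus
``flank`` bp on each side (one bin at the default 2 kb binning / 2 kb flank)
and compares it to the genome-wide mean.  Both the raw hotspot mean (the
plotted quantity in hotspot screens) and the genome-normalised ratio are
reported; raw means are not comparable across libraries of different depth,
the ratio is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PeakSet, SignalTrack

logger = logging.getLogger("tetherscan")

DEFAULT_SCREEN_FLANK = 2_000


@dataclass
class ScreenRecord:
    library: str
    category: str
    hotspot_mean: float
    genome_mean: float
    ratio: float
    n_hotspots: int


def hotspot_signal_score(track: SignalTrack, peaks: PeakSet,
                         flank: int = DEFAULT_SCREEN_FLANK):
    """``(hotspot_mean, genome_mean, ratio)`` for one track.

    The hotspot mean pools, across peaks, all valid bins within
    ``flank // bin_size`` bins of each peak bin; the genome mean is over all
    valid host bins.  Raises when every hotspot bin is masked.
    """
    g = track.genome
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    w = flank // g.bin_size
    slices = g.host_vector_slices()
    pooled = []
    for chrom, pos in zip(peaks.table["chrom"], peaks.table["pos"]):
        sl = slices[chrom]
        b = pos // g.bin_size
        lo = max(0, b - w)
        hi = min(sl.stop - sl.start, b + w + 1)
        pooled.append(track.values[sl.start + lo: sl.start + hi])
    pooled = np.concatenate(pooled)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError(
            f"all hotspot bins masked for track "
            f"{track.units or '(unnamed)'}"
        )
    hotspot_mean = float(pooled.mean())
    genome_mean = float(np.nanmean(track.values))
    ratio = hotspot_mean / genome_mean if genome_mean > 0 else np.nan
    return hotspot_mean, genome_mean, ratio


def screen_libraries(tracks, peaks: PeakSet,
                     flank: int = DEFAULT_SCREEN_FLANK):
    """Screen a list of ``(library_id, category, SignalTrack)`` at hotspots.

    Returns ``(table, category_summary)``: one row per library sorted by
    category then descending ratio, and the per-category median ratio.
    Duplicate library ids are rejected.
    """
    if not tracks:
        raise ValueError("no tracks to screen")
    ids = [t[0] for t in tracks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library ids in screen manifest")
    records = []
    for lib, cat, track in tracks:
        hmean, gmean, ratio = hotspot_signal_score(track, peaks, flank=flank)
        records.append(ScreenRecord(lib, cat, hmean, gmean, ratio,
                                    len(peaks)))
    table = pd.DataFrame(
        [
            {
                "library": r.library, "category": r.category,
                "hotspot_mean": r.hotspot_mean,
                "genome_mean": r.genome_mean, "ratio": r.ratio,
                "n_hotspots": r.n_hotspots,
            }
            for r in records
        ]
    ).sort_values(["category", "ratio"], ascending=[True, False],
                  kind="stable").reset_index(drop=True)
    summary = (
        table.groupby("category")["ratio"].median().rename("median_ratio")
        .reset_index()
    )
    return table, summary
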