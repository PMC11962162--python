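"""Hotspot detection: interpolation of masked bins and local-maxima calling.

Peaks are called per chromosome as strict local maxima of the interpolated
score, thresholded at ``height`` (score units; 0.8 = 80% of the
uniform-contact expectation) and thinned so that no two peaks are closer
than ``distance`` bins, keeping the higher peak (ties and plateaus resolve
to the leftmost bin, so output is deterministic and order-independent).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import ContactProfile, PeakSet

logger = logging.getLogger("tetherscan")

DEFAULT_HEIGHT = 0.8
DEFAULT_DISTANCE = 2


def interpolate_profile(profile: ContactProfile) -> ContactProfile:
    """Fill masked interior bins by per-chromosome linear interpolation.

    Leading/trailing masked bins stay masked (no extrapolation); valid bins
    are unchanged.  A chromosome with fewer than 2 valid bins is left fully
    masked and logged.
    """
    out = profile.scores.copy()
    for chrom, sl in profile.genome.host_vector_slices().items():
        v = out[sl]
        valid = ~np.isnan(v)
        if valid.sum() < 2:
            if np.isnan(v).any():
                logger.warning(
                    "interpolation: %s has <2 valid bins, left masked", chrom
                )
            continue
        idx = np.arange(v.size)
        first, last = idx[valid][0], idx[valid][-1]
        interior = (idx >= first) & (idx <= last)
        v[interior] = np.interp(idx[interior], idx[valid], v[valid])
        out[sl] = v
    return replace(profile, scores=out, interpolated=True)


def _plateau_maxima(v: np.ndarray):
    """Leftmost indices of strict local maxima, plateau-aware.

    A run of equal values is a maximum when both flanking distinct values are
    strictly lower; runs touching either end of the vector are ineligible
    (no two-sided neighbourhood).
    """
    n = v.size
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[i]:
            out.append(i)
        i = j + 1
    return out


def call_peaks(
    profile: ContactProfile,
    height: float = DEFAULT_HEIGHT,
    distance: int = DEFAULT_DISTANCE,
) -> PeakSet:
    """Call contact hotspots on an interpolated profile.

    ``height`` is the minimum score of a peak; among maxima closer than
    ``distance`` bins the higher one wins, resolved greedily from the highest
    peak down.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    g = profile.genome
    bs = g.bin_size
    candidates = []  # (score, chrom_order, bin)
    for order, (chrom, sl) in enumerate(g.host_vector_slices().items()):
        v = profile.scores[sl]
        valid = ~np.isnan(v)
        if not valid.any():
            continue
        lo, hi = np.flatnonzero(valid)[[0, -1]]
        seg = v[lo:hi + 1]
        if np.isnan(seg).any():  # interior gaps: treat each run separately
            runs = _valid_runs(seg)
        else:
            runs = [(0, seg.size)]
        for r0, r1 in runs:
            for m in _plateau_maxima(seg[r0:r1]):
                b = lo + r0 + m
                s = v[b]
                if s >= height:
                    candidates.append((float(s), order, int(b), chrom))
    # greedy suppression: highest first, leftmost wins ties
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: dict = {}
    for s, order, b, chrom in candidates:
        near = kept.get(order, [])
        if all(abs(b - kb) >= distance for kb in near):
            kept.setdefault(order, []).append(b)
    rows = []
    for order, (chrom, sl) in enumerate(g.host_vector_slices().items()):
        for b in sorted(kept.get(order, [])):
            rows.append((chrom, b * bs, float(profile.scores[sl][b])))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "score"])
    logger.info("peak calling (height=%.3g, distance=%d): %d hotspots",
                height, distance, len(table))
    return PeakSet(genome=g, table=table, height=height, distance=distance,
                   source=f"plasmid={profile.plasmid}")


def _valid_runs(seg: np.ndarray):
    valid = ~np.isnan(seg)
    runs = []
    i = 0
    n = seg.size
    while i < n:
        if valid[i]:
            j = i
            while j + 1 < n and valid[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs
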