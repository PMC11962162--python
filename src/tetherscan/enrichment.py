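"""Feature groups and permutation overlap enrichment.

The significance of hotspot/feature overlap is assessed by drawing, for each
of ``n_permutations`` realisations, the same number of distinct host bins
uniformly at random (so chromosomes are hit proportionally to their length)
and counting overlaps exactly as for the observed peaks.  The p-value is the
fraction of realisations with overlap >= observed; no multiple-testing
correction is applied across feature groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedGenome, FeatureSet, PeakSet

logger = logging.getLogger("tetherscan")

DEFAULT_SUBTELOMERE_FLANK = 30_000
DEFAULT_LONG_GENE_BP = 7_000
DEFAULT_PERMUTATIONS = 1_000


def subtelomere_intervals(genome: BinnedGenome,
                          flank: int = DEFAULT_SUBTELOMERE_FLANK) -> FeatureSet:
    """Terminal ``flank`` bp at both ends of every host chromosome.

    Chromosomes shorter than twice the flank yield one merged interval.
    Plasmid contigs are excluded.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    rows = []
    for chrom in genome.host_chromosomes:
        L = genome.chrom_length(chrom)
        if L <= 2 * flank:
            rows.append((chrom, 0, L, f"{chrom}_subtel", "subtelomere"))
        else:
            rows.append((chrom, 0, flank, f"{chrom}_subtel_L", "subtelomere"))
            rows.append((chrom, L - flank, L, f"{chrom}_subtel_R",
                         "subtelomere"))
    return FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "feat_class"]
    ))


def long_gene_group(genes: FeatureSet, min_length: int = DEFAULT_LONG_GENE_BP
                    ) -> FeatureSet:
    """Genes strictly longer than ``min_length`` bp.

    The threshold is species-configurable (7 kb for yeasts, 10 kb for the
    amoeba host) and strict: a gene of exactly ``min_length`` is excluded.
    """
    return genes.subset(genes.table["length"] > min_length)


def feature_hit_count(peaks: PeakSet, features: FeatureSet):
    """``(peak_overlap, features_hit)``.

    ``peak_overlap`` counts peaks whose single-bin interval intersects any
    feature; ``features_hit`` counts features intersected by at least one
    peak (for statements like "15 of the 19 long genes are hotspots").
    """
    g = peaks.genome
    features.validate_against(g)
    bs = g.bin_size
    peak_overlap = 0
    features_hit = np.zeros(len(features), dtype=bool)
    ft = features.table
    for chrom, pos in zip(peaks.table["chrom"], peaks.table["pos"]):
        b0, b1 = pos, min(pos + bs, g.chrom_length(chrom))
        hits = (ft["chrom"] == chrom) & (ft["start"] < b1) & (ft["end"] > b0)
        if hits.any():
            peak_overlap += 1
            features_hit |= hits.to_numpy()
    return int(peak_overlap), int(features_hit.sum())


@dataclass
class EnrichmentResult:
    """Outcome of a permutation overlap test for one feature group."""

    group: str
    observed: int
    n_permutations: int
    n_ge_observed: int
    p_value: float
    null_distribution: np.ndarray
    seed: int
    below_resolution: bool = False  # true when no realisation reached observed
    features_hit: int = 0
    n_peaks: int = 0

    def recompute_p(self) -> float:
        """p-value recomputed from the stored null distribution."""
        return float(
            (np.asarray(self.null_distribution) >= self.observed).mean()
        )

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_distribution))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_distribution, ddof=1))


def permutation_overlap_test(
    peaks: PeakSet,
    features: FeatureSet,
    genome: BinnedGenome,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    group: str = "",
    stratify_chromosomes: bool = False,
) -> EnrichmentResult:
    """Permutation test of peak/feature overlap.

    Each realisation draws ``len(peaks)`` distinct host bins uniformly over
    all host bins (or, with ``stratify_chromosomes``, preserving the
    per-chromosome peak counts) and scores the overlap like the observed
    peaks.  With observed overlap never reached by the null, the result
    records p = 0 and flags that p < 1/n_permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    if peaks.genome is not genome and peaks.genome != genome:
        raise ValueError("peaks and genome do not match")
    n_host = genome.n_genome
    if len(peaks) > n_host:
        raise ValueError("more peaks than host bins")
    features.validate_against(genome)

    indicator = features.bin_indicator(genome)
    observed, features_hit = feature_hit_count(peaks, features)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    if stratify_chromosomes:
        slices = genome.host_vector_slices()
        counts = peaks.table["chrom"].value_counts()
        groups = [
            (slices[c], int(k)) for c, k in counts.items()
        ]
        for r in range(n_permutations):
            tot = 0
            for sl, k in groups:
                draw = rng.choice(sl.stop - sl.start, size=k, replace=False)
                tot += int(indicator[sl.start + draw].sum())
            null[r] = tot
    else:
        k = len(peaks)
        for r in range(n_permutations):
            draw = rng.choice(n_host, size=k, replace=False)
            null[r] = int(indicator[draw].sum())
    n_ge = int((null >= observed).sum())
    p = n_ge / n_permutations
    res = EnrichmentResult(
        group=group, observed=observed, n_permutations=n_permutations,
        n_ge_observed=n_ge, p_value=p, null_distribution=null, seed=seed,
        below_resolution=(n_ge == 0), features_hit=features_hit,
        n_peaks=len(peaks),
    )
    logger.info(
        "enrichment %s: observed=%d null_mean=%.2f p=%s%s",
        group or "(unnamed)", observed, res.null_mean,
        p, " (< 1/n_permutations)" if res.below_resolution else "",
    )
    return res


def enrichment_table(results) -> pd.DataFrame:
    """Summary TSV-ready table of EnrichmentResults."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "n_peaks": r.n_peaks,
                "observed_overlap": r.observed,
                "features_hit": r.features_hit,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "p_value": r.p_value,
                "below_resolution": r.below_resolution,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )
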