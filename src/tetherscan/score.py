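"""Per-bin normalised plasmid contact score.

For every host bin *i* the score is

    S_i = (cp_i / T_i) / (n_plasmid / N_total)

where ``cp_i`` is the number of contacts between the plasmid contig and bin
*i*, ``T_i`` the total number of contacts involving bin *i*, and the
denominator is the plasmid's read share of the whole library.  S_i = 1 means
the bin contacts the plasmid exactly as often as expected if plasmid contacts
were spread proportionally to bin coverage.  Bins with T_i = 0 have an
undefined score and are masked (NaN).

The score is a ratio of proportions: rescaling every count in the library by
a common factor leaves it unchanged, so it is computed on raw counts, never
on balanced matrices.
"""

from __future__ import annotations

import logging

from .core import BinnedGenome, ContactMatrix, ContactProfile, LibraryStats

import numpy as np

logger = logging.getLogger("tetherscan")


def compute_contact_profile(
    matrix: ContactMatrix,
    plasmid: str,
    stats: LibraryStats | None = None,
    include_plasmid_in_total: bool = True,
) -> ContactProfile:
    """Compute the plasmid contact score over all host bins.

    Parameters
    ----------
    matrix
        Contact matrix over host chromosomes plus the plasmid contig.
    plasmid
        Name of the episomal contig (must be flagged in the genome).
    stats
        Library read totals; derived from the matrix when omitted
        (plasmid reads = trans plasmid contacts + 2x intra-plasmid pairs,
        total reads = 2x total pairs).
    include_plasmid_in_total
        Whether T_i includes the bin's contacts with the plasmid itself
        (default True; the plasmid contribution is at most a few percent).
    """
    g = matrix.genome
    if not g.is_plasmid(plasmid):
        raise ValueError(f"{plasmid!r} is not flagged as an episomal contig")
    if stats is None:
        stats = matrix.library_stats(plasmid)
    if stats.n_plasmid == 0:
        raise ValueError("n_plasmid is 0: contact score undefined")

    cp = matrix.plasmid_contacts(plasmid)
    totals = matrix.marginals()[g.host_to_flat()]
    if not include_plasmid_in_total:
        totals = totals - cp
    scores = np.full(g.n_genome, np.nan)
    covered = totals > 0
    scores[covered] = (cp[covered] / totals[covered]) / stats.plasmid_fraction
    n_masked = int((~covered).sum())
    if n_masked:
        logger.info("contact score: %d/%d host bins masked (zero coverage)",
                    n_masked, g.n_genome)
    return ContactProfile(genome=g, scores=scores, plasmid=plasmid,
                          stats=stats)
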