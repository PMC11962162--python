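"""Plasmid copy-number estimation and stability-assay statistics.

Copy number per plasmid-positive cell is estimated from shotgun read
proportions as

    (read proportion / expected proportion) / fraction of positive cells

with expected proportion = plasmid size / genome size (6 kb / 12 Mb = 0.0005
for the natural yeast episome).  Retention assays (colonies replica-plated
onto selective medium) are summarised as pooled proportions with Wilson
95% CIs; conditions are compared with a 2x2 Pearson chi-square on pooled
colony counts (no continuity correction) and copy-number groups with the
equal-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


@dataclass
class StabilityAssay:
    """Colony counts per replicate of one condition/time point."""

    condition: str
    totals: np.ndarray      # colonies on non-selective plates
    positives: np.ndarray   # colonies scored plasmid-positive
    timepoint: str = ""

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.positives = np.asarray(self.positives, dtype=np.int64)
        if self.totals.shape != self.positives.shape:
            raise ValueError("totals and positives differ in shape")
        if (self.totals <= 0).any():
            raise ValueError("totals must be positive")
        if ((self.positives < 0) | (self.positives > self.totals)).any():
            raise ValueError("require 0 <= positives <= totals")

    @property
    def n_replicates(self) -> int:
        return self.totals.size


@dataclass
class CopyNumberEstimate:
    read_proportion: float
    expected_proportion: float
    fraction_positive: float
    plasmids_per_positive_cell: float


def retention_proportion(assay: StabilityAssay, alpha: float = 0.05):
    """Pooled retention proportion with a Wilson (1-alpha) CI.

    Returns ``(proportion, (ci_low, ci_high))``.
    """
    pos = int(assay.positives.sum())
    tot = int(assay.totals.sum())
    ci = proportion_confint(pos, tot, alpha=alpha, method="wilson")
    return pos / tot, (float(ci[0]), float(ci[1]))


def stability_chi_square(assay_a: StabilityAssay, assay_b: StabilityAssay):
    """Pearson chi-square (df=1, no continuity correction) on pooled counts.

    The 2x2 table is [positive, negative] x [condition a, b]; identical
    proportions give chi2 = 0, p = 1.  A degenerate table (any expected
    cell 0) raises.
    """
    a_pos, a_tot = int(assay_a.positives.sum()), int(assay_a.totals.sum())
    b_pos, b_tot = int(assay_b.positives.sum()), int(assay_b.totals.sum())
    table = np.array([
        [a_pos, a_tot - a_pos],
        [b_pos, b_tot - b_pos],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero expected cell)")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def copy_number_per_positive_cell(
    read_proportion: float,
    plasmid_size: int,
    genome_size: int,
    fraction_positive: float,
) -> CopyNumberEstimate:
    """Plasmids per plasmid-positive cell from a shotgun read share."""
    if plasmid_size <= 0 or genome_size <= 0:
        raise ValueError("sizes must be positive")
    if not 0 < fraction_positive <= 1:
        raise ValueError("fraction_positive must be in (0, 1]")
    if read_proportion < 0:
        raise ValueError("read_proportion must be nonnegative")
    expected = plasmid_size / genome_size
    estimate = (read_proportion / expected) / fraction_positive
    return CopyNumberEstimate(
        read_proportion=read_proportion,
        expected_proportion=expected,
        fraction_positive=fraction_positive,
        plasmids_per_positive_cell=estimate,
    )


def copy_number_ttest(group_a, group_b):
    """Two-sided equal-variance two-sample t-test on copy-number estimates.

    Zero pooled variance with equal means returns (0, 1); zero variance
    with different means is an error (the statistic diverges).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with different means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def read_stability_tsv(path) -> dict:
    """Read a stability TSV (condition, replicate, timepoint, positive,
    total) into {(condition, timepoint): StabilityAssay}."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for (cond, tp), grp in df.groupby(["condition", "timepoint"]):
        out[(cond, str(tp))] = StabilityAssay(
            condition=cond, totals=grp["total"].to_numpy(),
            positives=grp["positive"].to_numpy(), timepoint=str(tp),
        )
    return out
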