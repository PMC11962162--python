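# tetherscan

Where does a nuclear episome sit on its host's chromosomes?  Natural
plasmids such as the *Saccharomyces cerevisiae* 2µ circle persist for
millions of years without integrating, apparently by physically tethering
to host chromatin and hitchhiking on chromosome segregation.
Proximity-ligation assays (Hi-C, Micro-C) record trans-contacts between the
episome and every genomic bin, so the tethering landscape can be mapped
directly.  `tetherscan` implements that analysis as a tested, reusable
library and command-line tool for binned contact matrices:

* **Contact score.**  For each host bin *i* at 2 kb resolution,

  `S_i = (cp_i / Σ_j c_ij) / (n_plasmid / N_total)`

  where `cp_i` counts contacts between the plasmid contig and bin *i*,
  `Σ_j c_ij` is the bin's total contact count, and `n_plasmid / N_total` is
  the plasmid's share of the library's reads.  `S_i = 1` means the bin
  contacts the plasmid exactly as often as expected if plasmid contacts
  followed bin coverage; the score is invariant under rescaling of the
  library, so raw (unbalanced) counts are the right input.
* **Hotspot calling.**  After linear interpolation over masked bins, tether
  hotspots are strict local maxima of `S` with height ≥ 0.8 and minimum
  separation 2 bins, called per chromosome.
* **Enrichment.**  Overlap of hotspots with feature groups (subtelomeres =
  terminal 30 kb; genes longer than 7 kb; any custom BED) is tested against
  1000 random draws of the same number of host bins; `p` is the fraction of
  draws with overlap ≥ observed.
* **Aggregate views.**  ±40 kb averaged profiles with 95% confidence
  bands, score-sorted window heatmaps, observed/expected contact pile-ups
  over hotspot pairs (inter-chromosomal mean or distance-decay expectation),
  per-gene score/expression/length rank correlations, GC content of hotspot
  windows, and the lag/phase between two periodic TSS-anchored tracks
  (e.g. nucleosome occupancy vs a partitioning-protein ChIP signal).
* **Screen.**  Mean signal of many binned genomic tracks over hotspot bins
  ± 2 kb, with genome-normalised enrichment ratios per library and category.
* **Plasmid metrics.**  Copy number per plasmid-positive cell from shotgun
  read shares (expected share = plasmid size / genome size; 6 kb / 12 Mb =
  0.0005), retention proportions with Wilson intervals, 2×2 Pearson
  chi-square on colony counts, and equal-variance t-tests.
* **Synthetic data.**  A generator that emulates the study's signal
  structure — a 12 Mb, 16-chromosome host binned at 2 kb with a ~6 kb
  episome, tether sites implanted inside long lowly expressed genes — so
  the whole pipeline is testable end-to-end with no external data.

Inputs are cooler single-resolution files or a plain-text COO dialect for
matrices, bedGraph for tracks, BED4/GFF3 for annotations, and TSV for
colony counts.  See `docs/methods.md` for the model, parameter and design
details.

## Worked example

```python
import numpy as np
from tetherscan import (standard_scenario, compute_contact_profile,
                        interpolate_profile, call_peaks, long_gene_group,
                        permutation_overlap_test, recovery_metrics)

sc = standard_scenario(seed=0)     # 12 Mb host, 30 tether sites at fold 3
profile = compute_contact_profile(sc["matrix"], "plasmid_2micron",
                                  sc["stats"])
peaks = call_peaks(interpolate_profile(profile), height=0.8, distance=2)
print(f"called {len(peaks)} hotspots; "
      f"median background score {np.nanmedian(profile.scores):.2f}; "
      f"top peak score {peaks.table['score'].max():.2f}")

genes = sc["features"].of_class("gene")
res = permutation_overlap_test(peaks, long_gene_group(genes, 7000),
                               sc["genome"], n_permutations=1000, seed=0)
print(f"long-gene overlap: {res.observed}/{len(peaks)} peaks, "
      f"null mean {res.null_mean:.2f}, p = {res.p_value:.3g}")
sens, prec, _ = recovery_metrics(peaks, sc["truth"], sc["genome"])
print(f"recovery vs implanted truth: sensitivity {sens:.2f}, "
      f"precision {prec:.2f}")
```

prints

```
called 31 hotspots; median background score 0.36; top peak score 1.34
long-gene overlap: 29/31 peaks, null mean 1.11, p = 0
recovery vs implanted truth: sensitivity 0.97, precision 0.94
```

The background score sits near 0.36 rather than 1 because roughly half of
a small high-copy episome's reads are plasmid–plasmid ligations, which
inflate the normaliser `n_plasmid / N_total`; the 3-fold tether sites rise
to ~1.1–1.3 and the height-0.8 threshold separates the two regimes.  29 of
31 called hotspots fall in genes longer than 7 kb against a null
expectation of ~1.1, and 29 of the 30 implanted sites are recovered within
±2 bins.

The same analysis is available from the shell:

```sh
tetherscan simulate --seed 0 --outdir sim
tetherscan run --matrix sim/contacts.coo.tsv --plasmid plasmid_2micron \
               --genes sim/genes.bed --outdir out
```

which writes `contact_score.tsv`, `hotspots.bed`, `enrichment.tsv`, the
profile/heatmap/pile-up matrices and a `manifest.json` with parameters,
seeds and input checksums.

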