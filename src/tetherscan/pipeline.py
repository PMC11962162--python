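"""End-to-end orchestration: score -> peaks -> enrichment -> profiles ->
screen, with a JSON manifest recording parameters, seeds and input
checksums.  Deterministic given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .core import FeatureSet
from .enrichment import (DEFAULT_LONG_GENE_BP, DEFAULT_PERMUTATIONS,
                         DEFAULT_SUBTELOMERE_FLANK, enrichment_table,
                         long_gene_group, permutation_overlap_test,
                         subtelomere_intervals)
from .peaks import DEFAULT_DISTANCE, DEFAULT_HEIGHT, call_peaks, \
    interpolate_profile
from .profiles import (DEFAULT_PILEUP_WINDOW, DEFAULT_PROFILE_FLANK,
                       DEFAULT_SORT_FLANK, gene_contact_stats, mean_profile,
                       pileup_pairs, sorted_heatmap, window_stack)
from .score import compute_contact_profile
from .screen import DEFAULT_SCREEN_FLANK, screen_libraries

logger = logging.getLogger("tetherscan")


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration.

    Defaults match the conventional analysis settings: 2 kb bins, peak
    height 0.8 / distance 2, 30 kb subtelomeres, 7 kb long genes, 1000
    permutations, +/-40 kb profiles, +/-20 kb heatmap sort, +/-2 kb screen
    flank.
    """

    matrix: str = ""
    plasmid: str = ""
    genes: str | None = None
    screen_manifest: str | None = None
    outdir: str = "tetherscan_out"
    peak_height: float = DEFAULT_HEIGHT
    peak_distance: int = DEFAULT_DISTANCE
    subtelomere_flank: int = DEFAULT_SUBTELOMERE_FLANK
    long_gene_bp: int = DEFAULT_LONG_GENE_BP
    custom_groups: list = field(default_factory=list)  # BED paths
    n_permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    profile_flank: int = DEFAULT_PROFILE_FLANK
    sort_flank: int = DEFAULT_SORT_FLANK
    pileup_window: int = DEFAULT_PILEUP_WINDOW
    screen_flank: int = DEFAULT_SCREEN_FLANK

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = yaml.safe_load(open(path)) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path):
        yaml.safe_dump(asdict(self), open(path, "w"), sort_keys=False)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis; returns the manifest dict.

    Any stage error aborts with the stage name and offending input in the
    exception message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": tio.TOOL,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    stage = "load"
    try:
        manifest["inputs"]["matrix"] = _sha256(config.matrix)
        genome, matrix = tio.load_contact_matrix(config.matrix)
        features = None
        if config.genes:
            manifest["inputs"]["genes"] = _sha256(config.genes)
            features = tio.load_features(config.genes)

        stage = "score"
        profile = compute_contact_profile(matrix, config.plasmid)
        track_df = _profile_table(profile)
        tio.write_tsv(track_df, out / "contact_score.tsv", genome)
        manifest["stages"]["score"] = {
            "n_valid_bins": int(profile.valid.sum()),
            "n_masked_bins": int((~profile.valid).sum()),
            "plasmid_read_fraction": profile.stats.plasmid_fraction,
        }

        stage = "peaks"
        interp = interpolate_profile(profile)
        peaks = call_peaks(interp, height=config.peak_height,
                           distance=config.peak_distance)
        _write_peaks_bed(peaks, out / "hotspots.bed")
        manifest["stages"]["peaks"] = {
            "n_peaks": len(peaks),
            "height": config.peak_height,
            "distance": config.peak_distance,
        }

        stage = "enrichment"
        results = []
        if len(peaks):
            groups = [("subtelomeres",
                       subtelomere_intervals(genome,
                                             config.subtelomere_flank))]
            if features is not None:
                genes = features.of_class("gene")
                groups.append((
                    f"long_genes_gt_{config.long_gene_bp}",
                    long_gene_group(genes, config.long_gene_bp),
                ))
            for path in config.custom_groups:
                groups.append((Path(path).stem, tio.load_features(path)))
            for name, group in groups:
                if len(group) == 0:
                    continue
                results.append(permutation_overlap_test(
                    peaks, group, genome,
                    n_permutations=config.n_permutations,
                    seed=config.seed, group=name,
                ))
        tio.write_tsv(enrichment_table(results),
                      out / "enrichment.tsv", genome)
        manifest["stages"]["enrichment"] = {
            r.group: r.p_value for r in results
        }

        stage = "profiles"
        if len(peaks):
            stack = window_stack(interp, peaks, flank=config.profile_flank)
            mean, half, nval = mean_profile(stack)
            tio.write_tsv(pd.DataFrame({
                "offset_bp": stack.offsets_bp, "mean": mean,
                "ci_half_width": half, "n_valid": nval,
            }), out / "mean_profile.tsv", genome)
            order, mat = sorted_heatmap(stack, score_flank=config.sort_flank)
            np.savetxt(out / "heatmap.tsv", mat, delimiter="\t")
            for mode in ("intra", "inter"):
                try:
                    pu = pileup_pairs(matrix, peaks, mode=mode,
                                      window=config.pileup_window)
                except ValueError:
                    pu = None
                if pu is not None:
                    np.savetxt(out / f"pileup_{mode}.tsv", pu,
                               delimiter="\t")
            manifest["stages"]["profiles"] = {"n_loci": stack.n_loci}

        stage = "genestats"
        if features is not None:
            table, corr = gene_contact_stats(profile,
                                             features.of_class("gene"))
            tio.write_tsv(table, out / "gene_contact_stats.tsv", genome)
            manifest["stages"]["genestats"] = {
                k: {"rho": v[0], "p": v[1]} for k, v in corr.items()
            }

        stage = "screen"
        if config.screen_manifest and len(peaks):
            manifest["inputs"]["screen_manifest"] = \
                _sha256(config.screen_manifest)
            entries = pd.read_csv(config.screen_manifest, sep="\t",
                                  comment="#")
            tracks = [
                (rec["library"], rec["category"],
                 tio.bin_track(tio.read_bedgraph(rec["path"]), genome))
                for _, rec in entries.iterrows()
            ]
            table, summary = screen_libraries(tracks, peaks,
                                              flank=config.screen_flank)
            tio.write_tsv(table, out / "screen.tsv", genome)
            tio.write_tsv(summary, out / "screen_categories.tsv", genome)
            manifest["stages"]["screen"] = {"n_libraries": len(table)}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}"
        ) from exc

    config.to_yaml(out / "config.resolved.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return manifest


def _profile_table(profile):
    g = profile.genome
    bs = g.bin_size
    rows = []
    for chrom, sl in g.host_vector_slices().items():
        for b, s in enumerate(profile.scores[sl]):
            rows.append((chrom, b * bs,
                         min((b + 1) * bs, g.chrom_length(chrom)),
                         s, not np.isnan(s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score",
                                       "valid"])


def _write_peaks_bed(peaks, path):
    g = peaks.genome
    with open(path, "w") as fh:
        fh.write(f"# {tio.TOOL}; height={peaks.height}; "
                 f"distance={peaks.distance}\n")
        for k, rec in peaks.table.iterrows():
            end = min(rec["pos"] + g.bin_size, g.chrom_length(rec["chrom"]))
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{end}\t"
                     f"hotspot_{k + 1}\t{rec['score']:.4f}\n")
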