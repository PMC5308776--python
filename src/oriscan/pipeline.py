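"""End-to-end pipeline: scan -> pairs -> call origins -> colocalize -> annotate.

Every intermediate file is the public interface of the corresponding stage
(plain BED/TSV, '#'-prefixed header comments); a provenance block recording
the configuration actually used is written alongside the outputs, so a run
is reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .annotate import annotate_origin
from .colocalize import (background_rate, colocalization_table,
                         late_origin_table)
from .io import (read_fasta, write_pairs_tsv, write_peaks_bed, write_sites_bed)
from .motif import FKH_CONSENSUS, enumerate_pairs, scan_sites
from .profiles import (call_early_peaks, read_origin_table, read_signal,
                       select_late_origins, write_origin_table)

logger = logging.getLogger("oriscan")


@dataclass
class RunConfig:
    """Configuration of one analysis run; defaults are the study parameters
    (RYMAAYA consensus, 62-88 bp gaps with the 71-79 bin highlighted,
    200 bp overlap window, 50-100 bp scrambled-background gaps)."""

    genome: str
    signal: Optional[str] = None
    origin_table: Optional[str] = None
    outdir: str = "oriscan_out"
    pattern: str = FKH_CONSENSUS
    gap_min: int = 62
    gap_max: int = 88
    gap_bins: Sequence[tuple[int, int]] = ((62, 70), (71, 79), (80, 88))
    overlap_window: int = 200
    background_gap: tuple[int, int] = (50, 100)
    max_late_ars_len: int = 600
    exclude_chroms: Sequence[str] = ("chrM", "chrmt", "2-micron")
    annotate_loci: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["gap_bins"] = [tuple(b) for b in raw.get("gap_bins", cls.gap_bins)]
        raw["background_gap"] = tuple(raw.get("background_gap", cls.background_gap))
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Missing input files raise FileNotFoundError naming the file.  The run is
    deterministic: identical inputs and config give identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for label, path in (("genome", config.genome), ("signal", config.signal),
                        ("origin table", config.origin_table)):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path}")

    genome = read_fasta(config.genome)
    genome = {c: s for c, s in genome.items() if c not in set(config.exclude_chroms)}
    logger.info("scanning %d chromosomes for %s", len(genome), config.pattern)

    sites = scan_sites(genome, config.pattern)
    write_sites_bed(sites, outdir / "sites.bed")
    pairs = enumerate_pairs(sites, config.gap_min, config.gap_max)
    write_pairs_tsv(pairs, outdir / "pairs.tsv")
    logger.info("%d sites, %d pairs (gap %d-%d)", len(sites), len(pairs),
                config.gap_min, config.gap_max)

    if config.signal and config.origin_table:
        profile = read_signal(config.signal)
        origins = read_origin_table(config.origin_table)
        peaks = call_early_peaks(profile, origins)
        write_peaks_bed(peaks, outdir / "peaks.bed")
        late = select_late_origins(origins, peaks, config.max_late_ars_len)
        write_origin_table(late, outdir / "late.bed")
        logger.info("%d early peaks, %d late origins", len(peaks), len(late))

        table = colocalization_table(pairs, peaks, config.gap_bins,
                                     config.overlap_window)
        background = background_rate(genome, peaks, *config.background_gap,
                                     window=config.overlap_window)
        table.to_csv(outdir / "colocalization.tsv", sep="\t", index=False)
        bg = background.as_frame()
        bg.loc[len(bg)] = {"pattern": "MEAN", "orientation": "all",
                           "fraction": background.mean}
        bg.to_csv(outdir / "background.tsv", sep="\t", index=False)
        late_table = late_origin_table(pairs, late, config.gap_bins,
                                       config.overlap_window)
        late_table.to_csv(outdir / "late_colocalization.tsv", sep="\t", index=False)

        if config.annotate_loci:
            _write_architecture(genome, pairs, config, outdir / "architecture.tsv")

    with open(outdir / "run_config.yaml", "w") as fh:
        fh.write(f"# oriscan {__version__} provenance\n")
        yaml.safe_dump(_yamlable(asdict(config)), fh)
    return outdir


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    return obj


def _write_architecture(genome, pairs, config, path, flank: int = 150) -> None:
    import pandas as pd

    rows = []
    for p in pairs:
        seq = genome[p.chrom]
        lo = max(0, p.upstream.start - flank)
        hi = min(len(seq), p.downstream.end + flank)
        arch = annotate_origin(seq[lo:hi], config.pattern,
                               gap_min=config.gap_min, gap_max=config.gap_max)
        rows.append({
            "chrom": p.chrom, "locus_start": lo, "locus_end": hi,
            "pair_orientation": p.orientation, "gap_bp": p.gap_bp,
            "midpoint": p.midpoint,
            "acs_found": arch.acs_hit is not None,
            "acs_within_100bp": arch.acs_within_100bp,
            "acs_proximal_complementary": arch.acs_proximal_site_on_complementary_strand,
            "n_a_tracks": len(arch.a_tracks),
            "due_signature": arch.due_signature,
            "doubled_site": arch.doubled_site,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
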