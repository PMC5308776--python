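"""File formats: FASTA genomes, BED sites/peaks, TSV pair and result tables.

Coordinates follow the formats' native dialects: BED and bedGraph are
0-based half-open; WIG input is 1-based (handled in :mod:`oriscan.profiles`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import MotifSite, SitePair, make_pair
from .profiles import EarlyOriginPeak


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record, line-wrapped FASTA into {name: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_sites_bed(sites: Iterable[MotifSite], path: str | Path) -> None:
    """BED6; name = matched forward-strand sequence, score = 0."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.matched_seq}\t0\t{s.strand}\n")


def read_sites_bed(path: str | Path) -> list[MotifSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            sites.append(MotifSite(chrom, int(start), strand,
                                   int(end) - int(start), name))
    return sites


def pairs_to_frame(pairs: Sequence[SitePair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": p.chrom,
        "up_start": p.upstream.start, "up_strand": p.upstream.strand,
        "down_start": p.downstream.start, "down_strand": p.downstream.strand,
        "gap_bp": p.gap_bp, "orientation": p.orientation, "midpoint": p.midpoint,
    } for p in pairs])


def write_pairs_tsv(pairs: Sequence[SitePair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path, length: int = 7) -> list[SitePair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        make_pair(MotifSite(r.chrom, int(r.up_start), r.up_strand, length),
                  MotifSite(r.chrom, int(r.down_start), r.down_strand, length))
        for r in df.itertuples(index=False)
    ]


def write_peaks_bed(peaks: Iterable[EarlyOriginPeak], path: str | Path) -> None:
    """BED6 of above-threshold runs; name = peak position, score = peak value."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.run_start}\t{p.run_end}\t"
                     f"peak@{p.peak_pos}\t{p.peak_value:g}\t.\n")


def read_peaks_bed(path: str | Path) -> list[EarlyOriginPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, _ = line.split("\t")[:6]
            peaks.append(EarlyOriginPeak(chrom, int(start), int(end),
                                         int(name.split("@")[1]), float(score), 0.0))
    return peaks
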