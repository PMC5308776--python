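"""Degenerate-consensus motif scanning and paired-site enumeration.

The Forkhead (Fkh1/2) consensus binding site RYMAAYA is written in IUPAC
degenerate nucleotide code (R = A/G, Y = C/T, M = A/C).  Because the
consensus is asymmetric, a match has a strand, and two nearby matches have a
relative orientation: divergent ("head-to-head", upstream match on the minus
strand, downstream on the plus strand), convergent ("tail-to-tail"), or
unidirectional ("head-to-tail").  This module scans a genome for all matches
on both strands, enumerates same-chromosome site pairs under an inner-gap
constraint, and provides the scrambled variants of the consensus used for
background estimation.

Conventions
-----------
* Coordinates are 0-based, half-open.
* ``strand == "+"`` means the forward-strand slice matches the pattern;
  ``"-"`` means it matches the pattern's reverse complement.
* The gap between two sites is the number of bases strictly between the two
  matches (inner-edge distance).
* ``N`` in a sequence never matches any pattern symbol, so assembly gaps
  cannot create sites.
* Matching is case-insensitive; soft-masked (lowercase) bases are scanned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

#: Allowed bases for each IUPAC nucleotide code.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Bases a pattern symbol accepts when matching.  N (on either side) never
#: matches, so assembly gaps and fully wild positions cannot create sites.
MATCH_SETS: dict[str, str] = {**IUPAC_SETS, "N": ""}

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVNacgtrymkswbdhvn",
                            "TGCAYRKMSWVHDBNtgcayrkmswvhdbn")

#: The Fkh1/2 consensus binding site.
FKH_CONSENSUS = "RYMAAYA"

#: Scrambled variants of the consensus (same symbol multiset, hence the same
#: expected hit frequency under any iid base model); used as background.
SCRAMBLED_CONSENSUS = ("YAAYMAR", "MAARYAY", "AAYMYAR")

DIVERGENT = "divergent"
CONVERGENT = "convergent"
UNIDIRECTIONAL = "unidirectional"


@dataclass(frozen=True, order=True)
class MotifSite:
    """One strand-aware consensus match on a chromosome.

    ``start`` is the 0-based position of the leftmost base of the match on
    the forward strand regardless of strand; ``matched_seq`` is the
    forward-strand slice.
    """

    chrom: str
    start: int
    strand: str
    length: int = 7
    matched_seq: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class SitePair:
    """Two same-chromosome sites, upstream before downstream.

    ``gap_bp`` is the inner-edge distance: bases strictly between the two
    matches.  ``midpoint`` is floor((up.start + down.start + down.length)/2),
    the centre of the span covered by the double site.
    """

    upstream: MotifSite
    downstream: MotifSite
    gap_bp: int
    orientation: str
    midpoint: int

    @property
    def chrom(self) -> str:
        return self.upstream.chrom


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty pattern")
    for ch in pattern:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
    return pattern


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC-degenerate string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    for ch in seq:
        if ch.upper() not in IUPAC_SETS:
            raise ValueError(f"invalid nucleotide/IUPAC character {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(window: str, pattern: str) -> bool:
    """True iff ``window`` (over A/C/G/T/N) matches the degenerate pattern.

    ``N`` in the window never matches, by convention (assembly gaps must not
    create sites).
    """
    pattern = _validate_pattern(pattern)
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}")
    window = window.upper()
    for base in window:
        if base not in "ACGTN":
            raise ValueError(f"non-nucleotide character {base!r} in window")
    return all(b in MATCH_SETS[p] for b, p in zip(window, pattern))


def _pattern_regex(pattern: str) -> re.Pattern[str] | None:
    # Lookahead so overlapping matches are all reported; None for a pattern
    # containing N, which can never match.
    if any(not MATCH_SETS[c] for c in pattern):
        return None
    body = "".join(f"[{MATCH_SETS[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan_sites(genome: Mapping[str, str], pattern: str = FKH_CONSENSUS) -> list[MotifSite]:
    """Find every match of ``pattern`` on both strands of every chromosome.

    A position where the forward slice matches both the pattern and its
    reverse complement yields two sites (one per strand).  Output is sorted
    by (chrom, start, strand) with "+" before "-".
    """
    pattern = _validate_pattern(pattern)
    fwd_re = _pattern_regex(pattern)
    rev_re = _pattern_regex(reverse_complement(pattern))
    length = len(pattern)
    sites: list[MotifSite] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        hits = [(m.start(), "+") for m in fwd_re.finditer(seq)] if fwd_re else []
        if rev_re:
            hits += [(m.start(), "-") for m in rev_re.finditer(seq)]
        hits.sort()
        sites.extend(
            MotifSite(chrom, start, strand, length, seq[start:start + length])
            for start, strand in hits
        )
    return sites


def classify_orientation(upstream_strand: str, downstream_strand: str) -> str:
    """Orientation class of an ordered pair of strands.

    (-,+) is divergent ("head-to-head"): the two asymmetric motifs point
    away from each other, the native configuration at ARS305/ARS607 where
    the upstream site reads TGTTTAT and the downstream reads GTAAATA on the
    forward strand.  (+,-) is convergent; same strand is unidirectional.
    """
    for s in (upstream_strand, downstream_strand):
        if s not in ("+", "-"):
            raise ValueError(f"invalid strand {s!r}")
    if upstream_strand == downstream_strand:
        return UNIDIRECTIONAL
    return DIVERGENT if upstream_strand == "-" else CONVERGENT


def make_pair(upstream: MotifSite, downstream: MotifSite) -> SitePair:
    """Build a SitePair from two sites (same chromosome, upstream first)."""
    if upstream.chrom != downstream.chrom:
        raise ValueError("sites on different chromosomes")
    if upstream.start >= downstream.start:
        raise ValueError("upstream site must start before downstream site")
    gap = downstream.start - upstream.end
    mid = (upstream.start + downstream.start + downstream.length) // 2
    return SitePair(upstream, downstream,
                    gap, classify_orientation(upstream.strand, downstream.strand), mid)


def enumerate_pairs(sites: Sequence[MotifSite], gap_min: int, gap_max: int) -> list[SitePair]:
    """All ordered same-chromosome site pairs with gap_min <= gap <= gap_max.

    Every qualifying pair is reported, so one site may belong to several
    pairs and overlapping ("doubled") sites are counted individually; any
    third site lying between the paired sites is ignored.
    """
    if gap_min < 0 or gap_min > gap_max:
        raise ValueError("require 0 <= gap_min <= gap_max")
    pairs: list[SitePair] = []
    by_chrom: dict[str, list[MotifSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: (s.start, s.strand))
        for i, up in enumerate(chrom_sites):
            for down in chrom_sites[i + 1:]:
                gap = down.start - up.end
                if gap > gap_max:
                    break
                if down.start > up.start and gap >= gap_min:
                    pairs.append(make_pair(up, down))
    return pairs


def collapse_pairs(pairs: Iterable[SitePair], midpoint_tol: int = 7) -> list[SitePair]:
    """Collapse near-duplicate pairs (same chromosome and orientation class,
    midpoints within ``midpoint_tol`` bp), keeping the leftmost.

    Off by default in the pipeline: doubled sites (two partially overlapping
    consensus matches at one pair end) are a real feature of several early
    origins and raw counts preserve them.
    """
    kept: list[SitePair] = []
    last: dict[tuple[str, str], int] = {}
    for p in sorted(pairs, key=lambda p: (p.chrom, p.midpoint, p.upstream.start)):
        key = (p.chrom, p.orientation)
        if key in last and p.midpoint - last[key] <= midpoint_tol:
            continue
        last[key] = p.midpoint
        kept.append(p)
    return kept


def scrambled_patterns() -> list[str]:
    """The three scrambled Fkh1/2 consensus variants used for background."""
    return list(SCRAMBLED_CONSENSUS)
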