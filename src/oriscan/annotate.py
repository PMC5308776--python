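"""Origin-architecture annotation.

Early origins carrying divergent Fkh1/2 sites share a recurring
architecture: two consensus sites separated by a 71-79 bp linker, an ARS
consensus sequence (ACS) within ~100 bp of (often overlapping) one site and
on the strand complementary to that site's A-rich consensus, and poly-A
tracks in the linker that act as a DNA-unwinding-element-like signature.
This module detects those features on a single origin locus sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .motif import (FKH_CONSENSUS, IUPAC_SETS, MotifSite, SitePair,
                    enumerate_pairs, make_pair, reverse_complement, scan_sites)

#: Degenerate ACS approximation used when no explicit coordinates are given.
#: The 11-bp T-rich ORC-binding consensus; matching allows one mismatch.
DEFAULT_ACS_PATTERN = "WTTTAYRTTTW"


@dataclass(frozen=True)
class AcsHit:
    """An ACS placement on the locus: ``strand`` is the strand on which the
    element reads T-rich."""

    start: int
    strand: str
    matched_seq: str
    mismatches: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass
class OriginArchitecture:
    """Per-origin annotation of the recurring early-origin features.

    ``due_signature`` follows the poly-A rule evaluated on the inter-site
    linker: at least one continuous A-track of >= 5 bases, or at least two
    maximal 4-base A-tracks (either strand).
    """

    fkh_sites: list[MotifSite] = field(default_factory=list)
    fkh_pair: Optional[SitePair] = None
    acs_hit: Optional[AcsHit] = None
    acs_within_100bp: bool = False
    acs_proximal_site_on_complementary_strand: bool = False
    a_tracks: list[tuple[int, int, str]] = field(default_factory=list)
    due_signature: bool = False
    doubled_site: bool = False


def find_a_tracks(seq: str, min_len: int) -> list[tuple[int, int, str]]:
    """Maximal poly-A runs of length >= ``min_len`` on either strand.

    Returns (start, length, strand) tuples sorted by start; strand "+" for
    A-runs on the given sequence, "-" for T-runs (A-runs on the complement).
    Runs are maximal: not extendable on either side.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    tracks = [(m.start(), len(m.group()), "+")
              for m in re.finditer(rf"A{{{min_len},}}", seq)]
    tracks += [(m.start(), len(m.group()), "-")
               for m in re.finditer(rf"T{{{min_len},}}", seq)]
    return sorted(tracks)


def due_signature(linker_seq: str) -> bool:
    """True iff the linker carries the poly-A unwinding signature: one
    maximal A-track of length >= 5, or two or more of length >= 4."""
    tracks = find_a_tracks(linker_seq, 4)
    if any(length >= 5 for _, length, _ in tracks):
        return True
    return len(tracks) >= 2


def _mismatches(window: str, pattern: str) -> int:
    return sum(b not in IUPAC_SETS[p] for b, p in zip(window, pattern))


def _trich_strand(seq: str) -> str:
    s = seq.upper()
    return "+" if s.count("T") >= s.count("A") else "-"


def locate_acs(seq: str, acs: str | tuple[int, str] = DEFAULT_ACS_PATTERN,
               max_mismatch: int = 2) -> Optional[AcsHit]:
    """Locate the ACS in a locus sequence.

    Explicit ``(offset, wt_seq)`` coordinates are the primary path: the
    slice at ``offset`` is verified (case-insensitively, either strand) and
    echoed back, with the strand set to whichever strand reads T-rich.
    Otherwise the degenerate pattern is matched on both strands allowing up
    to ``max_mismatch`` substitutions (a heuristic fallback — the T-rich
    ORC-binding consensus is only loosely defined, and functional ACSs such
    as the ARS305/ARS737 element TTTTAATATTT sit 2 substitutions from the
    canonical 11-mer, hence the default of 2); the best hit wins, ties
    broken leftmost then plus strand.
    """
    seq = seq.upper()
    if isinstance(acs, tuple):
        offset, wt = acs
        wt = wt.upper()
        found = seq[offset:offset + len(wt)]
        if found == wt:
            return AcsHit(offset, _trich_strand(wt), found, 0)
        if found == reverse_complement(wt):
            return AcsHit(offset, "+" if _trich_strand(wt) == "-" else "-", found, 0)
        return None
    pattern = acs.upper()
    rc = reverse_complement(pattern)
    best: Optional[AcsHit] = None
    for i in range(len(seq) - len(pattern) + 1):
        window = seq[i:i + len(pattern)]
        if "N" in window:
            continue
        for pat, strand in ((pattern, "+"), (rc, "-")):
            mm = _mismatches(window, pat)
            if mm <= max_mismatch and (best is None or mm < best.mismatches):
                best = AcsHit(i, strand, window, mm)
    return best


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge distance between two intervals; 0 when they overlap."""
    return max(0, b_start - a_end, a_start - b_end)


def annotate_origin(locus_seq: str, fkh_pattern: str = FKH_CONSENSUS,
                    acs_spec: str | tuple[int, str] = DEFAULT_ACS_PATTERN,
                    gap_min: int = 62, gap_max: int = 88,
                    proximity_bp: int = 100) -> OriginArchitecture:
    """Annotate one origin locus with its Fkh/ACS/poly-A architecture.

    Coordinates in the result are local to ``locus_seq``.  When several
    qualifying pairs exist the leftmost (smallest upstream start) is
    annotated.  All fields are null-safe when no pair or no ACS is found.
    """
    arch = OriginArchitecture()
    genome = {"locus": locus_seq}
    arch.fkh_sites = scan_sites(genome, fkh_pattern)
    pairs = enumerate_pairs(arch.fkh_sites, gap_min, gap_max)
    arch.acs_hit = locate_acs(locus_seq, acs_spec)
    if not pairs:
        return arch
    arch.fkh_pair = pairs[0]
    up, down = arch.fkh_pair.upstream, arch.fkh_pair.downstream

    linker = locus_seq[up.end:down.start].upper()
    arch.a_tracks = [(s + up.end, ln, st) for s, ln, st in find_a_tracks(linker, 4)]
    arch.due_signature = due_signature(linker)

    if arch.acs_hit is not None:
        acs = arch.acs_hit
        d_up = _edge_distance(acs.start, acs.end, up.start, up.end)
        d_down = _edge_distance(acs.start, acs.end, down.start, down.end)
        arch.acs_within_100bp = min(d_up, d_down) <= proximity_bp
        proximal = up if d_up <= d_down else down
        arch.acs_proximal_site_on_complementary_strand = proximal.strand != acs.strand

    arch.doubled_site = any(
        other is not site and other.chrom == site.chrom
        and other.start < site.end and site.start < other.end
        for site in (up, down) for other in arch.fkh_sites
    )
    return arch
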