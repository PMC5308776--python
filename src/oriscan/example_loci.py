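"""Synthetic reconstructions of the ARS607 and ARS305 origin loci.

These are NOT the genomic sequences: they are synthetic constructs that
embody the documented sequence architecture of the two origins — the exact
Fkh1/2 site 7-mers (proximal TGTTTAT read on the minus strand, distal
GTAAATA on the plus strand), the 72-bp inner gap between them, the ACS
strings (GTTTATATTTAG for ARS607, partially overlapping the proximal site;
TTTATATGTTTT for ARS305, upstream of it), and a 5-base poly-A track in the
linker — embedded in neutral G/C filler that is verified to contain no
further consensus matches.  They give the mutagenesis verifier and the
annotator a deterministic locus with the native site/ACS geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import scan_sites

PROXIMAL_SITE = "TGTTTAT"   # minus-strand Fkh1/2 match (revcomp ATAAACA)
DISTAL_SITE = "GTAAATA"     # plus-strand Fkh1/2 match
NATIVE_GAP = 72
ARS607_ACS = "GTTTATATTTAG"
ARS305_ACS = "TTTATATGTTTT"
ARS305_NATIVE_ACS = "TTTTAATATTT"  # ACS string shared by ARS305/ARS737 native-locus edits


@dataclass(frozen=True)
class LocusModel:
    """A synthetic origin locus with the coordinates of its elements
    (0-based, local to ``seq``)."""

    name: str
    seq: str
    proximal_start: int
    distal_start: int
    acs_offset: int
    acs_seq: str

    @property
    def gap_bp(self) -> int:
        return self.distal_start - (self.proximal_start + 7)


def _filler(n: int, rng: np.random.Generator) -> str:
    # G/C-only filler cannot contribute to the A-rich consensus on either
    # strand, so the planted sites are provably the only matches.
    return "".join(np.array(list("GC"))[rng.integers(0, 2, size=n)])


def _assemble(name: str, length: int, proximal_start: int, acs_offset: int,
              acs_seq: str, linker_inserts: dict[int, str], seed: int) -> LocusModel:
    rng = np.random.default_rng(seed)
    seq = list(_filler(length, rng))
    distal_start = proximal_start + 7 + NATIVE_GAP
    seq[proximal_start:proximal_start + 7] = PROXIMAL_SITE
    seq[distal_start:distal_start + 7] = DISTAL_SITE
    seq[acs_offset:acs_offset + len(acs_seq)] = acs_seq
    for linker_off, insert in linker_inserts.items():
        pos = proximal_start + 7 + linker_off
        seq[pos:pos + len(insert)] = insert
    locus = LocusModel(name, "".join(seq), proximal_start, distal_start,
                       acs_offset, acs_seq)
    sites = scan_sites({name: locus.seq})
    expected = {(proximal_start, "-"), (distal_start, "+")}
    found = {(s.start, s.strand) for s in sites}
    assert found == expected, f"unexpected consensus matches in {name}: {found}"
    return locus


def synthetic_ars607(length: int = 388, proximal_start: int = 150) -> LocusModel:
    """ARS607-style locus: ACS overlapping the proximal Fkh site (the two
    share the GTTTAT hexamer), divergent pair with a 72-bp gap, poly-A track
    mid-linker."""
    return _assemble(
        "ARS607_synthetic", length, proximal_start,
        acs_offset=proximal_start + 1, acs_seq=ARS607_ACS,
        linker_inserts={33: "AAAAA"}, seed=607)


def synthetic_ars305(length: int = 272, proximal_start: int = 100) -> LocusModel:
    """ARS305-style locus: ACS upstream of (close to, not overlapping) the
    proximal Fkh site, divergent pair with a 72-bp gap, poly-A track
    mid-linker."""
    return _assemble(
        "ARS305_synthetic", length, proximal_start,
        acs_offset=proximal_start - 17, acs_seq=ARS305_ACS,
        linker_inserts={33: "AAAAA"}, seed=305)
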