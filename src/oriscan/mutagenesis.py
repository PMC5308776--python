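"""In-silico origin mutagenesis and construct verification.

Applies the classes of edits used to rebuild origins ARS305 and ARS607 in
reporter loci — consensus-site knockout by substitution, site reversal
(replacement by the reverse complement), spacer insertion/deletion between
the two Fkh1/2 sites, and ACS point mutations — and verifies the resulting
construct by re-scanning it: which Fkh1/2 sites were gained or lost, what
pair configuration (orientation, gap) remains, and whether each ACS is
intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .motif import (FKH_CONSENSUS, MotifSite, SitePair, enumerate_pairs,
                    reverse_complement, scan_sites)

EDIT_KINDS = ("replace", "invert", "insert", "delete")


@dataclass(frozen=True)
class EditSpec:
    """One sequence edit at a 0-based construct offset.

    * ``replace``: ``original`` (required, checked in place) -> ``payload``.
    * ``invert``: reverse-complement ``length`` bases in place.
    * ``insert``: insert ``payload`` before ``anchor``.
    * ``delete``: remove ``length`` bases starting at ``anchor``.
    """

    kind: str
    anchor: int
    payload: str = ""
    original: str = ""
    length: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "replace" and not self.original:
            raise ValueError("replace edit requires the expected original sequence")
        if self.kind == "invert" and self.length <= 0:
            raise ValueError("invert edit requires length > 0")
        if self.kind == "insert" and not self.payload:
            raise ValueError("insert edit requires a payload sequence")
        if self.kind == "delete" and self.length <= 0:
            raise ValueError("delete edit requires length > 0")


@dataclass
class ConstructReport:
    """Scan-based verification of an edited construct (construct-local
    coordinates)."""

    edited_seq: str
    sites_before: list[MotifSite]
    sites_after: list[MotifSite]
    pairs_after: list[SitePair]
    acs_intact: dict[str, bool] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"construct length: {len(self.edited_seq)} bp",
            f"Fkh sites before: {len(self.sites_before)}, after: {len(self.sites_after)}",
        ]
        for p in self.pairs_after:
            lines.append(f"pair: {p.orientation}, gap {p.gap_bp} bp, "
                         f"midpoint {p.midpoint}")
        for name, ok in self.acs_intact.items():
            lines.append(f"ACS {name}: {'intact' if ok else 'MUTATED'}")
        return "\n".join(lines)


def apply_edit(seq: str, edit: EditSpec) -> str:
    """Apply one edit, returning a new sequence (pure function).

    A ``replace`` whose expected original is absent at the anchor raises,
    naming the offset and the sequence actually found.
    """
    n = len(seq)
    if not 0 <= edit.anchor <= n:
        raise ValueError(f"anchor {edit.anchor} outside sequence of length {n}")
    if edit.kind == "replace":
        found = seq[edit.anchor:edit.anchor + len(edit.original)]
        if found.upper() != edit.original.upper():
            raise ValueError(
                f"expected {edit.original.upper()!r} at offset {edit.anchor}, "
                f"found {found.upper()!r}")
        return seq[:edit.anchor] + edit.payload + seq[edit.anchor + len(edit.original):]
    if edit.kind == "invert":
        segment = seq[edit.anchor:edit.anchor + edit.length]
        return seq[:edit.anchor] + reverse_complement(segment) + seq[edit.anchor + edit.length:]
    if edit.kind == "insert":
        return seq[:edit.anchor] + edit.payload + seq[edit.anchor:]
    # delete
    if edit.anchor + edit.length > n:
        raise ValueError("deletion extends past end of sequence")
    return seq[:edit.anchor] + seq[edit.anchor + edit.length:]


def apply_edits(seq: str, edits: Sequence[EditSpec]) -> str:
    """Apply edits left to right; each anchor refers to the sequence as it
    stands after the previous edit."""
    for edit in edits:
        seq = apply_edit(seq, edit)
    return seq


def verify_construct(seq: str, edits: Sequence[EditSpec] = (),
                     fkh_pattern: str = FKH_CONSENSUS,
                     acs_refs: Sequence[tuple[str, str]] = (),
                     gap_min: int = 0, gap_max: int = 400) -> ConstructReport:
    """Apply ``edits`` to ``seq`` and verify the resulting construct.

    ``acs_refs`` are (name, wild-type sequence) entries; each ACS is deemed
    intact when its wild-type sequence still occurs in the edited construct
    on either strand (case-insensitive substring search, so edits elsewhere
    in the construct cannot shift it into a false "mutated" call).
    """
    sites_before = scan_sites({"construct": seq}, fkh_pattern)
    edited = apply_edits(seq, edits)
    sites_after = scan_sites({"construct": edited}, fkh_pattern)
    pairs_after = enumerate_pairs(sites_after, gap_min, gap_max)
    upper = edited.upper()
    acs_intact = {
        name: (wt.upper() in upper or reverse_complement(wt.upper()) in upper)
        for name, wt in acs_refs
    }
    return ConstructReport(edited, sites_before, sites_after, pairs_after, acs_intact)
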