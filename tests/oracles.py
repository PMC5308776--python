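"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (own IUPAC
table, own complement map, positional loops / numpy membership tests) and
never calls the scanning or pairing code paths it is used to verify.
"""

from __future__ import annotations

import numpy as np

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "M": {"A", "C"}, "K": {"G", "T"},
    "S": {"C", "G"}, "W": {"A", "T"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

ORACLE_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "M": "K",
    "K": "M", "S": "S", "W": "W", "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


def oracle_revcomp(seq: str) -> str:
    return "".join(ORACLE_COMPLEMENT[c] for c in reversed(seq.upper()))


def oracle_window_match(window: str, pattern: str) -> bool:
    return all(b in ORACLE_IUPAC[p] for b, p in zip(window.upper(), pattern.upper()))


def oracle_scan(genome: dict[str, str], pattern: str) -> list[tuple[str, int, str]]:
    """Position-by-position scan of every window on both strands (pure
    Python; for small genomes)."""
    pattern = pattern.upper()
    rc = oracle_revcomp(pattern)
    k = len(pattern)
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if oracle_window_match(window, pattern):
                hits.append((chrom, i, "+"))
            if oracle_window_match(window, rc):
                hits.append((chrom, i, "-"))
    return sorted(hits)


def oracle_scan_np(genome: dict[str, str], pattern: str) -> list[tuple[str, int, str]]:
    """Vectorised positional matcher for megabase genomes: per pattern
    offset, a numpy membership test of the shifted base array."""
    pattern = pattern.upper()
    k = len(pattern)
    hits = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].upper().encode(), dtype="S1")
        n = len(arr) - k + 1
        if n <= 0:
            continue
        for pat, strand in ((pattern, "+"), (oracle_revcomp(pattern), "-")):
            ok = np.ones(n, dtype=bool)
            for off, sym in enumerate(pat):
                allowed = np.frombuffer("".join(sorted(ORACLE_IUPAC[sym])).encode(), dtype="S1")
                ok &= np.isin(arr[off:off + n], allowed)
            hits.extend((chrom, int(i), strand) for i in np.nonzero(ok)[0])
    return sorted(hits)


def oracle_pairs(hits: list[tuple[str, int, str]], gap_min: int, gap_max: int,
                 k: int = 7) -> list[tuple[str, int, str, int, str]]:
    """All qualifying ordered pairs by exhaustive double loop."""
    out = []
    for i, (c1, s1, st1) in enumerate(hits):
        for c2, s2, st2 in hits:
            if c1 != c2 or s2 <= s1:
                continue
            gap = s2 - (s1 + k)
            if gap_min <= gap <= gap_max:
                out.append((c1, s1, st1, s2, st2))
    return sorted(out)


def oracle_orientation(up_strand: str, down_strand: str) -> str:
    if up_strand == down_strand:
        return "unidirectional"
    return "divergent" if up_strand == "-" else "convergent"


def oracle_colocalization_cells(pair_tuples, peaks, gap_bins, window=200, k=7):
    """(orientation, bin) -> (n_pairs, n_overlapping) by direct loops.

    ``pair_tuples`` as from :func:`oracle_pairs`; ``peaks`` as (chrom,
    peak_pos) tuples.
    """
    cells = {}
    for orientation in ("divergent", "convergent", "unidirectional"):
        for lo, hi in gap_bins:
            n = hit = 0
            for chrom, s1, st1, s2, st2 in pair_tuples:
                if oracle_orientation(st1, st2) != orientation:
                    continue
                gap = s2 - (s1 + k)
                if not lo <= gap <= hi:
                    continue
                n += 1
                mid = (s1 + s2 + k) // 2
                if any(pc == chrom and abs(mid - pp) <= window for pc, pp in peaks):
                    hit += 1
            cells[(orientation, (lo, hi))] = (n, hit)
    return cells


def oracle_a_runs(seq: str, min_len: int) -> list[tuple[int, int, str]]:
    """Maximal A-runs (strand +) and T-runs (strand -) by explicit walk."""
    seq = seq.upper()
    runs = []
    for base, strand in (("A", "+"), ("T", "-")):
        i = 0
        while i < len(seq):
            if seq[i] != base:
                i += 1
                continue
            j = i
            while j < len(seq) and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j - i, strand))
            i = j
    return sorted(runs)


def random_genome(rng: np.random.Generator, lengths: dict[str, int],
                  probs=(0.31, 0.19, 0.19, 0.31), n_frac: float = 0.0) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom, length in lengths.items():
        seq = bases[rng.choice(4, size=length, p=list(probs))]
        if n_frac > 0:
            mask = rng.random(length) < n_frac
            seq[mask] = "N"
        genome[chrom] = "".join(seq)
    return genome
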