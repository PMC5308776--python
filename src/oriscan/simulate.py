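"""Synthetic genomes, replication signals and origin tables with planted truth.

The generator emulates the three inputs of the analysis so every stage is
testable without downloads: an iid AT-skewed genome (yeast-like base
composition, A=T=0.31, C=G=0.19) with planted Fkh1/2 consensus pairs of
chosen orientation and gap, a binned noisy BrdU-in-HU-like signal with
triangular peaks at a chosen subset of planted loci, and a matching
OriDB-style origin table with confirmed/likely/dubious statuses.

What it emulates and what it does not: planted elements are exact consensus
instances drawn uniformly from the degenerate pattern's expansion, the
background is iid (no chromatin structure, repeats, or GC isochores), the
signal is uniform noise plus clean triangular peaks (no array smoothing or
replication gradients).  Chance consensus matches DO arise in the iid
background at roughly the genomic rate, which is intentional — the planted
elements sit in a realistic sea of background pairs.  Each planted element
is, however, insulated: chance matches within ``insulate_bp`` of it are
scrubbed by a minimal base substitution, so a planted locus carries exactly
its intended pair and chance pairs cannot borrow a planted locus's signal
peak.

One seeded generator drives all randomness; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .motif import (CONVERGENT, DIVERGENT, IUPAC_SETS, UNIDIRECTIONAL,
                    FKH_CONSENSUS, reverse_complement)
from .profiles import (CONFIRMED, DUBIOUS, OriginRecord, SignalProfile)

YEAST_BASE_PROBS = (0.31, 0.19, 0.19, 0.31)  # A, C, G, T

#: Concrete T-rich ACS instance planted when an element requests one
#: (drawn from the WTTTAYRTTTW expansion at generation time).
ACS_PATTERN = "WTTTAYRTTTW"


@dataclass(frozen=True)
class PlantedElement:
    """One planted double Fkh1/2 site: upstream match begins at ``pos``."""

    chrom: str
    pos: int
    orientation: str
    gap_bp: int
    with_acs: bool = False
    with_atrack: bool = False
    at_peak: bool = False


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``peak_height`` and ``noise_ceiling`` are in arbitrary enrichment units;
    the defaults give a 10:1 peak-to-noise ratio so planted peaks are
    unambiguous while decoy origins (height midway between the two) exercise
    the per-chromosome threshold rule.
    """

    chrom_lengths: Sequence[int]
    planted: Sequence[PlantedElement] = ()
    base_probs: Sequence[float] = YEAST_BASE_PROBS
    peak_height: float = 10.0
    noise_ceiling: float = 1.0
    bin_size: int = 50
    seed: int = 0
    n_decoys_per_chrom: int = 1
    n_late_per_chrom: int = 2
    n_dubious_per_chrom: int = 1
    origin_halfwidth: int = 150
    ars_length: int = 300
    insulate_bp: int = 250

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.peak_height <= self.noise_ceiling:
            raise ValueError("peak_height must exceed noise_ceiling")
        if not 0 < self.bin_size <= min(self.chrom_lengths):
            raise ValueError("require 0 < bin_size <= min chromosome length")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


def sample_instance(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete sequence uniformly from a degenerate pattern's
    expansion."""
    return "".join(rng.choice(list(IUPAC_SETS[c])) for c in pattern.upper())


def _element_span(e: PlantedElement, motif_len: int = 7) -> tuple[int, int]:
    return e.pos, e.pos + 2 * motif_len + e.gap_bp


def generate_genome(spec: SyntheticSpec,
                    fkh_pattern: str = FKH_CONSENSUS) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the genome and its truth table.

    Planted elements write two concrete consensus instances with the
    requested orientation and inner gap; ``with_acs`` adds a T-rich ACS
    instance at the start of the linker (plus strand), ``with_atrack`` a
    5-base poly-A run at the linker centre.  The truth table also fixes the
    positions of decoy, late and dubious origin loci so the signal and
    origin-table generators agree with it.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    motif_len = len(fkh_pattern)
    names = spec.chrom_names()
    lengths = dict(zip(names, spec.chrom_lengths))
    bases = np.array(list("ACGT"))
    genome = {
        name: "".join(bases[rng.choice(4, size=lengths[name], p=list(spec.base_probs))])
        for name in names
    }

    spans: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    rows = []
    for e in spec.planted:
        if e.chrom not in genome:
            raise ValueError(f"planted element on unknown chromosome {e.chrom!r}")
        lo, hi = _element_span(e, motif_len)
        if hi > lengths[e.chrom]:
            raise ValueError("planted element extends past chromosome end")
        for a, b in spans[e.chrom]:
            if lo < b and a < hi:
                raise ValueError("planted elements overlap")
        spans[e.chrom].append((lo, hi))

        instance_up = sample_instance(fkh_pattern, rng)
        instance_down = sample_instance(fkh_pattern, rng)
        if e.orientation == DIVERGENT:
            up_fwd, up_strand = reverse_complement(instance_up), "-"
            down_fwd, down_strand = instance_down, "+"
        elif e.orientation == CONVERGENT:
            up_fwd, up_strand = instance_up, "+"
            down_fwd, down_strand = reverse_complement(instance_down), "-"
        elif e.orientation == UNIDIRECTIONAL:
            up_fwd, up_strand = instance_up, "+"
            down_fwd, down_strand = instance_down, "+"
        else:
            raise ValueError(f"unknown orientation {e.orientation!r}")

        linker = list(genome[e.chrom][e.pos + motif_len:e.pos + motif_len + e.gap_bp])
        if e.with_acs:
            acs_instance = sample_instance(ACS_PATTERN, rng)
            if len(acs_instance) + 1 > e.gap_bp:
                raise ValueError("gap too small for an ACS")
            linker[1:1 + len(acs_instance)] = acs_instance
        if e.with_atrack:
            centre = e.gap_bp // 2
            if e.gap_bp < 20:
                raise ValueError("gap too small for an A-track")
            linker[centre - 2:centre + 3] = "AAAAA"

        seq = genome[e.chrom]
        down_start = e.pos + motif_len + e.gap_bp
        genome[e.chrom] = (seq[:e.pos] + up_fwd + "".join(linker)
                           + down_fwd + seq[down_start + motif_len:])
        rows.append({
            "kind": "element", "chrom": e.chrom,
            "up_start": e.pos, "up_strand": up_strand,
            "down_start": down_start, "down_strand": down_strand,
            "gap_bp": e.gap_bp, "orientation": e.orientation,
            "midpoint": (e.pos + down_start + motif_len) // 2,
            "with_acs": e.with_acs, "with_atrack": e.with_atrack,
            "at_peak": e.at_peak, "confirmed_origin": e.at_peak,
        })

    if spec.insulate_bp > 0:
        _insulate_elements(genome, spec, rows, spans, fkh_pattern)

    # Decoy / late / dubious origin loci, placed clear of planted elements.
    for name in names:
        occupied = sorted(spans[name])
        for kind, count in (("decoy", spec.n_decoys_per_chrom),
                            ("late", spec.n_late_per_chrom),
                            ("dubious", spec.n_dubious_per_chrom)):
            for _ in range(count):
                pos = _place_locus(rng, lengths[name], occupied,
                                   spec.origin_halfwidth + spec.bin_size)
                occupied.append((pos - spec.origin_halfwidth, pos + spec.origin_halfwidth))
                occupied.sort()
                rows.append({
                    "kind": kind, "chrom": name, "up_start": -1, "up_strand": ".",
                    "down_start": -1, "down_strand": ".", "gap_bp": -1,
                    "orientation": ".", "midpoint": pos,
                    "with_acs": False, "with_atrack": False,
                    "at_peak": kind == "decoy", "confirmed_origin": kind != "dubious",
                })
    truth = pd.DataFrame(rows)
    return genome, truth


def _insulate_elements(genome: dict[str, str], spec: SyntheticSpec,
                       rows: list[dict], spans: dict[str, list[tuple[int, int]]],
                       fkh_pattern: str, max_rounds: int = 50) -> None:
    """Scrub chance consensus matches within ``insulate_bp`` of each planted
    element by a minimal base substitution, leaving planted 7-mers, ACS
    inserts and A-tracks untouched.

    Without insulation, chance matches beside or inside a planted linker
    form pairs whose midpoints inherit the element's signal peak, smearing
    co-localization counts across orientation/gap classes.
    """
    from .motif import MATCH_SETS, _pattern_regex

    k = len(fkh_pattern)
    rc = reverse_complement(fkh_pattern)
    regexes = {"+": _pattern_regex(fkh_pattern), "-": _pattern_regex(rc)}
    offsets = sorted(range(k), key=lambda j: abs(j - k // 2))

    elements = [r for r in rows if r["kind"] == "element"]
    for name in sorted(spans):
        if not spans[name]:
            continue
        seq = list(genome[name])
        zones = [(max(0, lo - spec.insulate_bp), min(len(seq), hi + spec.insulate_bp))
                 for lo, hi in spans[name]]
        intended: set[tuple[int, str]] = set()
        protected: set[int] = set()
        for r in elements:
            if r["chrom"] != name:
                continue
            intended.add((r["up_start"], r["up_strand"]))
            intended.add((r["down_start"], r["down_strand"]))
            protected.update(range(r["up_start"], r["up_start"] + k))
            protected.update(range(r["down_start"], r["down_start"] + k))
            linker_start = r["up_start"] + k
            if r["with_acs"]:
                protected.update(range(linker_start + 1,
                                       linker_start + 1 + len(ACS_PATTERN)))
            if r["with_atrack"]:
                centre = linker_start + r["gap_bp"] // 2
                protected.update(range(centre - 2, centre + 3))
        tolerated: set[tuple[int, str]] = set()
        for _ in range(max_rounds):
            dirty = []
            for lo, hi in zones:
                region = "".join(seq[lo:hi])
                for strand, regex in regexes.items():
                    for m in regex.finditer(region):
                        key = (lo + m.start(), strand)
                        if key not in intended and key not in tolerated:
                            dirty.append(key)
            if not dirty:
                break
            for start, strand in dirty:
                pat = fkh_pattern if strand == "+" else rc
                window = "".join(seq[start:start + k])
                if len(window) < k or not all(b in MATCH_SETS[p]
                                              for b, p in zip(window, pat)):
                    continue  # already fixed by an earlier substitution
                for j in offsets:
                    pos = start + j
                    if pos in protected:
                        continue
                    kill = next((b for b in "CGAT" if b not in MATCH_SETS[pat[j]]),
                                None)
                    if kill is not None:
                        seq[pos] = kill
                        break
                else:
                    tolerated.add((start, strand))
        genome[name] = "".join(seq)


def _place_locus(rng: np.random.Generator, chrom_len: int,
                 occupied: list[tuple[int, int]], halfwidth: int,
                 max_tries: int = 5000) -> int:
    for _ in range(max_tries):
        pos = int(rng.integers(halfwidth, chrom_len - halfwidth))
        if all(not (pos - halfwidth < b and a < pos + halfwidth)
               for a, b in occupied):
            return pos
    raise RuntimeError("could not place origin locus without overlap")


def generate_signal(spec: SyntheticSpec, truth: pd.DataFrame) -> SignalProfile:
    """Binned signal: uniform noise in (0, noise_ceiling], a triangular peak
    of height ``peak_height`` centred at each at-peak element midpoint, and
    decoy bins at height midway between noise ceiling and peak height."""
    rng = np.random.default_rng(spec.seed + 1)
    frames = []
    lengths = dict(zip(spec.chrom_names(), spec.chrom_lengths))
    shoulder = np.array([0.35, 0.7, 1.0, 0.7, 0.35])
    for name in spec.chrom_names():
        n_bins = lengths[name] // spec.bin_size
        starts = np.arange(n_bins) * spec.bin_size
        values = rng.uniform(1e-6, spec.noise_ceiling, size=n_bins)
        sub = truth[truth["chrom"] == name]
        # Bins inside confirmed-origin intervals are excluded from the
        # threshold computation, so damp their noise: otherwise a noise
        # maximum hiding inside an origin could exceed the threshold and be
        # called as a spurious peak.
        for row in sub.itertuples(index=False):
            if not row.confirmed_origin:
                continue
            lo = max(0, (int(row.midpoint) - spec.origin_halfwidth) // spec.bin_size)
            hi = min(n_bins, (int(row.midpoint) + spec.origin_halfwidth) // spec.bin_size + 1)
            values[lo:hi] *= 0.5
        for row in sub.itertuples(index=False):
            centre_bin = int(row.midpoint) // spec.bin_size
            if row.kind == "element" and row.at_peak:
                for off, frac in zip(range(-2, 3), shoulder):
                    b = centre_bin + off
                    if 0 <= b < n_bins:
                        values[b] = max(values[b], spec.peak_height * frac)
            elif row.kind == "decoy":
                values[centre_bin] = (spec.noise_ceiling + spec.peak_height) / 2
        frames.append(pd.DataFrame({
            "chrom": name, "start": starts,
            "end": starts + spec.bin_size, "value": values,
        }))
    return SignalProfile(pd.concat(frames, ignore_index=True))


def generate_origin_table(spec: SyntheticSpec, truth: pd.DataFrame) -> list[OriginRecord]:
    """OriDB-style records matching the truth table: confirmed origins at
    at-peak elements and decoys, quiet confirmed origins (the late set,
    ARS length within the 600-bp late-origin filter), and dubious records
    to exercise status filtering."""
    records = []
    counter = 0
    for row in truth.itertuples(index=False):
        if row.kind == "element" and not row.at_peak:
            continue
        counter += 1
        status = DUBIOUS if row.kind == "dubious" else CONFIRMED
        mid = int(row.midpoint)
        records.append(OriginRecord(
            chrom=row.chrom, start=max(0, mid - spec.origin_halfwidth),
            end=mid + spec.origin_halfwidth, name=f"synth_{row.kind}_{counter}",
            status=status, ars_length=spec.ars_length))
    return records


@dataclass
class SyntheticDataset:
    """A matched genome / signal / origin-table triple with its truth."""

    spec: SyntheticSpec
    genome: dict[str, str]
    truth: pd.DataFrame
    profile: SignalProfile
    origins: list[OriginRecord]


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full matched triple for a spec."""
    genome, truth = generate_genome(spec)
    profile = generate_signal(spec, truth)
    origins = generate_origin_table(spec, truth)
    return SyntheticDataset(spec, genome, truth, profile, origins)


def random_study_spec(seed: int, n_chroms: int = 4, chrom_length: int = 60_000,
                      n_per_class: int = 20, at_peak_fraction: float = 0.3,
                      divergent_boost: float = 1.0,
                      gap_choices: Sequence[int] = tuple(range(62, 89))) -> SyntheticSpec:
    """Build a study spec with planted pairs spread over orientation and gap
    classes.

    ``at_peak_fraction`` of each class is placed at signal peaks;
    ``divergent_boost`` multiplies that fraction for divergent pairs with
    gaps of 71-79 bp (set to 3.0 to emulate the early-origin enrichment of
    that configuration).
    """
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    planted: list[PlantedElement] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    classes = [(o, lo, hi) for o in (DIVERGENT, CONVERGENT, UNIDIRECTIONAL)
               for lo, hi in ((62, 70), (71, 79), (80, 88))]
    for orientation, lo, hi in classes:
        frac = at_peak_fraction
        if orientation == DIVERGENT and (lo, hi) == (71, 79):
            frac = min(1.0, at_peak_fraction * divergent_boost)
        n_at_peak = round(n_per_class * frac)
        for i in range(n_per_class):
            gap = int(rng.choice([g for g in gap_choices if lo <= g <= hi]))
            chrom = names[int(rng.integers(n_chroms))]
            span = 2 * 7 + gap
            pos = _place_locus(rng, chrom_length, occupied[chrom], span // 2 + 300)
            occupied[chrom].append((pos - span // 2 - 300, pos + span // 2 + 300))
            planted.append(PlantedElement(
                chrom=chrom, pos=pos, orientation=orientation, gap_bp=gap,
                with_acs=bool(rng.integers(2)), with_atrack=bool(rng.integers(2)),
                at_peak=i < n_at_peak))
    return SyntheticSpec(chrom_lengths=[chrom_length] * n_chroms,
                         planted=planted, seed=seed)
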