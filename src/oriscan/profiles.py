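"""Replication-initiation signal handling and early/late origin calling.

The early-origin caller reproduces a simple per-chromosome threshold rule on
a BrdU-incorporation-in-hydroxyurea (HU) profile: HU stalls replication so
only early-firing origins incorporate BrdU.  On each chromosome the
threshold is the highest signal value that does not overlap any confirmed
replication origin (from an OriDB-style table); every contiguous
above-threshold run is then called as one early origin, with the peak placed
at the midpoint of the run's maximum-valued interval.  Late origins are
confirmed origins with a defined ARS no longer than 600 bp that contain no
called peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONFIRMED = "confirmed"
LIKELY = "likely"
DUBIOUS = "dubious"


@dataclass(frozen=True)
class OriginRecord:
    """One OriDB-style origin: 0-based half-open interval with a curation
    status and the length of the defined ARS element (bp)."""

    chrom: str
    start: int
    end: int
    name: str
    status: str
    ars_length: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"origin {self.name}: end <= start")


@dataclass(frozen=True)
class EarlyOriginPeak:
    """A called early origin: one contiguous above-threshold signal run and
    the position of its maximum."""

    chrom: str
    run_start: int
    run_end: int
    peak_pos: int
    peak_value: float
    threshold_used: float


@dataclass
class SignalProfile:
    """Per-chromosome stepwise genomic signal (sorted, non-overlapping
    0-based half-open intervals with non-negative finite values)."""

    data: pd.DataFrame  # columns: chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.data[["chrom", "start", "end", "value"]].copy()
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise ValueError("signal interval with end <= start")
        if not np.isfinite(df["value"]).all() or (df["value"] < 0).any():
            raise ValueError("signal values must be finite and >= 0")
        prev_end = df.groupby("chrom")["end"].shift()
        if (df["start"] < prev_end.fillna(-1)).any():
            raise ValueError("overlapping signal intervals")
        self.data = df

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data["chrom"].unique())

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom].reset_index(drop=True)


def read_signal(path: str | Path, format: str | None = None) -> SignalProfile:
    """Read a bedGraph or fixed-step WIG file into a SignalProfile.

    Format is inferred from the extension when not given (.wig -> wig, else
    bedgraph).  WIG positions are 1-based per that format's convention and
    are converted to 0-based half-open intervals.
    """
    path = Path(path)
    if format is None:
        format = "wig" if path.suffix.lower() == ".wig" else "bedgraph"
    if format == "bedgraph":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{i}: expected 4 bedGraph columns")
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    elif format == "wig":
        df = _read_fixedstep_wig(path)
    else:
        raise ValueError(f"unknown signal format {format!r}")
    return SignalProfile(df)


def _read_fixedstep_wig(path: Path) -> pd.DataFrame:
    rows = []
    chrom, pos, step, span = None, 0, None, None
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}:{i}: only fixedStep WIG is supported")
            if chrom is None:
                raise ValueError(f"{path}:{i}: data before fixedStep header")
            rows.append((chrom, pos, pos + span, float(line)))
            pos += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(profile: SignalProfile, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in profile.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_origin_table(path: str | Path) -> list[OriginRecord]:
    """Read an origin table TSV with columns chrom, start, end, name,
    status, ars_length (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        OriginRecord(str(r.chrom), int(r.start), int(r.end), str(r.name),
                     str(r.status), int(r.ars_length))
        for r in df.itertuples(index=False)
    ]


def write_origin_table(origins: Iterable[OriginRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(o) for o in origins])
    df.to_csv(path, sep="\t", index=False)


def chromosome_threshold(intervals: pd.DataFrame, confirmed: Sequence[OriginRecord]) -> float:
    """Highest signal value among intervals that do not overlap any
    confirmed origin on the chromosome.

    With no confirmed origins the threshold is the chromosome's global
    maximum (hence no peak can be called there); if every interval overlaps
    an origin the threshold degenerates to 0 with a warning.
    """
    if len(intervals) == 0:
        raise ValueError("empty signal for chromosome")
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    free = np.ones(len(intervals), dtype=bool)
    for o in confirmed:
        if o.status == CONFIRMED:
            free &= ~((starts < o.end) & (ends > o.start))
    if not free.any():
        warnings.warn("all signal intervals overlap confirmed origins; threshold set to 0")
        return 0.0
    return float(intervals["value"].to_numpy()[free].max())


def call_early_peaks(profile: SignalProfile, origins: Sequence[OriginRecord]) -> list[EarlyOriginPeak]:
    """Call early origins chromosome by chromosome.

    A peak is one maximal run of genomically contiguous intervals with value
    strictly above the chromosome threshold; the peak position is the
    midpoint of the run's maximum-valued interval (ties broken leftmost).
    Runs are never merged across below-threshold or missing-data gaps.
    """
    peaks: list[EarlyOriginPeak] = []
    for chrom in profile.chroms:
        iv = profile.chromosome(chrom)
        conf = [o for o in origins if o.chrom == chrom and o.status == CONFIRMED]
        thr = chromosome_threshold(iv, conf)
        above = iv["value"].to_numpy() > thr
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        values = iv["value"].to_numpy()
        i, n = 0, len(iv)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1] and starts[j + 1] == ends[j]:
                j += 1
            k = i + int(np.argmax(values[i:j + 1]))
            peaks.append(EarlyOriginPeak(
                chrom=chrom, run_start=int(starts[i]), run_end=int(ends[j]),
                peak_pos=int((starts[k] + ends[k]) // 2),
                peak_value=float(values[k]), threshold_used=thr))
            i = j + 1
    return peaks


def select_late_origins(origins: Sequence[OriginRecord], peaks: Sequence[EarlyOriginPeak],
                        max_ars_len: int = 600) -> list[OriginRecord]:
    """Confirmed origins with ARS length <= ``max_ars_len`` whose interval
    contains no called early peak position."""
    peak_by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        peak_by_chrom.setdefault(p.chrom, []).append(p.peak_pos)
    late = []
    for o in origins:
        if o.status != CONFIRMED or o.ars_length > max_ars_len:
            continue
        if any(o.start <= pos < o.end for pos in peak_by_chrom.get(o.chrom, ())):
            continue
        late.append(o)
    return late
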