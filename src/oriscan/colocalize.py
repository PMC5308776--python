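"""Co-localization of paired Fkh1/2 sites with replication origins.

A double site co-localizes with an early origin when its midpoint lies
within a fixed window (default 200 bp) of a called BrdU peak maximum.  The
co-localization table stratifies pairs by orientation class and inner-gap
bin and reports the percentage overlapping; the background rate is the
average overlap frequency of pairs of scrambled consensus variants
(YAAYMAR, MAARYAY, AAYMYAR; all orientations; 50-100 bp gaps), which share
the symbol multiset of RYMAAYA and hence its expected hit frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import (CONVERGENT, DIVERGENT, UNIDIRECTIONAL, SitePair,
                    enumerate_pairs, scan_sites, scrambled_patterns)
from .profiles import EarlyOriginPeak, OriginRecord

ORIENTATIONS = (DIVERGENT, CONVERGENT, UNIDIRECTIONAL)
DEFAULT_GAP_BINS = ((62, 70), (71, 79), (80, 88))


@dataclass(frozen=True)
class BackgroundEstimate:
    """Overlap fraction per (scrambled pattern, orientation) and their mean.

    Combinations with no pairs are missing (NaN) and excluded from the mean;
    a genome with no scramble pairs at all yields mean 0 with a warning.
    """

    components: Mapping[tuple[str, str], float]
    mean: float

    def as_frame(self) -> pd.DataFrame:
        rows = [{"pattern": p, "orientation": o, "fraction": f}
                for (p, o), f in self.components.items()]
        return pd.DataFrame(rows)


def overlaps_peak(chrom: str, midpoint: int, peaks: Sequence[EarlyOriginPeak],
                  window: int = 200) -> bool:
    """True iff some same-chromosome peak maximum lies within ``window`` bp
    of ``midpoint`` (boundary inclusive)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    return any(p.chrom == chrom and abs(midpoint - p.peak_pos) <= window
               for p in peaks)


def _table(pairs: Sequence[SitePair], hit: Sequence[bool],
           gap_bins: Sequence[tuple[int, int]]) -> pd.DataFrame:
    rows = []
    for orientation in ORIENTATIONS:
        for lo, hi in gap_bins:
            sel = [h for p, h in zip(pairs, hit)
                   if p.orientation == orientation and lo <= p.gap_bp <= hi]
            n, k = len(sel), sum(sel)
            rows.append({
                "orientation": orientation, "gap_bin": f"{lo}-{hi}",
                "n_pairs": n, "n_overlapping": k,
                "percent": round(100.0 * k / n, 1) if n else np.nan,
            })
    return pd.DataFrame(rows)


def colocalization_table(pairs: Sequence[SitePair], peaks: Sequence[EarlyOriginPeak],
                         gap_bins: Sequence[tuple[int, int]] = DEFAULT_GAP_BINS,
                         window: int = 200) -> pd.DataFrame:
    """One row per orientation x gap bin: pair count, overlapping count, and
    percentage co-localizing with early-origin peaks.

    A pair is assigned to every bin containing its gap and counts once even
    if it lies near two peaks.  Empty cells report a missing percentage.
    """
    hit = [overlaps_peak(p.chrom, p.midpoint, peaks, window) for p in pairs]
    return _table(pairs, hit, gap_bins)


def late_origin_table(pairs: Sequence[SitePair], late_origins: Sequence[OriginRecord],
                      gap_bins: Sequence[tuple[int, int]] = DEFAULT_GAP_BINS,
                      window: int = 200, mode: str = "midpoint") -> pd.DataFrame:
    """Co-localization of pairs with late origins, computed as for early
    origins but against origin intervals.

    ``mode="midpoint"`` (default) measures distance to the origin interval
    midpoint with the same window; ``mode="containment"`` counts a pair when
    its midpoint falls inside the origin interval.
    """
    if mode not in ("midpoint", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    hit = []
    for p in pairs:
        ok = False
        for o in late_origins:
            if o.chrom != p.chrom:
                continue
            if mode == "midpoint":
                ok = abs(p.midpoint - (o.start + o.end) // 2) <= window
            else:
                ok = o.start <= p.midpoint < o.end
            if ok:
                break
        hit.append(ok)
    return _table(pairs, hit, gap_bins)


def background_rate(genome: Mapping[str, str], peaks: Sequence[EarlyOriginPeak],
                    gap_min: int = 50, gap_max: int = 100,
                    window: int = 200) -> BackgroundEstimate:
    """Average overlap frequency of scrambled-consensus double sites with
    early-origin peaks.

    Each of the three scrambled patterns is scanned and paired (gap in
    [gap_min, gap_max], all orientations); the mean of the per-(pattern,
    orientation) overlap fractions is the background.
    """
    components: dict[tuple[str, str], float] = {}
    for pattern in scrambled_patterns():
        sites = scan_sites(genome, pattern)
        pairs = enumerate_pairs(sites, gap_min, gap_max)
        for orientation in ORIENTATIONS:
            sub = [p for p in pairs if p.orientation == orientation]
            if not sub:
                components[(pattern, orientation)] = float("nan")
                continue
            k = sum(overlaps_peak(p.chrom, p.midpoint, peaks, window) for p in sub)
            components[(pattern, orientation)] = k / len(sub)
    values = [v for v in components.values() if not np.isnan(v)]
    if not values:
        warnings.warn("no scrambled-pattern pairs found; background set to 0")
        return BackgroundEstimate(components, 0.0)
    return BackgroundEstimate(components, float(np.mean(values)))


def plot_colocalization(table: pd.DataFrame, background_percent: float | None = None,
                        path: str | None = None):
    """Bar plot of percent co-localizing per gap bin, one panel per
    orientation, with an optional dashed background line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orientations = [o for o in ORIENTATIONS if o in set(table["orientation"])]
    fig, axes = plt.subplots(1, len(orientations), figsize=(4 * len(orientations), 3),
                             sharey=True, squeeze=False)
    for ax, orientation in zip(axes[0], orientations):
        sub = table[table["orientation"] == orientation]
        ax.bar(sub["gap_bin"], sub["percent"].fillna(0.0), color="steelblue")
        if background_percent is not None:
            ax.axhline(background_percent, ls="--", color="black", lw=1)
        ax.set_title(orientation)
        ax.set_xlabel("gap (bp)")
    axes[0][0].set_ylabel("% co-localizing")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
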