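"""Shared study conditions for the numbered analysis drivers.

One seeded synthetic study stands in for the genome + BrdU-in-HU profile +
origin table triple; every driver works from the same dataset so their
outputs compose.  Large intermediates (FASTA, bedGraph) are cached under
scratch/; the small summary tables the drivers produce go to results/.
"""

from __future__ import annotations

from pathlib import Path

from oriscan.simulate import SyntheticDataset, generate_dataset, random_study_spec

STUDY_SEED = 1
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def study_dataset() -> SyntheticDataset:
    """The study dataset: 4 x 60 kb chromosomes, 180 planted double sites
    (20 per orientation x gap class), threefold peak placement for
    divergent 71-79 bp pairs."""
    spec = random_study_spec(seed=STUDY_SEED, at_peak_fraction=0.3,
                             divergent_boost=3.0)
    return generate_dataset(spec)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
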