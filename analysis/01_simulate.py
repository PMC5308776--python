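"""Generate the synthetic study inputs: genome, replication signal, origin table.

Writes the full triple (plus the planted-truth table) under scratch/sim/ so
the later drivers — and anyone wanting to rerun a stage by hand with the
`oriscan` CLI — can work from files rather than in-memory objects.
"""

from common import SCRATCH, ensure_dirs, study_dataset
from oriscan.io import write_fasta
from oriscan.profiles import write_bedgraph, write_origin_table

ensure_dirs()
ds = study_dataset()

write_fasta(ds.genome, SCRATCH / "genome.fa")
write_bedgraph(ds.profile, SCRATCH / "signal.bedgraph",
               header=f"synthetic BrdU-in-HU-like profile, seed={ds.spec.seed}")
write_origin_table(ds.origins, SCRATCH / "origins.tsv")
ds.truth.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)

elements = ds.truth[ds.truth.kind == "element"]
print(f"genome: {len(ds.genome)} chromosomes, "
      f"{sum(map(len, ds.genome.values())):,} bp total")
print(f"planted double Fkh1/2 sites: {len(elements)} "
      f"({int(elements.at_peak.sum())} at signal peaks)")
print(f"origin table: {len(ds.origins)} records")
print(f"wrote genome.fa / signal.bedgraph / origins.tsv / truth.tsv -> {SCRATCH}")
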