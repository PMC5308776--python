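# Methods

`oriscan` implements a genome-scale analysis of paired Forkhead (Fkh1/2)
consensus binding sites at budding-yeast DNA replication origins, together
with the synthetic data needed to validate every stage without external
downloads. This note records the model, the conventions and defaults, the
genuinely open design choices and how they were resolved, and what the
synthetic validation does and does not establish.

## Motif model

The Fkh1/2 binding site is the degenerate 7-mer consensus **RYMAAYA**
(IUPAC codes: R = A/G, Y = C/T, M = A/C). Matching is exact against the
degenerate consensus — no position-weight-matrix scoring — because the
downstream analysis is a census of consensus occurrences, not an affinity
ranking. Both strands are scanned: a site on the minus strand is a
forward-strand window matching the reverse complement of the pattern
(TRTTKRY). Conventions:

* Coordinates are 0-based, half-open throughout the library; BED output is
  0-based half-open, WIG input is treated as 1-based per that format.
* `N` never matches, on either side of the comparison, so assembly gaps
  cannot create sites. Matching is case-insensitive (soft-masking is
  ignored; no masking rule is part of the model).
* All matches are reported, including partially overlapping ("doubled")
  sites, and every qualifying pair is counted individually. A post-hoc
  collapse utility (`collapse_pairs`: same chromosome and orientation,
  midpoints within 7 bp) is available but off by default, because doubled
  sites are a real architectural feature of several early origins; the pair
  census reports raw and collapsed counts side by side.

## Pair geometry

Two same-chromosome sites with the upstream match starting strictly before
the downstream one form a pair when their **inner gap** — bases strictly
between the two 7-mers, `down.start − (up.start + 7)` — lies in the
configured window (default 62–88 bp, with 71–79 bp as the highlighted bin).
The inner-edge definition is adopted because it is the one consistent with
the ~70–80 bp Mcm2-7 double-hexamer footprint that the 71–79 bp spacing
mirrors. Orientation is fixed by the strand combination:

| upstream | downstream | class |
|---|---|---|
| − | + | divergent ("head-to-head") |
| + | − | convergent ("tail-to-tail") |
| same | same | unidirectional ("head-to-tail") |

The mapping is anchored to the native ARS305/ARS607 configuration
(upstream TGTTTAT = minus-strand match, downstream GTAAATA = plus-strand
match, gap 72 bp → divergent; reversing both sites → convergent). The pair
midpoint is `floor((up.start + down.start + 7)/2)`. Any third site lying
between the paired sites is ignored — only the gap constraint applies — and
one site may belong to several pairs.

## Early-origin calling

The replication-initiation profile (a BrdU-incorporation-in-hydroxyurea
signal, in which only early-firing origins label) is consumed as published
interval values — bedGraph or fixed-step WIG — with no re-normalization or
smoothing. Per chromosome:

1. **Threshold** = the highest signal value among intervals with zero
   overlap with any *confirmed*-status origin from the OriDB-style table.
   With no confirmed origins on a chromosome the threshold equals the
   global maximum (so nothing is called there); if every interval overlaps
   an origin the threshold degenerates to 0 with a warning. Likely/dubious
   records never mask signal (configurable in principle, confirmed-only by
   default).
2. **Peaks** = maximal runs of genomically contiguous intervals with value
   strictly above the threshold. Runs are never merged across
   below-threshold intervals, and additionally break where consecutive
   intervals are not adjacent (end ≠ next start), since bedGraph files may
   omit zero-coverage stretches. The peak position is the midpoint of the
   run's maximum-valued interval, ties broken leftmost — the rule needs a
   point and the interval midpoint is the symmetric choice.

**Late origins** are confirmed records with a defined ARS no longer than
600 bp whose interval contains no called peak position.

## Co-localization and background

A pair co-localizes with an early origin when its midpoint lies within
200 bp (boundary inclusive) of a peak maximum; a pair near two peaks counts
once. The table stratifies by orientation × gap bin (defaults 62–70, 71–79,
80–88; bins are configurable and may overlap, a pair entering every bin
containing its gap), reporting counts alongside percentages rounded to one
decimal so nothing is lost to rounding. Empty cells report a missing
percentage rather than 0.

The background is the average overlap frequency of double sites of the
three scrambled consensus variants **YAAYMAR, MAARYAY, AAYMYAR** — each a
permutation of the RYMAAYA symbol multiset, hence with identical expected
hit frequency under any iid base model — paired at 50–100 bp gaps in all
three orientations. The mean is taken over the 9 (pattern, orientation)
fractions; combinations with no pairs are reported missing and excluded,
and a genome with no scramble pairs at all yields background 0 with a
warning.

Late-origin co-localization is computed identically, with the origin
*interval midpoint* as the reference point under the same 200 bp window
(the analysis needs a point and this parallels the early-origin rule);
containment-in-interval is available as an alternative switch.

## Origin architecture

For a locus sequence the annotator composes the scanner, the pair
enumerator, ACS location and poly-A track detection:

* **ACS** (ARS consensus sequence, the ~11-bp T-rich ORC-binding element).
  Explicit user-supplied coordinates are the primary path and are verified
  and echoed. The fallback is a degenerate search with **WTTTAYRTTTW**
  allowing up to 2 substitutions on either strand (ties: leftmost, then
  plus strand). The mismatch budget of 2 reflects that functional ACSs are
  only loosely consensus-like — the ARS305/ARS737 element TTTTAATATTT
  itself sits 2 substitutions from the best canonical window. The ACS
  strand is the strand on which the element reads T-rich.
* **Proximity**: `acs_within_100bp` is true when the edge-to-edge distance
  from the ACS to the nearer Fkh site is ≤ 100 bp, overlap counting as 0.
* **Strand relation**: the ACS-proximal Fkh site is the one at smaller edge
  distance; the complementarity flag is true when its strand differs from
  the ACS T-rich strand (consensus on the A-rich strand, ACS on the T-rich
  strand).
* **Poly-A tracks** (a DNA-unwinding-element-like signature): maximal runs
  of A (plus strand) or T (minus strand, i.e. A on the complement) in the
  inter-site linker — bases strictly between the two 7-mers. The signature
  is true iff the linker has at least one maximal track of ≥ 5 bases or at
  least two of ≥ 4.
* **Doubled site**: any further consensus match overlapping either paired
  site by ≥ 1 bp.

When several pairs qualify, the leftmost is annotated; all fields are
null-safe when no pair or no ACS exists. No multiple alignment of origins
is produced — each locus is annotated independently and features are
tabulated.

## Construct mutagenesis

`apply_edit`/`verify_construct` implement the four edit classes used to
rebuild ARS305/ARS607 in reporter loci: checked replacement (fails loudly
if the expected original is absent at the anchor), in-place inversion
(identically reverse complementation, an involution), insertion and
deletion. Verification re-scans the edited construct for sites and pairs
and checks each named ACS by case-insensitive substring search on either
strand — deliberately not at a fixed offset, so spacer edits elsewhere in
the construct cannot shift a wild-type ACS into a false "mutated" call.
Lower-case letters in mutation strings (e.g. GTTTATATccAG) are just
substituted-base markup; comparison is case-insensitive.

The ARS607/ARS305 loci used by the examples and the construct panel are
**synthetic reconstructions** (`oriscan.example_loci`): the documented
elements — proximal TGTTTAT (minus strand), distal GTAAATA (plus strand),
72-bp inner gap, the locus-specific ACS string (GTTTATATTTAG overlapping
the proximal site at ARS607 via their shared GTTTAT hexamer; TTTATATGTTTT
upstream of the proximal site at ARS305), a 5-base poly-A linker track —
embedded in G/C filler that provably contributes no further consensus
matches (asserted at construction). They reproduce the native site/ACS
geometry exactly but are not the genomic sequences.

## Synthetic data

The generator emulates the analysis's three inputs with planted truth:

* **Genome**: iid bases at yeast-like composition (A = T = 0.31,
  C = G = 0.19). Planted elements write two concrete consensus instances —
  drawn uniformly from the pattern's expansion, so tests also exercise
  degenerate matching — at the requested orientation and gap; options add a
  T-rich ACS instance at the linker start and/or a 5-base poly-A track at
  the linker centre. Chance consensus matches arise in the background at
  the genomic rate (~0.2% of positions per strand), which is intentional:
  planted pairs sit in a realistic sea of background pairs. Each element
  is, however, **insulated**: chance matches within 250 bp (default) are
  scrubbed by a minimal base substitution, because a chance site beside or
  inside a planted linker forms pairs whose midpoints inherit the planted
  locus's signal peak and smear co-localization counts across every
  orientation/gap class.
* **Signal**: binned values (50 bp bins), uniform noise in (0, 1], a
  triangular peak of height 10 (shoulders 0.7 and 0.35 of the height) at
  each at-peak element midpoint, and single-bin decoy origins at height 5.5
  — above the noise ceiling but below the peaks — covered by confirmed
  origin records so the threshold rule is genuinely exercised. Noise inside
  confirmed-origin intervals is halved so that a noise maximum hiding where
  the threshold cannot see it is never called as a spurious peak.
* **Origin table**: confirmed records (ARS length 300 bp, interval ±150 bp)
  at at-peak elements and decoys, quiet confirmed records forming the late
  set, and dubious records to exercise status filtering.

One seeded generator (numpy PCG64) drives all randomness; identical seeds
give byte-identical outputs.

**Study conditions.** The standard study (`random_study_spec`) plants 20
pairs in each of the 9 orientation × gap-bin classes across 4 × 60 kb
chromosomes, places 30% of each class at signal peaks, and triples that
rate (to 90%) for divergent 71–79 bp pairs — the scaled-down analogue of
the empirical enrichment in which that configuration co-localizes with
early origins roughly three times more often than any other. The base
co-localization rate is far above the genome-scale ~3% so that per-cell
counts are statistically stable at desk scale; the enrichment *ratio*, not
the absolute rate, is the recovered quantity. The acceptance checks pool
counts over 10 seeded replicates, where the observed ratio concentrates
near 2.8–3.0.

**What passing tests show — and don't.** Exact planted-truth recovery and
dual-route (regex scanner vs independent positional matcher, library
pairing vs exhaustive loops) equality establish the correctness of the
machinery. They do not establish anything about real chromatin: the
synthetic genome has no repeats, GC isochores, nucleosome structure or
replication gradients, the signal has no array smoothing or copy-number
trend, and planted insulation removes precisely the motif clustering that
real genomes do contain. Genome-scale census numbers (total sites, total
62–88 bp pairs) therefore have no synthetic counterpart here and require
the real reference genome and a published replication profile as inputs to
the same pipeline.

## Numerical and degenerate-input choices

* Thresholding uses strict inequality (`value > threshold`): the
  threshold-setting interval itself can never be part of a peak.
* Tie-breaks everywhere are deterministic and leftmost (run maxima, ACS
  hits), with plus strand preferred at equal position.
* Signal values must be finite and ≥ 0; overlapping signal intervals are a
  hard error, as are inverted intervals and unknown edit kinds.
* `enumerate_pairs` requires `0 ≤ gap_min ≤ gap_max`; sites at identical
  starts (palindromic-compatible double sites) never pair with each other.
* Percentages are reported to one decimal; counts are always carried
  alongside.
* The mitochondrial genome and episomes are excluded by default in the
  pipeline (`exclude_chroms`), configurable.

## Problem sizes

Desk-scale validation uses genomes of 0.24–2 Mb: 200 random genomes up to
10 kb for scanner/oracle equivalence, a 2-Mb genome with 60 planted
elements for exact end-to-end truth recovery, 0.6-Mb genomes for scramble
neutrality, and 10 × 0.24-Mb replicates for enrichment-shape recovery.
These sizes make every property checkable exactly (integer-for-integer
against independent oracles) while keeping the full suite and the
acceptance script fast; the pipeline itself is linear in genome size and
runs a 12-Mb genome without modification.

## Known limitations

* Exact degenerate matching only; no PWM scoring, no motif discovery, no
  ChIP-peak assignment.
* The early-origin caller implements the threshold rule only — no
  model-based replication-timing inference.
* The ACS pattern fallback is a heuristic; explicit coordinates are the
  intended path when the ACS is known.
* No formal enrichment p-values: the scrambled-pattern background is the
  only null model, by design.
* The late-origin overlap reference point (interval midpoint) is a modeling
  choice; containment mode is provided for sensitivity analysis.
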