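# Methods

This note records the models, conventions and numerical choices behind
`mitolepi`, and what its tests do and do not demonstrate.

## Coordinate and strand conventions

All coordinates are 1-based and inclusive on the forward strand — the
majority (J) strand that carries most genes — matching GenBank and the way
mitogenome annotation tables are printed.  Minority-strand ("R") features
are stored in forward coordinates; `feature_sequence` reverse-complements
on extraction so gene sequences always read 5′→3′ on the coding strand.
Features spanning the origin are rejected: insect mitogenomes are
conventionally linearised at trnM, so no annotated feature crosses the
join, and supporting wrap-spanning spans would complicate every downstream
computation for a case that does not occur.

The declared "Size" and "Intergenic Nucleotides" columns of an annotation
table are treated as assertions to cross-check, never as inputs: every
reported size is `end − start + 1`, and every junction value is
`start(downstream) − end(upstream) − 1`, computed on the circle for the
wrapping pair.  The packaged *H. persimilis* and *H. nama* tables are
transcribed verbatim, typos included; the validator surfaces exactly three
(one declared size off by one, two anticodon positions outside their
genes).  Same-strand protein-gene overlaps of ≤ 10 bp are *not* flagged:
the 7 bp atp8/atp6 and 1 bp atp6/cox3 overlaps are canonical mitochondrial
size economization (the former carrying the conserved ATGATAA motif), not
annotation errors.  The threshold is a parameter.

## Junction ledger

Each adjacent feature pair contributes one signed value: positive =
intergenic spacer, negative = overlap, zero = abutting.  The telescoping
identity Σ sizes + Σ signed values = genome length holds on every valid
circular annotation and is property-tested on random tilings.  Summary
statistics exclude the control region's two junctions: the control region
is itself the largest non-coding stretch, and only under this reading do
the published spacer counts (12 totalling 150 bp; 11 totalling 118 bp)
emerge from the printed coordinates.  Junction motif searches are exact
matches on the forward strand of the window (spacer, or overlap stretch);
reverse-strand search is an explicit flag.

## Codon usage

The genetic code is NCBI table 5 (invertebrate mitochondrial: ATA = Met,
TGA = Trp, AGA/AGG = Ser), built from Biopython's table rather than
hard-coded.  Synonymous families follow the mitogenome-plot convention:
Leu1 (CUN) and Leu2 (UUR), Ser1 (AGN) and Ser2 (UCN); stop codons belong
to no family.

Counting convention (both toggles exposed): start codons are included and
stop codons excluded by default.  Truncated stops — a trailing T or TA
completed to TAA by transcript polyadenylation — are never counted as
codons.  The non-ATN cox1 initiator CGA is counted in the codon total but
excluded from the Arg family: it is an initiation signal, not an arginine,
and including it would distort a family that may otherwise be empty.
Consequently Σ CDspT falls short of 1000 by (excluded starts)/total —
about 0.3 per mille here — which the tests bound explicitly.  Published
codon totals for these genomes (3703/3709) are not derivable from the
printed gene lengths under any single start/stop convention (Σ ⌊size/3⌋
alone is 3740), so totals are reported under the documented convention and
never asserted against those figures.

RSCU(c) = count(c)·|family|/Σ family counts; a family with zero usable
count yields undefined (None) RSCU rather than 0, distinguishing "unused
codon in a used family" from "unused family".

## Control region dissection

The region is read on the J strand from its rrnS-proximal boundary, which
is how the four conserved structures are described: ATAGA origin motif,
poly-T immediately after it, an (AT)n microsatellite and a tandem-repeated
unit in the interior, poly-A abutting trnM.  The adjacency window (how far
after the motif the poly-T may start, and how far before trnM the poly-A
may end) defaults to 10 bp — the conserved-structure descriptions give no
exact linker lengths, so this is deliberately loose and configurable.
Poly-runs are perfect runs (a single interruption terminates them) with a
minimum reportable length of 5 bp.

**Microsatellites** are maximal non-overlapping perfect runs, scanned
left-greedily per motif; phase-shifted motifs (AT vs TA) that overlap are
resolved in favour of the longer run.

**Tandem repeats** are found by comparing the sequence against itself
shifted by each candidate unit length p (2–50 by default): an array
accretes copies while each copy matches the previous one at ≥ 85% of its p
positions, a trailing partial copy contributes its exactly-matching prefix
as a fraction, and arrays must reach 1.9 copies.  Two definitional
refinements matter:

* *Anchoring.* An array must start on a position that matches its
  p-shifted partner.  Without this, a candidate shifted left into the
  flank absorbs up to ⌊(1−identity)·p⌋ mismatching flank bases, and under
  the copies×length scoring such candidates always outrank the exactly
  phased call, diluting both the reported boundary and the identity.
  Anchoring mirrors how alignment-based finders trim array boundaries and
  makes plant-and-recover exact whenever the flanks genuinely differ.
* *Low-complexity filtering at dissection time.* The raw scanner reports
  whatever meets the thresholds; the dissector then drops arrays whose
  consensus unit is itself a repetition with period below the minimum unit
  (homopolymers, (AT)n echoes at even unit lengths) and arrays nested
  inside a reported microsatellite.  AT-rich sequence intrinsically
  carries short-period near-repeats — at 90% AT two positions a fixed lag
  apart match with probability ≈ 0.41, so unit-5..9 arrays at 85% identity
  arise by chance in a few hundred bases — and these are reported honestly
  rather than suppressed; only units ≥ 10 bp are rare enough to be
  meaningful calls, which is why the generator sanitises its filler
  against them (below).

Overlapping calls are resolved by highest copies × unit length, ties to
the smaller unit, then the earlier start.  The detector is verified
candidate-for-candidate against a brute-force all-(p, offset) enumeration
on every property-suite sequence.

## Phylogenetic stage

The heavy inference of a mitogenome paper (partitioned ML, Bayesian MCMC)
belongs to external engines; this package writes their inputs and verifies
topological claims with its own distance + NJ stage.  The supermatrix
concatenates the 13 PCGs in genome order, fills missing genes with gaps,
and exports by-gene (13) and by-gene×codon-position (39) partitions in
RAxML syntax plus relaxed PHYLIP and NEXUS matrices.  The published
multi-species matrix length depends on dozens of external accessions and
an unstated alignment/trimming protocol, so supermatrix building accepts
pre-aligned blocks and delegates alignment to a pluggable callback.

Distances use pairwise deletion by default (complete deletion by flag).
K2P follows Kimura's closed form; a saturated pair (non-positive log
argument) is flagged and set to a configurable cap (default 5
substitutions/site) rather than returned as infinity, so downstream NJ
still runs.  NJ is the standard Q-criterion agglomeration with a
deterministic tie-break (lowest current index pair) and negative branch
lengths clamped to zero with a log notice.  It is exact on additive
matrices (property-tested against generating topologies up to 12 taxa, and
against exhaustive least-squares over all 15 five-taxon topologies) and
cross-checked against scikit-bio's independent NJ on noisy matrices.
Monophyly of a taxon set is decided by bipartitions: true iff some edge
separates exactly the query set from the side containing the outgroup.

## Synthetic data generator

The generator favours exact bookkeeping over biological realism: its job
is to make every analysis stage falsifiable.  Non-coding regions are
i.i.d. draws under a per-region AT bias; PCG interiors are drawn codon-wise
from a stop-free codon profile whose per-base AT level is solved
numerically so the codon distribution hits the region's AT target
(excluding the AT-rich stop codons would otherwise depress it by ≈ 1
point).  Start/stop codons, anticodon triplets, junction motifs and
control-region elements are written last, and all ground truth (junction
values, pooled codon counts, per-region base counts, element offsets) is
read back from the final base array by direct slicing — independent of the
analysis modules it is used to test.

Study conditions baked into the defaults: the layout template is the
*H. persimilis* annotation (so genome length 15,252 bp and the 12/150,
14/66 junction summary hold by construction), whole-genome AT target 80%,
control region AT 91% with ATAGA + 19 bp poly-T + (AT)₁₀ + a 23 bp unit
× 2 + 9 bp poly-A.  Guard bases separate planted elements so runs cannot
merge, and the tandem array is flanked by forced-mismatch guard blocks
(every guard base differs from its p-shifted partner), which — together
with anchoring — makes tandem recovery exact.  Control-region filler is
rejection-sampled to contain no microsatellite runs and no unit-≥10
tandem arrays, leaving the planted elements unambiguous; short-period
background is left in as intrinsic to AT-rich sequence.  The ~16 guard
bases depress the control region's realised AT a few points below its
target; the whole-genome target is unaffected to within binomial noise.

Panels evolve on a guide tree under the K80 model with transition/
transversion ratio κ (default 2), rate-normalised so branch lengths are
expected substitutions per site; root sequences are AT-biased (0.8), so
the process is deliberately non-stationary at the root, as mitochondrial
data are.  The transition-probability closed form is tested against
scipy's matrix exponential, and observed divergences against the
Chapman–Kolmogorov expectation.  The topology-recovery benchmark is a
six-leaf tree with 0.08-substitutions/site internal edges and 13 genes of
300 bp (3.9 kb total) — deliberately smaller than a real mitogenome
supermatrix, which only makes the recovery task harder; NJ on K2P
distances recovers the generating topology in ≥ 95 of 100 seeded
replicates.

What passing tests show — and do not.  The generator has no indels, no
rate heterogeneity across sites, no secondary-structure constraints, no
compositional heterogeneity across lineages, and draws codons i.i.d.;
agreement with its ground truth demonstrates the *accounting* is correct
(coordinates, strands, counting conventions, detector definitions), not
that the statistics are robust to real mitogenomes' alignment ambiguity or
saturation.  The published base-composition percentages of the two real
genomes require their sequences (only the annotation tables are
redistributed here), so composition is verified on synthetic genomes
against planted targets instead.

## Degenerate inputs and tie-breaks, summarised

Empty regions, missing sequences, unknown gene names, unsorted or
duplicated features, malformed locations/Newick, taxa without genes, and
zero-comparable-site pairs raise errors naming the offender.  Internal
in-frame stops and non-canonical start codons are reported, not raised.
All tie-breaks are deterministic: microsatellite overlap resolution
prefers longer runs then earlier starts; tandem resolution prefers higher
copies×length, smaller units, earlier starts; NJ joins the lowest-index
minimal-Q pair; consensus-unit ties go to the first copy's base.
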