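# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ymarker`, and what the synthetic experiments do and
do not demonstrate.

## Coordinates and alphabets

All coordinates are 0-based, half-open; strand is `+`/`-`.  Sequences
are uppercase over {A, C, G, T, N}.  `U` and IUPAC ambiguity codes
other than `N` are rejected at parse time, because the fixed-difference
caller needs unambiguous bases: an ambiguous X base cannot witness a
fixed X–Y difference, and silently treating it as one would inflate the
candidate site list.

## Global alignment

`align_global` is affine-gap global alignment (Needleman–Wunsch/Gotoh)
via Biopython's `PairwiseAligner`.  A gap of length L costs
`gap_open + L·gap_extend`.  Defaults — match +2, mismatch −3, gap open
−5, gap extend −2 — are megablast-like and deliberately mismatch-averse:
for X/Y copies of one gene the alignments are near-diagonal and the
fixed-difference projection is insensitive to the exact scheme.  Among
co-optimal alignments the aligner's first traceback is returned, which
is deterministic for fixed inputs; only gap placement, never the score,
can differ between tied alignments.

## Synonymous divergence (NG86)

dS between X and Y coding copies uses the Nei–Gojobori (1986)
unweighted-pathway method:

* Site counts: each codon position contributes the fraction of its 3
  possible single-base changes that are synonymous; changes to stop
  codons count as nonsynonymous.  S and N are averaged between the two
  sequences.
* Differences: for codons differing at k positions, all k! mutational
  orderings are averaged with equal weight.  Orderings passing through
  a stop codon are excluded (the standard convention); in the
  degenerate case where every ordering is blocked, all are used so the
  count remains defined.
* Correction: Jukes–Cantor, dS = −(3/4)·ln(1 − (4/3)·pS), flagged
  *saturated* (NaN) when pS ≥ 3/4.
* Degenerate input: codon pairs containing a gap or N are dropped
  pairwise; trailing incomplete codons are trimmed; a terminal stop
  codon is skipped; a premature stop raises an error rather than
  silently truncating, since it usually means a frame problem upstream.

A gene's dS is the mean over its X haplotypes of the Y-vs-X estimate.
Genes are then filtered (Y-expressed → oldest stratum → top-20 dS,
saturated estimates ranked last because their magnitude is unknowable →
intron ≥ 300 bp).  The oldest stratum is taken from the metadata's
ordinal labels (minimum = oldest); strata are never inferred from
sequence.

## Fixed X–Y differences

Each X haplotype is aligned to the Y copy and its bases projected onto
Y coordinates.  A site is reported iff every X has the same ungapped,
unambiguous base and it differs from the Y base.  With one X haplotype
this degenerates to the mismatch-column set; a warning recommends ≥ 3 X
sources from different cultivars, since cross-population fixity is what
makes a marker portable.

## Primer design

Candidate windows are filtered on:

* length 18–24 nt; GC 30–70%;
* Tm 55–62 °C by nearest-neighbor thermodynamics (unified SantaLucia
  parameter set, 50 mM Na⁺, 0.25 µM oligo, entropic salt correction) —
  a window bracketing a 58 °C annealing step;
* product size 100–600 bp (agarose-resolvable);
* dimer screening: reject if any complementary run ≥ 8 bp, or any run
  ≥ 4 bp ending at either primer's 3′ terminus, for self- and
  cross-combinations.  The threshold test is implemented as substring
  search (a run of length ≥ k exists iff the reverse complement of some
  k-mer of one primer occurs in the other), which is exactly equivalent
  to thresholding the full run-length scan and far cheaper.

Y-specificity requires the amplicon to span ≥ 2 fixed differences and
≥ 1 primer to carry a fixed difference within its 3′-terminal 3 nt.
The 3-nt anchor window intentionally equals the binding model's
3′-exact zone (below), so an anchored primer is *guaranteed* to reject
the X allele under the package's own binding semantics; a wider window
would admit pairs whose X rejection is not assured.  Both windows are
configurable together.

Enumeration is exhaustive.  When a caller caps the candidate count
(`max_pairs`), the search space is subsampled on a strided 2-D grid
over (forward window, reverse window) rather than truncated, so the
capped set stays spread over template positions and product sizes —
truncation would return hundreds of near-identical pairs sharing one
primer, which poisons downstream panel assembly.

## Multiplex assembly

`select_multiplex` searches (2 Y-specific pairs from distinct genes +
1 autosomal control) triples for: pairwise product-size gaps ≥ 60 bp
(default; gel-separability) and no cross-pair dimer violations, ranked
by total fixed differences covered, then total inter-pair dimer score,
then ids.  Above ~200k triples the per-gene lists are capped at 20
candidates, round-robined across product-size bands of the gap width —
size-diverse, primer-diverse subsets keep the capped search from
inheriting correlated failures.  Infeasibility raises an error naming
the constraint that eliminated the most triples.

## In silico PCR

A primer binds where the template matches with ≤ 2 mismatches overall
and 0 mismatches in the 3′-terminal 3 nt (template N counts as a
mismatch; primers containing N are rejected).  Both strands are
scanned with a vectorized sliding-window comparison.  Amplicons pair
plus-strand forward sites with downstream minus-strand reverse sites,
require non-overlapping footprints, and cap the product at 3000 bp.  A
Y-specific pair is valid iff every male genome yields exactly one
product and every female genome none; a control pair must yield exactly
one product everywhere.  Band interpretation: no control band →
failed; control + any Y band → male; control alone → female; bands
attributable to no panel member within ±10% of an expected size are
flagged.

## Assay evaluation

Per-cultivar confusion counts feed the true positive success rate
100·(correct males + correct females)/n — rounded to an integer per
cultivar and one decimal for the total, matching the precision of the
published validation table — and the specificity
100·(males called male)/(males called male + males called female),
i.e. the absence of the costly error (a male slipping through as
female).  Failed reactions count in n but never in the numerator.

## Synthetic cohorts

The generator emulates the data regime the pipeline assumes and
nothing more:

* Ancestral coding sequences are uniform sense codons; the Y copy is
  mutated until the NG86 estimate first crosses the stratum's target dS
  (synonymous proposals always accepted, nonsynonymous at 20% —
  a crude purifying-selection bias; stops never created).  Because the
  stop rule *is* the estimator's threshold, recovery is tight: the mean
  estimate over 50 replicates of 300-codon genes sits within ±0.01 of
  targets in [0.05, 0.40].
* X haplotypes are the ancestor with low per-site noise
  (`intra_x_diversity` = 0.002 « stratum dS, enforced at config
  validation); true fixed differences are recorded as generator truth.
* One intron (default 400 bp, random sequence, mutated like its
  flanking gene) is inserted at a random codon boundary; primers are
  designed on the genomic marker (exon–intron–exon) with fixed sites
  lifted through the structure.
* Chromosome templates concatenate gene structures with 200–1000 bp
  random spacers; X haplotypes share a spacer backbone, the hemizygous
  Y has its own.  Females carry 1–2 distinct X templates (a homozygote
  holds one record), males X + Y; everyone carries the autosome.
* Defaults mirror the validated assay's scale: 12 cultivars × 16
  samples = 192 (half male), 3 X haplotype sources, 300-codon genes, an
  old stratum at dS 0.20 and a younger at 0.05, a 61% Y-expression
  rate, and a phenotyping error rate of 1/192.  The gene count (12) is
  a deliberate scale-down of the hundreds of sex-linked genes a real
  transcriptome screen yields; it keeps full-pipeline runs in seconds
  while leaving ~6 genes in the oldest stratum.
* One integer seed drives a hierarchical `SeedSequence`, so cohorts are
  byte-reproducible and per-gene regeneration is stable.

**What the synthetic experiments do not show.**  Real genomes contain
repeats, paralogs, and assembly gaps that can create off-target binding
sites or hide true ones; real X haplotypes have structured linkage
rather than i.i.d. noise; indel divergence between X and Y is not
simulated (alignments are exercised, but fixed-difference calling on
heavily gapped genes is not stress-tested); and the thermodynamic model
ignores secondary structure.  Passing the synthetic suite therefore
demonstrates internal correctness of the selection → anchoring →
amplification logic, not field performance on new cultivars.

## Problem sizes in the shipped experiments

Tests and the acceptance script use 120–300-codon genes, 2–12 gene
cohorts, 20 replicate cohorts for the design-stage properties, 50
replicates per dS-recovery target, and one full 192-sample chain —
sizes chosen so the complete suite runs in about a minute while every
property is still exercised on hundreds to thousands of instances.

## Known limitations

* dS is NG86-only; no maximum-likelihood codon model is provided, and
  near saturation (pS → 3/4) the estimate is flagged rather than
  rescued.
* Primer thermodynamics cover duplex Tm and complementarity runs, not
  hairpins or heterodimer ΔG.
* In silico PCR uses mismatch counts, not extension-efficiency
  modeling; the 3′-exact zone is a binary proxy for allele-specific
  suppression.
* The multiplex search under capping is near-optimal by construction
  of the diverse subset, but only the uncapped search is provably the
  ranking optimum (and is what the exhaustive-oracle test checks).
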