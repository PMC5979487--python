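# Methods

`plastdiff` quantifies divergence between two chloroplast genomes of one
species and mines polymorphic markers from it. This note records the model,
the conventions and defaults that matter, what the simulator does and does
not emulate, and the package's known limitations.

## Genome model

A plastome is a circular DNA molecule of roughly 120–170 kb with the
quadripartite architecture LSC–IRb–SSC–IRa: a large and a small single-copy
region separated by two inverted repeats that are exact reverse complements
of each other. Internally every coordinate is 0-based half-open; every
report output is 1-based inclusive. The genome is handled unwrapped at the
LSC start (the conventional deposition); the spacer closing the circle is
represented with an interval running past the sequence end and sequence
access wraps.

Annotations are read from GenBank flat files (gene/CDS/tRNA/rRNA features,
`join()` locations) or from a documented 6-column tab-separated table
(name, ftype, strand, exon_starts, exon_ends, notes; 1-based inclusive in
the file). The quadripartite partition is supplied explicitly, carried as
`region` rows in the table, or inferred: the IRs are detected as the longest
pair of exact reverse-complement repeats of at least `min_ir_len` (default
10 kb, the scale of real plastome IRs; tests use smaller values on toy
genomes), the larger single-copy stretch is labelled LSC, and IRb is the
copy that follows the LSC on the plus strand. Detection is seed-and-extend
on k-mers against the reverse complement and returns maximal repeats, so a
genome whose planted or annotated IR boundary is not maximal will be
assigned the (correct) maximal one.

GC content counts G+C over the full length; N bases count in the
denominator only. Coding fraction is the union of CDS exon bases over
genome length, so IR-duplicated genes are not double counted. The union
convention is documented rather than claimed to match any particular
published coding-fraction figure, whose convention is typically unstated.

## Locus catalog

Gene loci are full gene spans (exons plus introns); intergenic spacers are
the maximal gaps between consecutive gene spans along the plus strand,
named `upstream-downstream`; intron loci are the gaps between consecutive
exons of a feature. Loci lying fully inside IRb are dropped and their IRa
twins analysed once with region label "IR" — event totals over
LSC/SSC/IR then count each IR mutation exactly once, which is the only
convention consistent with summing per-region totals to the overall event
count. Homologous loci are paired across genomes by (name, category);
unmatched loci are reported, never silently dropped. Event region labels
are assigned from the event's own position in the reference partition, so
events inside a boundary-spanning spacer are labelled by where they
actually fall.

Divergence analysis runs over gene and spacer loci only; intron loci are
catalogued for locus-level accounting but excluded from the alignment set
(events in introns are already covered by their gene's locus, and aligning
both would double-count).

## Alignment and event calling

Each locus pair is aligned globally with Needleman–Wunsch under affine gap
penalties (Gotoh three-state dynamic programming): match +2, mismatch −3,
gap open −5, gap extend −2, a gap of length k costing `open + k·extend`.
These values are fixed and documented because reproducible event counts
require a fixed scheme; published intraspecific comparisons typically name
a tool "with default settings", which is not recoverable. N scores 0
against anything and N-containing columns are excluded from SNP calling.
Traceback ties prefer diagonal over up over left; the final-cell state
prefers match over the gap states. Loci at plastome scale (up to a few kb)
are aligned with full DP (a numba kernel); no banded mode is provided
because the full DP is already fast at these sizes.

Alignments are left-normalized before event calling: every gap run is
shifted maximally left while preserving both ungapped sequences and the
column-wise match structure (the classic variant-normalization rule). This
gives stable, canonical indel coordinates inside repeats; the operation is
idempotent and score-preserving on optimal alignments, both of which are
property-tested.

Event grammar: one SNP per mismatching non-N column; one indel event per
maximal gap run in either row, whatever its length (a 44-bp gap is one
event of size 44). Adjacent gap runs in opposite rows separated by at least
one aligned column are distinct events. Coordinates are reported on the
reference genome — by convention genome B, the "previously published" role;
insertions are positioned before the reference base they precede.

Whole-genome colinearity is checked before locus analysis with unique
k-mer anchors (default k = 25): the genomes are syntenic iff shared unique
anchors appear in the same order and essentially no unique k-mers match
only in reverse-complement orientation (which would betray an inversion).
IR-internal k-mers occur twice per genome and therefore never anchor.

## Mutation classification

* Transition/transversion by the purine/pyrimidine classes.
* CDS SNPs are mapped to codons on the spliced, strand-oriented coding
  sequence (multi-exon CDSs spliced first, minus-strand genes
  reverse-complemented), the affected codon substituted and both codons
  translated with NCBI translation table 11 (the standard choice for
  plastids). A stop-gain is reported as nonsynonymous with a nonsense
  flag. CDSs whose spliced length is not a multiple of 3 are rejected with
  the gene name.
* Large indels (> 10 bp, the conventional inventory threshold) are tested
  for repeat association: the event is repeat-linked if the allele (or its
  reverse complement) shares an exact match of length
  `min(min_match, size)` with the flanking sequence within a window
  (defaults: `min_match` 10, window `max(100, 3·size)` — the smallest
  inventoried indels are ~11 bp and the window scales with event size), or
  if the allele is itself a tandem array (smallest period at most half its
  length). This captures both flank-duplication expansions/contractions
  and slippage-style arrays.

## Variability statistic and marker selection

Per locus, the proportion of variation is `P = (NS + ID)/L × 100` with NS
the SNP count, ID the indel event count, and L the aligned length in
columns, gap columns included (the printed arithmetic of published marker
tables, e.g. 3/234 → 1.28 %, only works with this denominator).
Percentages are rounded half-up to two decimals wherever printed; the
profile mean is taken over polymorphic loci only (vc_count > 0), averaging
unrounded values and rounding once.

Marker selection keeps loci with 200 ≤ L ≤ 1500 bp (a Sanger-amplifiable
window) and P strictly greater than 0.25 %, ranked by P descending with
ties broken by larger L then name, truncated to n (default 20).

## SSR detection and polymorphic cpSSR mining

Detection uses the standard chloroplast MISA-style minimums — 10 units for
mononucleotide motifs, 6 for di-, 5 for tri- through hexanucleotide. A
tract is a maximal exact head-to-tail repetition of a primitive motif;
trailing partial units are excluded. Overlapping candidates across unit
lengths are resolved greedily (longer tract wins, ties to the smaller
start — a choice that is deterministic but, like any such rule, not
strand-symmetric in exact-tie cases). Motif canonicalization uses the
minimal rotation only, not the reverse complement, so (A) and (T) tracts
remain distinct, as they do in published cpSSR tables. Compound
(adjacent) tracts are reported as separate loci.

Cross-genome matching pairs tracts with equal canonical motifs whose 20-bp
flanks each align with at most 2 mismatches and no indels; assignment is
one-to-one, best flank identity first with ties by genomic distance, and
an exact tie between two free partners is reported as an ambiguity rather
than guessed. Matched pairs with unequal tract lengths are the polymorphic
cpSSRs, reported "min–max" style.

## The simulator

`synthetic_plastomes.simulate_pair` builds genome B first — region sizes
from the quadripartite fractions; genes tiled region by region with
random-length spacers (every spacer at least the configured minimum);
coding genes as stop-free codon runs with start/stop, a fraction carrying
one intron; tRNA- and rRNA-sized noncoding genes; IRa constructed as the
exact reverse complement of IRb with mirrored annotations — and then
derives genome A by applying exactly the planted edit list.

Defaults are the study conditions this package replays: 160 kb genome,
LSC/SSC/IR fractions 0.53/0.09/0.19, GC 38 %, 75 SNPs and 80 indels,
coding SNPs synonymous-only (planted at four-fold degenerate third
positions; 53 % of SNPs in CDSs, 26 % in genic noncoding sequence, the
rest in spacers), transitions planted as an exact count of
`round(0.85 × n_cds_snp)` among coding SNPs (34 of 40 at defaults, the
condition being a reported count, not a rate), 25 % of indels large
(11–120 bp; 15 insertions to 5 deletions; all planted as repeat
expansions — duplicating the left flank — or contractions — deleting one
unit of a tandem pair written into B), 31 detectable SSR tracts (plus
below-threshold decoys) of which 8 are length-polymorphic mononucleotide
tracts whose slippage edits are drawn from the indel budget, and a minimum
event spacing of 25 bp.

Details that make validation exact rather than approximate:

* The random background is scrubbed of near-threshold repeats before
  planting (homopolymers ≥ 8, dinucleotide runs ≥ 5 units, etc., are
  broken), so the detected SSR set equals the seeded set and indel
  normalization shifts stay short.
* Planted edits are left-normalized against genome B with the same rule
  the event caller uses, so recovered events can be compared to the
  manifest by exact (kind, position, allele) identity.
* Edits are kept clear of locus and region boundaries (30-bp margins, a
  20-bp normalization-shift allowance, registry-enforced spacing), and IR
  edits are planted on the IRa copy and mirrored into IRb via interior IRb
  spacers only, so the IR dedup counts each planted event exactly once and
  `IRa == revcomp(IRb)` holds in both genomes.
* The IR/SSC junction is adjusted so the planted partition is the maximal
  exact repeat, keeping auto-detection and ground truth identical.
* Applying the manifest to genome B must reproduce genome A byte-exactly;
  this round trip is asserted in the tests.

What the simulator does **not** emulate: realistic substitution processes
(no HKY/GTR, no rate heterogeneity along the genome), gene content and
order of real plastomes (names and sizes are synthetic), annotation errors,
sequencing or assembly artefacts (no N runs by default), events closer than
the spacing floor, and rearrangements. Passing validation therefore
demonstrates that the pipeline's calling, classification, counting and
mining logic is exact under clean, well-separated mutations — not that it
is robust to misannotation or to clustered mutations, which intraspecific
plastome comparisons rarely contain but which would require manual review.

## Validation scale and runtime choices

The many-seed validation sweep runs on a miniature genome
(`small_config`: 14 kb, 12 genes, 8 SNPs, 8 indels, 6 SSR tracts, same
structure, same 25-bp spacing), which exercises every code path in a few
hundredths of a second per seed; 500 seeds complete in about a minute.
Study-scale runs (160 kb, 155 events) are exercised once in the test suite
and once per acceptance-script invocation (a few seconds each). These sizes
are the package's own choice of validation design: the miniature genome
makes the sweep wide (many seeds) where width matters, and the full-scale
run confirms the defaults.

## Numerical and edge-case conventions

* Rounding: decimal half-up everywhere a percentage is printed.
* `vc_percent` rejects L = 0; empty marker selections are legal.
* Zero-length spacers (abutting genes) are omitted; overlapping gene spans
  produce no spacer and are logged.
* Multi-allelic columns cannot occur with two genomes; N columns are
  skipped.
* VCF export uses the conventional anchor-base representation for indels;
  the TSV event table uses the package's anchor-free alleles.
* All randomness flows from one `numpy` Generator keyed by the seed;
  identical seeds give bit-identical genomes, manifests and reports.

## Known limitations

* Locus pairing is by annotation name; diverged or inconsistently named
  annotations end up in the unmatched report rather than being rescued by
  sequence similarity.
* The colinearity check detects rearrangements but the pipeline does not
  analyse rearranged genomes; it warns and proceeds with name-based
  pairing.
* Repeat association is a heuristic with a documented false-positive rate
  on random sequence (empirically well under 5 % for 20-mers; property-
  tested), not a mechanistic inference.
* The marker length window and variability threshold are fixed filters;
  no primer design or PCR feasibility check beyond the window is done.
* SSR overlap resolution ties and one-to-one flank matching can, in
  pathological duplication scenarios, reject as ambiguous what a curator
  would resolve by eye; the error lists the conflicting loci.
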