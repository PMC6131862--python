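# Methods

This note documents the models, conventions and design choices behind
contigsv: what each stage computes, which knobs matter, what the synthetic
data does and does not emulate, and where behaviour was genuinely open and
had to be pinned.

## Coordinates and conventions

All internal coordinates are 0-based half-open on the genome forward
strand.  GTF (1-based inclusive) and SAM (1-based) are converted at the
I/O boundary; the event TSV re-emits 1-based positions and the BEDPE
0-based half-open intervals.  A breakpoint is the coordinate of the
terminal *aligned base* with an orientation: `L` means the aligned
reference continues toward lower coordinates from that base, `R` toward
higher.  In BEDPE, strand `+` encodes `L` and `-` encodes `R`.

Contig coordinates always refer to the contig as it appears in the FASTA,
including clipped bases; reverse-strand and hard-clipped supplementary
records are re-expressed in this frame during parsing so that split
records of one contig share a single coordinate system.

## Alignment decoding

CIGAR `M/=/X` extend the current block; `I` records an insertion gap with
its sequence; `N` always splits blocks (a splice); `D` below
`min_intron_size` (default 20) is a deletion gap, at or above it a block
split — the genome does not label where a deletion ends and an intron
begins, so the boundary is a configuration key.  Secondary records are
dropped; supplementary records are kept as fragments of a chimeric
contig.

## Structural events

Fragments of one contig, ordered by contig coordinate and filtered to
`min_fragment_len` ≥ 30 aligned bases, yield one adjacency per
consecutive pair when the contig gap is ≤ `max_novel_seq` (50) and the
overlap ≤ `max_homology` (10).  Overlapping bases are reported as
microhomology with the breakpoint left-aligned: of all placements
consistent with the overlap, the one giving breakpoint 1 the lowest
genome coordinate is reported, matching indel-normalisation convention.

Classification is a fixed decision cascade (duplication geometry →
read-through → fusion) because the relative precedence of the classes is
not derivable from the taxonomy itself and determinism requires pinning
it.  Duplication geometry on the forward strand is an `L` breakpoint at a
higher coordinate joined to an `R` breakpoint at a lower one (mirrored on
the reverse strand).  The ITD/PTD split follows the field's usage: PTD
needs both breakpoints on annotated exon boundaries and ≥ 1 complete exon
duplicated; ITD needs breakpoints interior to a single exon or a span
containing no complete exon; everything else is a generic duplication.
"Adjacent" genes (for read-throughs) share chromosome and strand with no
third same-strand gene entirely between them.  Exon-boundary matching is
exact (`exon_boundary_tolerance` 0): annotation treats boundary versus
interior as a sharp dichotomy, and the tolerance is a config key for
annotation sets where that is too strict.

The 5'/3' partner assignment uses fragment sense: a fragment aligned in
its gene's strand reads that gene 5'→3' along the contig, so the sense
fragment that comes first on the contig contributes the 5' side; if both
fragments are antisense the contig is the reverse complement of the
chimeric transcript and the assignment flips.  Ties between overlapping
genes at one breakpoint break deterministically: strand agreement with
the fragment, then exonic overlap, then lexicographic gene id.

Gapped events compare the gap sequence with its genomic flanks.  The
repeat test (minimal unit of length ≤ `max_repeat_unit` = 6 tiling the
insert, with one unit copy adjacent in the genome) runs before the
full-length duplication test whenever the insert decomposes into a
shorter unit; otherwise an `AG`-unit expansion next to an `AG` tract
would be mislabelled as a duplication of the tract's tail.  Duplicated
insertions inside an exon of ≥ `min_itd_len` (9) bases are ITDs — long
enough to exclude the common 1–2 codon polymorphic duplications while
admitting the shortest reported clinically relevant ITDs.  Events outside
annotated exons are kept but flagged (`intronic`/`intergenic`).

Merging collapses events identical in (type, ordered breakpoints,
untemplated insert) across contigs, concatenating contig ids; support is
then counted once at the read level (distinct read names).  The insert
sequence participates in the key because two junctions sharing
coordinates but differing in inserted bases are distinct alleles, which
the output must keep separate.  With the exon-boundary restriction on
(default), fusions with both breakpoints away from annotated boundaries
are flagged `not_exon_boundary` rather than deleted, so turning the
restriction off is purely a filtering decision.

## Frame status

For fusions and read-throughs the check runs in spliced coordinates:
`u` = coding bases from the 5' CDS start through the breakpoint base,
`i` = untemplated insert length, `p` = (3' breakpoint offset from its CDS
start) mod 3; in frame iff `(u + i) mod 3 = p`.  For duplications the
duplicated length is measured in spliced coordinates (introns inside a
PTD span contribute nothing), and indels use the net length change.  The
result is NA whenever a transcript lacks CDS or a breakpoint falls
outside it.  The test suite verifies this arithmetic against an
independent oracle that reconstructs the chimeric coding sequence and
translates it.

## Splicing events

Events are called against the single best-matching isoform, chosen by
exactly matched exon edges (with matched annotated introns scoring their
two edges again, so the isoform whose junction structure the contig uses
wins), then overlapped exonic length, then lexicographic id.  A junction
reproduced by any isoform of the gene is never novel — isoform switching
must not masquerade as novelty.  Junction gaps below `min_intron_size`
are left to the indel caller.  Per junction: both edges annotated and
spanning whole exons → skipped exon (one event listing all skipped
exons); one edge displaced ≤ `max_junction_shift` (300, bounding
pathological alignments) → novel donor or acceptor, named in transcript
orientation (the donor is the upstream exon's exon→intron edge); both
edges inside one exon → novel intron.  A block wholly inside an annotated
intron flanked by junctions on both sides is a novel exon (both new
introns' motifs are reported, canonical only if both are); a block
running continuously across exon–intron–exon is a retained intron, whose
canonical flag is NA because it creates no new edge.  Motifs are the
first and last intron dinucleotides, reverse-complemented for
minus-strand genes; the canonical set defaults to {GT-AG} with an
extended {GT-AG, GC-AG, AT-AC} option.

## Read support

A spanning read's alignment to the contig must cover
`[break1 − min_overhang, break2 + min_overhang)` with `min_overhang` = 4;
only primary, non-duplicate records count, which is conservative and
reproducible.  Single reads, not pairs, are the unit.  The four-read PASS
threshold (`min_support`, inclusive) is the standard evidence rule for
this class of caller; splice-junction depth uses the same machinery on
the junction point.

## Read binning

The multi-index filter is realised as one hashed ID array rather than a
stack of per-gene Bloom filters: each slot is empty, a gene index, or an
ambiguity sentinel, and array size and hash count follow the standard
Bloom sizing for the configured false-positive rate (1e-3) over all
inserted keys.  The contract is the classical one — zero false negatives
for inserted frames, bounded false positives — not any specific bit
layout.  Five spaced seeds of length `k` = 25 with ~70% care positions
(first and last positions always care) are generated once from a fixed
internal seed so patterns never vary between runs; a frame hits with
≥ 5 − `allowed_miss` = 3 seed agreements, which absorbs up to two seed
losses per frame from substitutions.  Every transcript k-mer is inserted
on both strands, making forward-only querying strand-agnostic; this
replaces canonical-k-mer keying, which interacts poorly with asymmetric
spaced-seed masks, at the cost of doubling insertions.  A read classifies
to the gene with the most hitting frames (ambiguous frames count toward
any candidate; ties break lexicographically); a pair is binned when
either mate classifies, and may enter two bins when the mates disagree.

## Synthetic data

The generator emulates: multi-chromosome genomes with non-overlapping
multi-exon genes on both strands; canonical GT-AG introns by
construction; a central ORF (ATG, stop-free codons, TAA) as CDS; a
microsatellite tract, a cryptic GT..AG segment inside one exon, and a
cryptic exon inside one intron (positioned so its inclusion creates two
canonical introns) as substrate for repeat and splice events.  Planted
events are constructed in transcript space as segment lists (reference
blocks, untemplated inserts, forced fragment breaks), which makes the
oracle SAM exact by construction: CIGARs, split records, flags and
strands come from the trace, never from sequence search.  Reads are
sampled uniformly with normal insert sizes (250 ± 25 bp, 100 bp reads)
and independent per-base substitutions (default rate 0.37%, the default
Illumina error profile of the data the pipeline targets); indel
sequencing errors, quality models and GC bias are *not* emulated.
Everything is deterministic under its seed.

What passing tests therefore show: the classification logic, coordinate
arithmetic, motif logic and support counting are exact on clean,
structurally faithful inputs.  What they do not show: robustness to
misassembly, ambiguous multi-mapping alignments, aligner-specific
breakpoint jitter, or annotation errors — those live upstream of this
package's contract, which takes contigs and alignments as given.

## Titration benchmark

Assembly is deliberately not re-implemented.  Its coverage dependence is
emulated by a reconstructibility rule: reads are simulated from a ±250 bp
window around each planted junction, and the oracle contig retains the
junction only when ≥ `min_support` simulated reads span it; otherwise
only the 5' half of the window is emitted.  This is an explicit emulation
knob, not a claim about any assembler.  Per coverage cell, a true
positive is a PASS fusion whose unordered gene pair matches a planted
pair; the false-positive denominator is all pairs of background
transcripts.  The default desk-scale design (20 fusions × 40 background
transcripts; full scale is a config choice) runs in seconds and
reproduces the expected shape: a sensitivity dip at 4× breakpoint
coverage, 100% above, and zero false positives from background
transcripts — background contigs are exact transcript sequences, so any
false fusion would have to come from the caller itself.

## Problem sizes and numerical choices

The shipped test suite and acceptance script use 16–130-gene universes,
20-fusion titrations and ~400 k-read binning panels — sizes chosen so
the full validation runs on a laptop in minutes while every measured
quantity is still computed, never assumed.  Degenerate inputs are pinned:
introns shorter than 4 bases are an error for motif lookup; gaps at
contig edges with insufficient flank fall back to plain indel calls with
boundary status NA; contigs absent from the reads-to-contig alignment
get zero support and a warning rather than an exception.  All tie-breaks
(gene, transcript, bin) are lexicographic after the scientific criteria,
and outputs are stably sorted, so repeated runs are byte-identical.

## Known limitations

* Contig-to-transcriptome alignments are not consumed; gene assignment is
  genomic only, so events entirely inside unannotated transcribed regions
  are reported but filtered.
* Multi-fragment contigs are classified pairwise per consecutive junction;
  no multi-way event type exists.
* Inversions and insertional translocations not expressible in transcript
  space are out of scope, as are SNVs and expression quantification.
* Support counting ignores discordant read-pair (flanking) evidence and
  base qualities.
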