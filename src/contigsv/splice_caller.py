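"""Novel splicing-variant detection from block-vs-exon comparison.

A contig aligned to the genome decomposes into blocks separated by
intron-sized skips.  Comparing those blocks and their junctions with the
exon structure of the best-matching annotated transcript yields six event
classes: skipped exon, novel exon, novel intron, retained intron, and
novel donor/acceptor sites.  Junctions reproduced by *any* isoform of the
matched gene are never called novel, so isoform switching does not create
false events.

Donor/acceptor naming follows transcript orientation: the donor is the
exon-to-intron edge of the upstream exon (the intron's low-coordinate edge
on a plus-strand gene, its high-coordinate edge on a minus-strand gene).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotation import GeneIndex
from .io_formats import revcomp
from .models import (
    ContigAlignment,
    GeneModel,
    PipelineConfig,
    SpliceEventCall,
    TranscriptModel,
)


@dataclass
class BlockExonCorrespondence:
    contig_id: str
    transcript_id: str
    gene_id: str = ""
    # (block_index, exon_index, left_edge_match, right_edge_match)
    matches: list[tuple[int, int, bool, bool]] = field(default_factory=list)
    unmatched_blocks: list[int] = field(default_factory=list)
    unmatched_exons_in_span: list[int] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.transcript_id)


def _genome_sorted_blocks(aln: ContigAlignment) -> list[tuple[int, int, int, int]]:
    return sorted(aln.blocks, key=lambda b: b[0])


def _score_transcript(
    t: TranscriptModel, blocks: list[tuple[int, int, int, int]]
) -> tuple[int, int]:
    """(exact edge matches, overlapped exonic length) of blocks vs exons.

    Block edges coinciding with annotated exon boundaries score one each;
    a block junction reproducing one of the transcript's annotated introns
    scores its two edges again, so the isoform whose junction structure the
    contig actually uses wins over isoforms that merely share boundaries.
    """
    starts = {s for s, _ in t.exons}
    ends = {e for _, e in t.exons}
    introns = set(t.introns())
    edges = 0
    overlap = 0
    for gs, ge, _, _ in blocks:
        if gs in starts:
            edges += 1
        if ge in ends:
            edges += 1
        for s, e in t.exons:
            overlap += max(0, min(ge, e) - max(gs, s))
    for i in range(len(blocks) - 1):
        junction = (blocks[i][1], blocks[i + 1][0])
        if junction in introns:
            edges += 2
    return edges, overlap


def match_transcript(
    alignment: ContigAlignment, index: GeneIndex
) -> BlockExonCorrespondence:
    """Pick the transcript best explaining the alignment's block structure.

    Candidates are all isoforms of genes overlapping the aligned span,
    ranked by exactly matched exon edges, then overlapped exonic length,
    then lexicographic transcript id.  The returned correspondence pairs
    blocks with exons monotonically by interval overlap.
    """
    blocks = _genome_sorted_blocks(alignment)
    lo, hi = alignment.genome_start, alignment.genome_end
    cands: list[tuple[GeneModel, TranscriptModel]] = []
    tree_genes = set()
    for pos in (lo, hi - 1):
        for g in index.genes_at(alignment.chrom, pos):
            tree_genes.add(g.gene_id)
    # also catch genes fully inside the span
    tree = index._trees.get(alignment.chrom)
    if tree is not None:
        for iv in tree.overlap(lo, hi):
            tree_genes.add(iv.data)
    for gid in sorted(tree_genes):
        g = index.gms.genes[gid]
        for t in g.transcripts:
            cands.append((g, t))
    if not cands:
        return BlockExonCorrespondence(alignment.contig_id, "")

    def rank(gt):
        edges, overlap = _score_transcript(gt[1], blocks)
        return (-edges, -overlap, gt[1].transcript_id)

    gene, t = min(cands, key=rank)

    corr = BlockExonCorrespondence(
        contig_id=alignment.contig_id,
        transcript_id=t.transcript_id,
        gene_id=gene.gene_id,
    )
    ei = 0
    matched_exons = set()
    for bi, (gs, ge, _, _) in enumerate(blocks):
        # advance to the first exon not entirely left of this block
        while ei < len(t.exons) and t.exons[ei][1] <= gs:
            ei += 1
        if ei < len(t.exons):
            s, e = t.exons[ei]
            if min(ge, e) > max(gs, s):
                corr.matches.append((bi, ei, gs == s, ge == e))
                matched_exons.add(ei)
                ei += 1
                continue
        corr.unmatched_blocks.append(bi)
    for i, (s, e) in enumerate(t.exons):
        if i not in matched_exons and s >= lo and e <= hi:
            corr.unmatched_exons_in_span.append(i)
    return corr


def check_splice_motif(
    genome,
    chrom: str,
    intron_start: int,
    intron_end: int,
    strand: str,
    canonical_set: tuple[str, ...] = ("GT-AG",),
) -> tuple[str, bool]:
    """Donor/acceptor dinucleotides of an intron, in transcript orientation.

    Returns ``("GT-AG", True)`` style pairs; canonical iff the motif is in
    ``canonical_set`` (default the major spliceosome motif; an extended set
    may add GC-AG and AT-AC).  Raises on introns shorter than 4 bases.
    """
    if intron_end - intron_start < 4:
        raise ValueError(
            f"degenerate intron {chrom}:{intron_start}-{intron_end} (<4 bases)"
        )
    seq = genome[chrom]
    left = str(seq[intron_start : intron_start + 2]).upper()
    right = str(seq[intron_end - 2 : intron_end]).upper()
    if len(left) < 2 or len(right) < 2 or intron_start < 0:
        raise IndexError("intron outside genome bounds")
    if strand == "+":
        motif = f"{left}-{right}"
    else:
        motif = f"{revcomp(right)}-{revcomp(left)}"
    return motif, motif in canonical_set


def _safe_motif(genome, chrom, s, e, strand, canonical_set):
    try:
        return check_splice_motif(genome, chrom, s, e, strand, canonical_set)
    except (IndexError, KeyError, ValueError):
        return "NA", False


def call_splice_events(
    correspondence: BlockExonCorrespondence,
    alignment: ContigAlignment,
    genome,
    index: GeneIndex,
    config: Optional[PipelineConfig] = None,
) -> list[SpliceEventCall]:
    """Call the six novel-splicing classes for one contig alignment.

    Junction-by-junction comparison against the matched transcript, with a
    novelty veto from every isoform of the gene.  Splice-site motifs of any
    newly created intron edge are looked up in the genome (reverse
    complemented for minus-strand genes); retained introns carry the motif
    of the retained intron with canonical status undetermined.
    """
    cfg = config or PipelineConfig()
    if not correspondence:
        return []
    t = index.gms.get_transcript(correspondence.transcript_id)
    gene = index.gms.genes[correspondence.gene_id]
    chrom = alignment.chrom
    blocks = _genome_sorted_blocks(alignment)
    canon = tuple(cfg.canonical_motifs)

    known_introns = set()
    for iso in gene.transcripts:
        known_introns.update(iso.introns())
    t_starts = {s for s, _ in t.exons}
    t_ends = {e for _, e in t.exons}

    def contig_break_at(i: int) -> int:
        """Contig coordinate of the junction after genome-sorted block i."""
        if alignment.strand == "+":
            return blocks[i][3]
        return blocks[i + 1][3]

    events: list[SpliceEventCall] = []

    def emit(etype, coords, motif, canonical, cbreak):
        events.append(
            SpliceEventCall(
                event_type=etype,
                gene=gene.gene_id,
                transcript=t.transcript_id,
                chrom=chrom,
                coords=coords,
                splice_motif=motif,
                canonical=canonical,
                contig_ids=[alignment.contig_id],
                contig_break=cbreak,
            )
        )

    # --- novel exons: a block wholly inside an annotated intron, flanked
    # by junctions on both sides
    novel_exon_junctions: set[int] = set()  # indices of junctions consumed
    for j, (gs, ge, _, _) in enumerate(blocks):
        if j == 0 or j == len(blocks) - 1:
            continue
        inside = any(is_ <= gs and ge <= ie for is_, ie in t.introns())
        if not inside:
            continue
        i1 = (blocks[j - 1][1], gs)
        i2 = (ge, blocks[j + 1][0])
        m1, c1 = _safe_motif(genome, chrom, *i1, gene.strand, canon)
        m2, c2 = _safe_motif(genome, chrom, *i2, gene.strand, canon)
        if gene.strand == "-":
            m1, m2 = m2, m1
            c1, c2 = c2, c1
        emit(
            "novel_exon",
            [(gs, ge)],
            f"{m1},{m2}",
            c1 and c2,
            contig_break_at(j - 1),
        )
        novel_exon_junctions.update({j - 1, j})

    # --- junction-wise comparison
    for i in range(len(blocks) - 1):
        if i in novel_exon_junctions:
            continue
        d, a = blocks[i][1], blocks[i + 1][0]
        if a - d < cfg.min_intron_size:
            continue  # sub-intron gaps are indels, handled by the SV caller
        if (d, a) in known_introns:
            continue
        cbreak = contig_break_at(i)
        left_annot = d in t_ends
        right_annot = a in t_starts
        if left_annot and right_annot:
            skipped = [
                (s, e) for s, e in t.exons if d <= s and e <= a
            ]
            if skipped:
                motif, c = _safe_motif(genome, chrom, d, a, gene.strand, canon)
                emit("skipped_exon", skipped, motif, c, cbreak)
            continue
        if left_annot != right_annot:
            if left_annot:
                shift = min(
                    (abs(a - s) for s in t_starts), default=cfg.max_junction_shift + 1
                )
                shifted_is_low_edge = False
            else:
                shift = min(
                    (abs(d - e) for e in t_ends), default=cfg.max_junction_shift + 1
                )
                shifted_is_low_edge = True
            if shift > cfg.max_junction_shift:
                continue
            # low-coordinate intron edge is the donor on '+', acceptor on '-'
            if gene.strand == "+":
                etype = "novel_donor" if shifted_is_low_edge else "novel_acceptor"
            else:
                etype = "novel_acceptor" if shifted_is_low_edge else "novel_donor"
            motif, c = _safe_motif(genome, chrom, d, a, gene.strand, canon)
            emit(etype, [(d, a)], motif, c, cbreak)
            continue
        # neither edge annotated: a new intron entirely inside one exon
        within = any(s < d and a < e for s, e in t.exons)
        if within:
            motif, c = _safe_motif(genome, chrom, d, a, gene.strand, canon)
            emit("novel_intron", [(d, a)], motif, c, cbreak)

    # --- retained introns: one block covering exon-intron-exon
    for gs, ge, cs, ce in blocks:
        for is_, ie in t.introns():
            if gs < is_ and ie < ge:
                motif, _ = _safe_motif(genome, chrom, is_, ie, gene.strand, canon)
                if alignment.strand == "+":
                    cbreak = cs + (is_ - gs)
                else:
                    cbreak = cs + (ge - ie)
                emit("retained_intron", [(is_, ie)], motif, None, cbreak)

    events.sort(key=lambda e: (e.coords[0], e.event_type))
    return events
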