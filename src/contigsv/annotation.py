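"""Spatial lookup of gene models: which gene/transcript/exon is at a locus.

Ties between overlapping genes are broken deterministically:
strand agreement with the aligned fragment, then larger exonic overlap at
the query position, then lexicographic gene_id.
"""
from __future__ import annotations

from typing import Optional

from intervaltree import IntervalTree

from .models import GeneModel, GeneModelSet, TranscriptModel


class GeneIndex:
    def __init__(self, gms: GeneModelSet):
        self.gms = gms
        self._trees: dict[str, IntervalTree] = {}
        for gid, g in gms.genes.items():
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end, gid)

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.gms.genes[iv.data] for iv in tree.at(pos)),
            key=lambda g: g.gene_id,
        )

    def pick_gene(
        self, chrom: str, pos: int, frag_strand: Optional[str] = None
    ) -> Optional[GeneModel]:
        cands = self.genes_at(chrom, pos)
        if not cands:
            return None

        def rank(g: GeneModel):
            in_exon = any(
                s <= pos < e for t in g.transcripts for s, e in t.exons
            )
            exonic = max(
                (sum(e - s for s, e in t.exons) for t in g.transcripts),
                default=0,
            )
            strand_ok = frag_strand is None or g.strand == frag_strand
            return (not strand_ok, not in_exon, -exonic, g.gene_id)

        return min(cands, key=rank)

    # -- transcript / exon helpers ------------------------------------------

    @staticmethod
    def boundary_match(
        t: TranscriptModel, pos: int, orient: str, tol: int = 0
    ) -> Optional[int]:
        """Exon index whose junction-side boundary matches ``pos``.

        Orientation L means the aligned reference ends at ``pos`` (so the
        matching annotated boundary is an exon end); R means it starts
        there (an exon start).  Returns the exon index or None.
        """
        for i, (s, e) in enumerate(t.exons):
            if orient == "L" and abs((e - 1) - pos) <= tol:
                return i
            if orient == "R" and abs(s - pos) <= tol:
                return i
        return None

    @staticmethod
    def exon_index_at(t: TranscriptModel, pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(t.exons):
            if s <= pos < e:
                return i
        return None

    def pick_transcript(
        self, gene: GeneModel, pos: int, orient: Optional[str] = None, tol: int = 0
    ) -> TranscriptModel:
        """Best transcript of ``gene`` for a breakpoint at ``pos``."""

        def rank(t: TranscriptModel):
            bm = (
                self.boundary_match(t, pos, orient, tol) is not None
                if orient
                else False
            )
            in_exon = self.exon_index_at(t, pos) is not None
            in_span = t.start <= pos < t.end
            return (not bm, not in_exon, not in_span, t.transcript_id)

        return min(gene.transcripts, key=rank)

    def adjacent_same_strand(self, g1: GeneModel, g2: GeneModel) -> bool:
        """True when no third gene on the same strand lies between g1 and g2."""
        if g1.chrom != g2.chrom or g1.strand != g2.strand:
            return False
        lo = min(g1.end, g2.end)
        hi = max(g1.start, g2.start)
        if lo > hi:
            return True  # overlapping genes count as adjacent
        tree = self._trees[g1.chrom]
        for iv in tree.overlap(lo, hi):
            g = self.gms.genes[iv.data]
            if g.gene_id in (g1.gene_id, g2.gene_id):
                continue
            if g.strand == g1.strand and g.start >= lo and g.end <= hi:
                return False
        return True
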