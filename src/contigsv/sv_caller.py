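"""Structural-rearrangement calling from split and gapped contig alignments.

Two evidence paths feed one event taxonomy:

* **split (chimeric) alignments** — two or more alignment records for one
  contig.  Consecutive fragments in contig coordinates define a novel
  adjacency joining two reference loci; the adjacency's geometry relative
  to the gene models classifies it as fusion, read-through, ITD or PTD.
* **gapped alignments** — I/D CIGAR operations inside one record yield
  insertions, deletions, tandem duplications (ITDs) and repeat-number
  changes, resolved by comparing the gap sequence with its genomic flanks.

Orientation convention: ``L`` means the aligned reference continues toward
lower coordinates from the breakpoint, ``R`` toward higher ones.  A tandem
duplication therefore shows the signature of an ``L`` breakpoint at a
higher coordinate re-joined to an ``R`` breakpoint at a lower one (on the
gene's forward strand; mirrored on the reverse strand).
"""
from __future__ import annotations

from typing import Optional, Sequence

from .annotation import GeneIndex
from .io_formats import revcomp
from .models import (
    Adjacency,
    Breakpoint,
    ContigAlignment,
    EventCall,
    GeneModel,
    PipelineConfig,
    TranscriptModel,
)


def _gseq(genome, chrom: str, start: int, end: int) -> str:
    """Forward-strand genome substring; empty when out of bounds."""
    if start < 0 or end < start:
        return ""
    seq = genome[chrom]
    s = str(seq[start:end])
    if len(s) != end - start:
        return ""
    return s.upper()


# ---------------------------------------------------------------------------
# adjacency discovery


def find_adjacencies(
    alignments: Sequence[ContigAlignment],
    contig_seq: str,
    config: Optional[PipelineConfig] = None,
) -> list[Adjacency]:
    """Derive novel adjacencies from the split alignments of one contig.

    Fragments shorter than ``min_fragment_len`` aligned bases are ignored.
    Consecutive fragments in contig coordinates produce one adjacency when
    their contig-interval gap is at most ``max_novel_seq`` (unaligned bases
    become the untemplated ``novel_seq``) and their overlap at most
    ``max_homology`` (overlapping bases become ``homology_seq``, with the
    breakpoint placed left-aligned: the lowest genome coordinate on the
    first breakpoint's side).
    """
    cfg = config or PipelineConfig()
    frags = sorted(
        (a for a in alignments if a.aligned_len >= cfg.min_fragment_len),
        key=lambda a: (a.contig_start, a.contig_end, a.chrom, a.genome_start),
    )
    out: list[Adjacency] = []
    for a, b in zip(frags, frags[1:]):
        gap = b.contig_start - a.contig_end
        if gap > cfg.max_novel_seq or -gap > cfg.max_homology:
            continue
        if gap >= 0:
            novel = contig_seq[a.contig_end : b.contig_start].upper()
            homology = ""
            t_a = t_b = 0
            cb1, cb2 = a.contig_end, b.contig_start
        else:
            novel = ""
            homology = contig_seq[b.contig_start : a.contig_end].upper()
            # left-align: minimise breakpoint1's genome coordinate
            split = b.contig_start if a.strand == "+" else a.contig_end
            t_a = a.contig_end - split
            t_b = split - b.contig_start
            cb1 = cb2 = split
        if a.strand == "+":
            bp1 = Breakpoint(a.chrom, a.genome_end - 1 - t_a, "L")
        else:
            bp1 = Breakpoint(a.chrom, a.genome_start + t_a, "R")
        if b.strand == "+":
            bp2 = Breakpoint(b.chrom, b.genome_start + t_b, "R")
        else:
            bp2 = Breakpoint(b.chrom, b.genome_end - 1 - t_b, "L")
        out.append(
            Adjacency(
                contig_id=a.contig_id,
                breakpoint1=bp1,
                breakpoint2=bp2,
                contig_break1=cb1,
                contig_break2=cb2,
                novel_seq=novel,
                homology_seq=homology,
            )
        )
    return out


# ---------------------------------------------------------------------------
# adjacency classification


def _frag_strand(bp: Breakpoint, side: int) -> str:
    """Aligned strand of the fragment that contributed breakpoint ``bp``.

    The first fragment's junction is at its contig end (L on '+', R on '-');
    the second fragment's junction is at its contig start (R on '+').
    """
    if side == 1:
        return "+" if bp.orient == "L" else "-"
    return "+" if bp.orient == "R" else "-"


def _pick_transcript_pair(
    gene: GeneModel, pos_lo: int, pos_hi: int, index: GeneIndex, tol: int
) -> TranscriptModel:
    """Transcript matching both duplication breakpoints best."""

    def rank(t: TranscriptModel):
        b_lo = index.boundary_match(t, pos_lo, "R", tol) is not None
        b_hi = index.boundary_match(t, pos_hi, "L", tol) is not None
        in_lo = index.exon_index_at(t, pos_lo) is not None
        in_hi = index.exon_index_at(t, pos_hi) is not None
        return (-(b_lo + b_hi), -(in_lo + in_hi), t.transcript_id)

    return min(gene.transcripts, key=rank)


def classify_adjacency(
    adj: Adjacency,
    index: GeneIndex,
    config: Optional[PipelineConfig] = None,
    genome=None,
) -> EventCall:
    """Classify one novel adjacency against the gene models.

    Decision order: same-gene duplication geometry (ITD/PTD/duplication),
    then read-through (adjacent same-strand genes joined at annotated exon
    boundaries in transcript order), then fusion.  Adjacencies with no gene
    annotation at either breakpoint are kept but filtered ("intergenic").
    """
    cfg = config or PipelineConfig()
    tol = cfg.exon_boundary_tolerance
    bp1, bp2 = adj.breakpoint1, adj.breakpoint2
    s1, s2 = _frag_strand(bp1, 1), _frag_strand(bp2, 2)
    g1 = index.pick_gene(bp1.chrom, bp1.pos, s1)
    g2 = index.pick_gene(bp2.chrom, bp2.pos, s2)

    ev = EventCall(
        event_type="fusion",
        contig_ids=[adj.contig_id],
        adjacency=adj,
        chrom1=bp1.chrom,
        pos1=bp1.pos,
        orient1=bp1.orient,
        chrom2=bp2.chrom,
        pos2=bp2.pos,
        orient2=bp2.orient,
        novel_seq=adj.novel_seq,
        homology_seq=adj.homology_seq,
        contig_break1=adj.contig_break1,
        contig_break2=adj.contig_break2,
    )

    if g1 is None and g2 is None:
        ev.filter_status = "intergenic"
        return ev
    if g1 is None or g2 is None:
        present, pos, orient = (
            (g2, bp2.pos, bp2.orient) if g1 is None else (g1, bp1.pos, bp1.orient)
        )
        t = index.pick_transcript(present, pos, orient, tol)
        if g1 is None:
            ev.gene3, ev.transcript3 = present.gene_id, t.transcript_id
        else:
            ev.gene5, ev.transcript5 = present.gene_id, t.transcript_id
        ev.filter_status = "partner_intergenic"
        return ev

    # ---- same-gene duplication geometry ----------------------------------
    if g1.gene_id == g2.gene_id and bp1.chrom == bp2.chrom and s1 == s2:
        dup = (bp1.orient, bp2.orient) == ("L", "R") and bp1.pos > bp2.pos or (
            bp1.orient,
            bp2.orient,
        ) == ("R", "L") and bp2.pos > bp1.pos
        if dup:
            return _classify_duplication(adj, ev, g1, index, cfg)

    # ---- two genes: read-through or fusion -------------------------------
    if g1.gene_id != g2.gene_id:
        return _classify_two_gene(adj, ev, g1, g2, s1, s2, index, cfg)

    # same gene, non-duplication geometry (e.g. antisense self-join):
    # reported as a fusion-type adjacency within one gene, never PASS-fused
    t = index.pick_transcript(g1, bp1.pos, bp1.orient, tol)
    ev.gene5 = ev.gene3 = g1.gene_id
    ev.transcript5 = ev.transcript3 = t.transcript_id
    ev.filter_status = "same_gene_rearrangement"
    return ev


def _classify_duplication(
    adj: Adjacency, ev: EventCall, gene: GeneModel, index: GeneIndex, cfg: PipelineConfig
) -> EventCall:
    bp1, bp2 = adj.breakpoint1, adj.breakpoint2
    pos_lo, pos_hi = min(bp1.pos, bp2.pos), max(bp1.pos, bp2.pos)
    tol = cfg.exon_boundary_tolerance
    t = _pick_transcript_pair(gene, pos_lo, pos_hi, index, tol)
    ev.gene5 = ev.gene3 = gene.gene_id
    ev.transcript5 = ev.transcript3 = t.transcript_id

    b_lo = index.boundary_match(t, pos_lo, "R", tol)
    b_hi = index.boundary_match(t, pos_hi, "L", tol)
    span = (pos_lo, pos_hi + 1)
    full_exons = [
        i for i, (s, e) in enumerate(t.exons) if s >= span[0] and e <= span[1]
    ]
    ex_lo = index.exon_index_at(t, pos_lo)
    ex_hi = index.exon_index_at(t, pos_hi)

    if b_lo is not None and b_hi is not None and full_exons:
        ev.event_type = "PTD"
        ev.at_exon_boundary = "both"
        nums = sorted(t.exon_number(i) for i in full_exons)
        ev.exons_involved = [nums[0], nums[-1]]
    elif (
        ex_lo is not None
        and ex_lo == ex_hi
        and b_lo is None
        and b_hi is None
    ) or not full_exons:
        ev.event_type = "ITD"
        ev.at_exon_boundary = "none"
        if ex_lo is not None:
            ev.exons_involved = [t.exon_number(ex_lo)]
    else:
        ev.event_type = "duplication"
        ev.at_exon_boundary = "one" if (b_lo is None) != (b_hi is None) else "none"
    # duplicated length in spliced coordinates (introns inside a PTD span
    # do not contribute to the transcript)
    tl = t.genome_to_transcript(pos_lo)
    th = t.genome_to_transcript(pos_hi)
    c0, c1 = t.cds_start_tpos(), t.cds_end_tpos()
    if tl is None or th is None or c0 is None:
        ev.in_frame = None
    else:
        lo_t, hi_t = sorted((tl, th))
        dup_len = hi_t - lo_t + 1 + len(adj.novel_seq)
        in_cds = c0 <= lo_t and hi_t < c1
        ev.in_frame = (dup_len % 3 == 0) if in_cds else None
    return ev


def _classify_two_gene(
    adj: Adjacency,
    ev: EventCall,
    g1: GeneModel,
    g2: GeneModel,
    s1: str,
    s2: str,
    index: GeneIndex,
    cfg: PipelineConfig,
) -> EventCall:
    bp1, bp2 = adj.breakpoint1, adj.breakpoint2
    tol = cfg.exon_boundary_tolerance
    t1 = index.pick_transcript(g1, bp1.pos, bp1.orient, tol)
    t2 = index.pick_transcript(g2, bp2.pos, bp2.orient, tol)

    # which side contributes the 5' (upstream in transcript orientation) part:
    # a fragment aligned in its gene's sense reads that gene 5'->3' along the
    # contig, so the sense fragment earlier on the contig is the 5' side.
    sense1 = s1 == g1.strand
    sense2 = s2 == g2.strand
    five_is_first = sense1 if (sense1 or not sense2) else False

    if five_is_first:
        ev.gene5, ev.transcript5 = g1.gene_id, t1.transcript_id
        ev.gene3, ev.transcript3 = g2.gene_id, t2.transcript_id
        bp5, t5, bp3, t3 = bp1, t1, bp2, t2
    else:
        ev.gene5, ev.transcript5 = g2.gene_id, t2.transcript_id
        ev.gene3, ev.transcript3 = g1.gene_id, t1.transcript_id
        bp5, t5, bp3, t3 = bp2, t2, bp1, t1

    m5 = index.boundary_match(t5, bp5.pos, bp5.orient, tol)
    m3 = index.boundary_match(t3, bp3.pos, bp3.orient, tol)
    n_match = (m5 is not None) + (m3 is not None)
    ev.at_exon_boundary = {2: "both", 1: "one", 0: "none"}[n_match]
    e5 = index.exon_index_at(t5, bp5.pos)
    e3 = index.exon_index_at(t3, bp3.pos)
    ev.exons_involved = [
        t5.exon_number(e5) if e5 is not None else 0,
        t3.exon_number(e3) if e3 is not None else 0,
    ]

    gene5 = index.gms.genes[ev.gene5]
    gene3 = index.gms.genes[ev.gene3]
    read_through = (
        index.adjacent_same_strand(gene5, gene3)
        and n_match == 2
        and (
            (gene5.strand == "+" and bp5.pos < bp3.pos)
            or (gene5.strand == "-" and bp5.pos > bp3.pos)
        )
    )
    ev.event_type = "read_through" if read_through else "fusion"
    ev.in_frame = _fusion_frame(t5, bp5.pos, t3, bp3.pos, len(adj.novel_seq))
    return ev


# ---------------------------------------------------------------------------
# frame checking


def _fusion_frame(
    t5: TranscriptModel, pos5: int, t3: TranscriptModel, pos3: int, insert_len: int
) -> Optional[bool]:
    """Reading-frame compatibility across a chimeric junction.

    Computed in spliced coordinates: the 5' side contributes
    ``upstream_len`` coding bases (CDS start through the breakpoint base);
    the junction lands at the 3' transcript's CDS phase.  In frame iff the
    dangling codon bases match: (upstream_len + insert) mod 3 == phase3.
    """
    cds5 = t5.cds_start_tpos()
    cds3 = t3.cds_start_tpos()
    if cds5 is None or cds3 is None:
        return None
    tp5 = t5.genome_to_transcript(pos5)
    tp3 = t3.genome_to_transcript(pos3)
    if tp5 is None or tp3 is None:
        return None
    cds5_end = t5.cds_end_tpos()
    cds3_end = t3.cds_end_tpos()
    if not (cds5 <= tp5 < cds5_end) or not (cds3 <= tp3 < cds3_end):
        return None
    upstream_len = tp5 - cds5 + 1
    phase3 = (tp3 - cds3) % 3
    return (upstream_len + insert_len) % 3 == phase3


def check_frame(event: EventCall, gms, genome=None) -> Optional[bool]:
    """Frame status of an event (True/False, or None when undetermined).

    Fusions and read-throughs compare the 5' coding length against the 3'
    CDS phase; length-changing events within one gene are in frame iff the
    net inserted-minus-deleted length is a multiple of three.  None when a
    transcript lacks CDS or a breakpoint falls outside it.
    """
    if event.event_type in ("fusion", "read_through"):
        if event.transcript5 is None or event.transcript3 is None:
            return None
        t5 = gms.get_transcript(event.transcript5)
        t3 = gms.get_transcript(event.transcript3)
        # identify which recorded side is 5': the one inside gene5's span
        g5 = gms.genes[event.gene5]
        if g5.chrom == event.chrom1 and g5.start <= event.pos1 < g5.end:
            pos5, pos3 = event.pos1, event.pos2
        else:
            pos5, pos3 = event.pos2, event.pos1
        return _fusion_frame(t5, pos5, t3, pos3, len(event.novel_seq))
    return event.in_frame


# ---------------------------------------------------------------------------
# gapped events


def _minimal_unit(seq: str, max_unit: int) -> Optional[str]:
    """Smallest repeat unit (length <= max_unit, shorter than seq) tiling seq."""
    n = len(seq)
    for u in range(1, min(max_unit, n - 1) + 1):
        if n % u == 0 and seq == seq[:u] * (n // u):
            return seq[:u]
    return None


def _flanked_by_unit(genome, chrom: str, pos: int, end: int, unit: str) -> bool:
    u = len(unit)
    return (
        _gseq(genome, chrom, pos - u, pos) == unit
        or _gseq(genome, chrom, end, end + u) == unit
    )


def call_gapped_events(
    alignment: ContigAlignment,
    contig_seq: str,
    genome,
    index: GeneIndex,
    config: Optional[PipelineConfig] = None,
) -> list[EventCall]:
    """Classify the I/D gaps of one alignment record.

    Insertions that decompose into a short repeat unit also present in the
    genomic flank are repeat expansions; insertions duplicating their
    immediate flank are duplications (promoted to ITD inside an exon at
    ``min_itd_len`` or longer); deletions removing whole copies of a
    flanking repeat unit are repeat contractions.  Everything else stays a
    plain insertion/deletion.  Events outside annotated exons are kept but
    flagged (filter_status "intronic"/"intergenic").
    """
    cfg = config or PipelineConfig()
    out: list[EventCall] = []
    chrom = alignment.chrom
    for gap in alignment.gaps:
        pos = gap.genome_pos
        gene = index.pick_gene(chrom, pos, alignment.strand)
        t = index.pick_transcript(gene, pos, None, 0) if gene else None
        exon_i = index.exon_index_at(t, pos) if t else None

        ev = EventCall(
            event_type=gap.kind,
            contig_ids=[alignment.contig_id],
            chrom1=chrom,
            pos1=pos - 1,
            orient1="L",
            chrom2=chrom,
            pos2=pos if gap.kind == "insertion" else pos + gap.length,
            orient2="R",
            gene5=gene.gene_id if gene else None,
            gene3=gene.gene_id if gene else None,
            transcript5=t.transcript_id if t else None,
            transcript3=t.transcript_id if t else None,
            contig_break1=gap.contig_pos,
            contig_break2=gap.contig_pos
            + (gap.length if gap.kind == "insertion" else 0),
        )
        if exon_i is not None:
            ev.exons_involved = [t.exon_number(exon_i)]
            ev.at_exon_boundary = "none"

        if gap.kind == "insertion":
            # gap sequences are held in contig orientation; compare on the
            # genome forward strand
            gseq = (
                revcomp(gap.inserted_seq)
                if alignment.strand == "-"
                else gap.inserted_seq
            ).upper()
            ev.novel_seq = gseq
            unit = _minimal_unit(gseq, cfg.max_repeat_unit)
            if unit is not None and _flanked_by_unit(genome, chrom, pos, pos, unit):
                ev.event_type = "repeat_expansion"
            else:
                left = _gseq(genome, chrom, pos - gap.length, pos)
                right = _gseq(genome, chrom, pos, pos + gap.length)
                if not left and not right:
                    ev.at_exon_boundary = "NA"  # no usable flank at contig edge
                elif gseq in (left, right) and gseq:
                    ev.event_type = "duplication"
                    if exon_i is not None and gap.length >= cfg.min_itd_len:
                        ev.event_type = "ITD"
            net = gap.length
        else:
            removed = _gseq(genome, chrom, pos, pos + gap.length)
            unit = None
            n = gap.length
            for u in range(1, min(cfg.max_repeat_unit, n) + 1):
                if n % u == 0 and removed == removed[:u] * (n // u):
                    unit = removed[:u]
                    break
            if unit is not None and _flanked_by_unit(
                genome, chrom, pos, pos + gap.length, unit
            ):
                ev.event_type = "repeat_contraction"
            net = -gap.length

        in_cds = (
            t is not None
            and t.cds_start is not None
            and exon_i is not None
            and t.cds_start <= pos < t.cds_end
        )
        ev.in_frame = (net % 3 == 0) if in_cds else None
        if gene is None:
            ev.filter_status = "intergenic"
        elif exon_i is None:
            ev.filter_status = "intronic"
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# merging and filtering


def merge_and_filter(
    events: Sequence[EventCall],
    restrict_exon_boundary: bool = True,
    max_dist: int = 0,
) -> list[EventCall]:
    """Merge identical events across contigs and apply the boundary filter.

    Events sharing (type, chrom1, pos1, chrom2, pos2) after canonical side
    ordering merge into one call with concatenated contig ids; read support
    is summed later at the read level.  Near-duplicates farther apart than
    ``max_dist`` (default 0: only exact matches merge) stay separate, so
    distinct breakpoint alleles of one gene pair remain distinct events.
    With ``restrict_exon_boundary``, fusions whose breakpoints are both
    away from annotated exon boundaries are kept but filtered
    ("not_exon_boundary").
    """
    merged: dict[tuple, EventCall] = {}
    for ev in events:
        s1 = (ev.chrom1, ev.pos1)
        s2 = (ev.chrom2, ev.pos2)
        lo, hi = sorted([s1, s2])
        # the untemplated insert distinguishes junction alleles that share
        # breakpoint coordinates
        key = (ev.event_type, *lo, *hi, ev.novel_seq)
        if key in merged:
            ids = set(merged[key].contig_ids) | set(ev.contig_ids)
            merged[key].contig_ids = sorted(ids)
        else:
            ev.contig_ids = sorted(set(ev.contig_ids))
            merged[key] = ev
    out = [merged[k] for k in sorted(merged)]
    if restrict_exon_boundary:
        for ev in out:
            if (
                ev.event_type == "fusion"
                and ev.at_exon_boundary == "none"
                and ev.filter_status == "PASS"
            ):
                ev.filter_status = "not_exon_boundary"
    return out
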