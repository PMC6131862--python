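"""Readers and writers for the standard formats the pipeline touches.

One internal coordinate convention (0-based half-open, forward strand) is
used everywhere; GTF (1-based inclusive) and SAM (1-based) are converted
here at the boundary.  Event tables are emitted 1-based (TSV) and 0-based
half-open (BEDPE).
"""
from __future__ import annotations

import re
import sys
import warnings
from typing import Iterable, Optional, Union

import pysam

from .models import (
    Adjacency,
    ContigAlignment,
    EventCall,
    GapRecord,
    GeneModel,
    GeneModelSet,
    SpliceEventCall,
    TranscriptModel,
)

_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]+)"?\s*;?')

EVENT_TSV_COLUMNS = [
    "event_type",
    "chrom1",
    "pos1",
    "orient1",
    "chrom2",
    "pos2",
    "orient2",
    "gene1",
    "transcript1",
    "gene2",
    "transcript2",
    "contig_ids",
    "novel_seq",
    "microhomology_seq",
    "in_frame",
    "exons_involved",
    "spanning_reads",
    "filter_status",
    "splice_motif",
    "canonical",
]


# ---------------------------------------------------------------------------
# GTF


def _parse_attributes(attr_col: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_col))
    if not attrs:
        raise ValueError(f"GTF line {lineno}: malformed attribute column: {attr_col!r}")
    return attrs


def parse_gene_models(gtf_path: str) -> GeneModelSet:
    """Parse a GTF into a :class:`GeneModelSet`.

    Exon features must carry ``gene_id`` and ``transcript_id`` attributes;
    CDS features are optional.  Both quoted and unquoted attribute values
    are accepted.  GTF 1-based inclusive coordinates are converted to
    0-based half-open.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gid, gname, chrom, strand)

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"GTF line {lineno}: expected 9 columns")
            chrom, _, feature, start, end, _, strand, _, attr_col = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attributes(attr_col, lineno)
            if "transcript_id" not in attrs:
                raise ValueError(f"GTF line {lineno}: {feature} without transcript_id")
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line {lineno}: {feature} without gene_id")
            tid = attrs["transcript_id"]
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
            meta.setdefault(
                tid,
                (attrs["gene_id"], attrs.get("gene_name", attrs["gene_id"]), chrom, strand),
            )

    gms = GeneModelSet()
    for tid, ivs in exons.items():
        gid, gname, chrom, strand = meta[tid]
        tm = TranscriptModel(transcript_id=tid, exons=sorted(ivs), strand=strand)
        if tid in cds:
            tm.cds_start = min(s for s, _ in cds[tid])
            tm.cds_end = max(e for _, e in cds[tid])
        if gid not in gms.genes:
            gms.genes[gid] = GeneModel(gene_id=gid, gene_name=gname, chrom=chrom, strand=strand)
        gms.genes[gid].transcripts.append(tm)
    for g in gms.genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return gms


def write_gene_models(gms: GeneModelSet, gtf_path: str) -> None:
    """Emit a GeneModelSet back to GTF (round-trip safe on coordinates)."""
    lines = []
    for gid in sorted(gms.genes):
        g = gms.genes[gid]
        for t in g.transcripts:
            for i, (s, e) in enumerate(t.exons):
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_name "{g.gene_name}"; exon_number "{t.exon_number(i)}";'
                )
                lines.append(
                    f"{g.chrom}\tcontigsv\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
                )
            if t.cds_start is not None:
                for s, e in t.exons:
                    cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                    if cs < ce:
                        attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                        lines.append(
                            f"{g.chrom}\tcontigsv\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t.\t{attrs}"
                        )
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# SAM/BAM contig-to-genome alignments

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M I S = X
_FULL_LEN_OPS = {0, 1, 4, 5, 7, 8}  # + hard clips for full-contig length

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _decode_record(
    rec: pysam.AlignedSegment,
    min_intron_size: int,
    order: int,
    contig_len_override: Optional[int] = None,
) -> Optional[ContigAlignment]:
    cig = rec.cigartuples
    if cig is None:
        warnings.warn(f"record {rec.query_name}: CIGAR '*', skipped")
        return None
    full_len = sum(l for op, l in cig if op in _FULL_LEN_OPS)
    if contig_len_override is not None:
        full_len = contig_len_override
    h_lead = cig[0][1] if cig[0][0] == 5 else 0
    seq = rec.query_sequence or ""

    blocks: list[tuple[int, int, int, int]] = []
    gaps: list[GapRecord] = []
    gpos = rec.reference_start
    qpos = 0  # full-contig coordinate in SAM orientation
    cur: Optional[list[int]] = None  # [gstart, gend, cstart, cend]

    def flush():
        nonlocal cur
        if cur is not None:
            blocks.append(tuple(cur))
            cur = None

    for op, length in cig:
        if op in (4, 5):  # soft/hard clip
            qpos += length
        elif op in (0, 7, 8):  # aligned block
            if cur is not None and cur[1] == gpos and cur[3] == qpos:
                cur[1] += length
                cur[3] += length
            else:
                flush()
                cur = [gpos, gpos + length, qpos, qpos + length]
            gpos += length
            qpos += length
        elif op == 1:  # insertion
            ins = seq[qpos - h_lead : qpos - h_lead + length] if seq else ""
            gaps.append(GapRecord("insertion", gpos, qpos, length, ins))
            flush()
            qpos += length
        elif op == 2:  # deletion; intron-sized deletions become block splits
            if length >= min_intron_size:
                flush()
            else:
                gaps.append(GapRecord("deletion", gpos, qpos, length))
                flush()
            gpos += length
        elif op == 3:  # N: splice-like skip, always a new block
            flush()
            gpos += length
        # P (6) ignored
    flush()

    strand = "-" if rec.is_reverse else "+"
    if strand == "-":
        # re-express contig coordinates in the original (FASTA) orientation
        blocks = [(gs, ge, full_len - ce, full_len - cs) for gs, ge, cs, ce in blocks]
        blocks.sort(key=lambda b: b[2])
        for gap in gaps:
            if gap.kind == "insertion":
                gap.contig_pos = full_len - gap.contig_pos - gap.length
                gap.inserted_seq = revcomp(gap.inserted_seq)
            else:
                gap.contig_pos = full_len - gap.contig_pos
        gaps.sort(key=lambda g: g.contig_pos)

    return ContigAlignment(
        contig_id=rec.query_name,
        contig_len=full_len,
        chrom=rec.reference_name,
        strand=strand,
        blocks=blocks,
        gaps=gaps,
        mapq=rec.mapping_quality,
        is_supplementary=rec.is_supplementary,
        alignment_order_on_contig=order,
    )


def parse_contig_alignments(
    aln_path: str,
    contig_fasta=None,
    min_intron_size: int = 20,
) -> dict[str, list[ContigAlignment]]:
    """Decode contig-to-genome SAM/BAM into per-contig alignment groups.

    ``contig_fasta`` (a :class:`pyfaidx.Fasta` or mapping of id -> sequence)
    supplies full contig lengths for hard-clipped records.  Records are
    grouped by contig and ordered by the contig coordinate of their aligned
    span.
    """
    groups: dict[str, list[ContigAlignment]] = {}
    mode = "rb" if str(aln_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(aln_path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            override = None
            if contig_fasta is not None:
                try:
                    override = len(contig_fasta[rec.query_name])
                except KeyError:
                    raise KeyError(f"contig {rec.query_name} absent from contig FASTA")
            aln = _decode_record(rec, min_intron_size, order=0, contig_len_override=override)
            if aln is None:
                continue
            groups.setdefault(aln.contig_id, []).append(aln)
    for alns in groups.values():
        alns.sort(key=lambda a: (a.contig_start, a.contig_end, a.chrom, a.genome_start))
        for i, a in enumerate(alns):
            a.alignment_order_on_contig = i
    return groups


# ---------------------------------------------------------------------------
# event tables


def _fmt_bool(v: Optional[bool]) -> str:
    return "NA" if v is None else ("True" if v else "False")


def _event_row(ev: Union[EventCall, SpliceEventCall]) -> list[str]:
    if isinstance(ev, SpliceEventCall):
        c0 = ev.coords[0]
        c1 = ev.coords[-1]
        return [
            ev.event_type,
            ev.chrom,
            str(c0[0] + 1),
            "NA",
            ev.chrom,
            str(c1[1]),
            "NA",
            ev.gene,
            ev.transcript,
            ev.gene,
            ev.transcript,
            ",".join(sorted(ev.contig_ids)),
            "",
            "",
            "NA",
            "",
            str(ev.junction_depth) if ev.junction_depth >= 0 else "NA",
            ev.filter_status,
            ev.splice_motif,
            _fmt_bool(ev.canonical),
        ]
    # order the two loci: (chrom1,pos1) <= (chrom2,pos2)
    side1 = (ev.chrom1, ev.pos1, ev.orient1, ev.gene5, ev.transcript5)
    side2 = (ev.chrom2, ev.pos2, ev.orient2, ev.gene3, ev.transcript3)
    if ev.chrom2 and (ev.chrom2, ev.pos2) < (ev.chrom1, ev.pos1):
        side1, side2 = side2, side1
    return [
        ev.event_type,
        side1[0],
        str(side1[1] + 1),
        side1[2] or "NA",
        side2[0] or side1[0],
        str(side2[1] + 1) if side2[1] >= 0 else str(side1[1] + 1),
        side2[2] or "NA",
        side1[3] or "NA",
        side1[4] or "NA",
        side2[3] or "NA",
        side2[4] or "NA",
        ",".join(sorted(ev.contig_ids)),
        ev.novel_seq,
        ev.homology_seq,
        _fmt_bool(ev.in_frame),
        ",".join(str(x) for x in ev.exons_involved),
        str(ev.spanning_reads) if ev.spanning_reads >= 0 else "NA",
        ev.filter_status,
        "NA",
        "NA",
    ]


def _sort_key(row: list[str]) -> tuple:
    return (row[0], row[1], int(row[2]), row[4], int(row[5]), row[11])


def write_events(
    events: Iterable[Union[EventCall, SpliceEventCall]],
    tsv_path: str,
    bedpe_path: Optional[str] = None,
) -> None:
    """Write the event table (TSV, 1-based) and adjacency BEDPE.

    Output is deterministic: rows are stably sorted on
    (event_type, chrom1, pos1, chrom2, pos2, contig_ids), so permuting the
    input event list leaves the files byte-identical.
    """
    events = list(events)
    rows = sorted((_event_row(ev) for ev in events), key=_sort_key)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(EVENT_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    if bedpe_path is None:
        return
    bed_rows = []
    for ev in events:
        if isinstance(ev, SpliceEventCall) or ev.adjacency is None:
            continue
        s1 = (ev.chrom1, ev.pos1, ev.orient1)
        s2 = (ev.chrom2, ev.pos2, ev.orient2)
        if (s2[0], s2[1]) < (s1[0], s1[1]):
            s1, s2 = s2, s1
        name = f"{ev.event_type}:{','.join(sorted(ev.contig_ids))}"
        # strand encodes orientation: '+' = reference continues left (L)
        bed_rows.append(
            (
                s1[0], s1[1], s1[1] + 1,
                s2[0], s2[1], s2[1] + 1,
                name, ".",
                "+" if s1[2] == "L" else "-",
                "+" if s2[2] == "L" else "-",
            )
        )
    bed_rows.sort()
    with open(bedpe_path, "w") as fh:
        for r in bed_rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# small sequence-file helpers (used by the synthetic generator and CLI)


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(records: Iterable[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def iter_fastq(path: str):
    import gzip

    from Bio import SeqIO

    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()
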