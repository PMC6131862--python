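"""Self-contained synthetic test universes for the variant-calling pipeline.

The generator produces a random multi-chromosome genome carrying
non-overlapping multi-exon genes on both strands with canonical GT-AG
introns and a central ORF as CDS, plants any of the fourteen structural
and splicing event classes into spliced transcripts, emits the variant
transcripts as contigs together with oracle contig-to-genome SAM records
derived from the construction trace (no sequence search is performed),
and simulates error-bearing paired-end reads with their reads-to-contig
placements.  Every output is deterministic for a fixed seed.

Three cryptic features are embedded in every gene at generation time so
repeat and splice events have realistic substrate:

* a microsatellite tract (short unit, several copies) inside one exon,
  for repeat expansions/contractions;
* a GT..AG segment inside one wide exon, usable as a cryptic intron;
* a cryptic exon inside one intron, positioned so that including it
  creates two new canonical GT-AG introns.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .io_formats import revcomp, write_fasta, write_gene_models
from .models import GeneModel, GeneModelSet, TranscriptModel

_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]
_REPEAT_UNITS = ["AG", "CA", "CT", "TG", "AT"]

_CRYPTIC_INTRON_LEN = 40
_CRYPTIC_EXON_LEN = 60


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneBuild:
    """Construction trace of one generated gene (transcript orientation)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    g0: int  # genomic start of the gene body on the forward strand
    length: int  # unspliced gene length
    exon_local: list[tuple[int, int]]  # gene-local, transcript orientation
    cds_t: tuple[int, int]  # spliced-coordinate CDS interval
    repeat: tuple[int, int, str, int]  # exon_idx, offset, unit, copies
    cryptic_intron: tuple[int, int, int]  # exon_idx, offset, length
    cryptic_exon: Optional[tuple[int, int, int]]  # intron_idx, offset, length

    @property
    def n_exons(self) -> int:
        return len(self.exon_local)

    def intron_local(self) -> list[tuple[int, int]]:
        return [
            (self.exon_local[i][1], self.exon_local[i + 1][0])
            for i in range(self.n_exons - 1)
        ]

    def local_iv_to_genome(self, a: int, b: int) -> tuple[int, int]:
        """Gene-local (transcript-orientation) interval -> genomic interval."""
        if self.strand == "+":
            return self.g0 + a, self.g0 + b
        return self.g0 + self.length - b, self.g0 + self.length - a

    def exon_genome_iv(self, j: int) -> tuple[int, int]:
        return self.local_iv_to_genome(*self.exon_local[j])


@dataclass
class Segment:
    """One transcript-space building block of a planted contig.

    ``kind`` "ref" maps genome sequence, "ins" carries untemplated bases,
    and "break" forces a fragment boundary in the oracle alignment (used
    at chimeric junctions that would otherwise be genome-collinear, e.g.
    read-throughs).
    """

    kind: str  # "ref" | "ins" | "break"
    chrom: str = ""
    gstart: int = 0
    gend: int = 0
    strand: str = "+"
    seq: str = ""  # untemplated bases (kind == "ins")

    def tlen(self) -> int:
        if self.kind == "break":
            return 0
        return len(self.seq) if self.kind == "ins" else self.gend - self.gstart


@dataclass
class TruthRecord:
    """Exact expected call for one planted event."""

    event_type: str
    contig_id: str
    gene5: Optional[str] = None
    gene3: Optional[str] = None
    chrom1: str = ""
    pos1: int = -1
    orient1: str = ""
    chrom2: str = ""
    pos2: int = -1
    orient2: str = ""
    coords: list[tuple[int, int]] = field(default_factory=list)
    in_frame: Optional[bool] = None
    at_exon_boundary: str = ""
    exons_involved: list[int] = field(default_factory=list)
    novel_seq: str = ""
    splice_motif: str = ""
    canonical: Optional[bool] = None


@dataclass
class PlantedContig:
    contig_id: str
    seq: str
    segments: list[Segment]
    truths: list[TruthRecord]


@dataclass
class Reference:
    genome: dict[str, str]
    gms: GeneModelSet
    transcripts: dict[str, str]  # transcript_id -> spliced sequence
    builds: dict[str, GeneBuild]  # gene_id -> build trace

    def gene_ids(self) -> list[str]:
        return sorted(self.builds)

    def write(self, outdir: str) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "gtf": os.path.join(outdir, "genes.gtf"),
            "transcripts": os.path.join(outdir, "transcripts.fa"),
        }
        write_fasta(sorted(self.genome.items()), paths["genome"])
        write_gene_models(self.gms, paths["gtf"])
        write_fasta(sorted(self.transcripts.items()), paths["transcripts"])
        return paths


@dataclass
class EventSpec:
    """Parameters of one event to plant (all coordinates 1-based exon/intron
    numbers in transcript orientation)."""

    kind: str
    gene: str = ""
    gene3: str = ""
    exon: int = 2
    exon3: int = 2
    exons: list[int] = field(default_factory=list)
    length: int = 45
    shift: int = 13
    insert_len: int = 0
    boundary5: bool = True
    boundary3: bool = True
    offset5: int = 13
    offset3: int = 17
    copies: int = 2
    intron: int = 1
    donor_shift: int = 0


# ---------------------------------------------------------------------------
# reference generation


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def generate_reference(
    n_genes: int = 20,
    exons_per_gene_range: tuple[int, int] = (3, 5),
    exon_len_range: tuple[int, int] = (150, 300),
    intron_len_range: tuple[int, int] = (100, 400),
    rng_seed: int = 0,
    n_chroms: int = 2,
    intergenic_range: tuple[int, int] = (400, 900),
) -> Reference:
    """Generate a toy genome with multi-exon genes on both strands.

    Every intron starts GT and ends AG in transcript orientation (the
    forward-strand text is strand-adjusted), a central ORF provides the
    CDS, and each gene embeds the cryptic substrate features described in
    the module docstring.  Deterministic for a fixed ``rng_seed``.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if exon_len_range[0] < 2 * _CRYPTIC_INTRON_LEN + 20:
        raise ValueError(
            f"minimum exon length must be >= {2 * _CRYPTIC_INTRON_LEN + 20}"
        )
    if intron_len_range[1] < _CRYPTIC_EXON_LEN + 40:
        raise ValueError(
            f"maximum intron length must be >= {_CRYPTIC_EXON_LEN + 40}"
        )
    rng = np.random.default_rng(rng_seed)
    chrom_parts: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(n_chroms)}
    chrom_cursor: dict[str, int] = {c: 0 for c in chrom_parts}

    gms = GeneModelSet()
    transcripts: dict[str, str] = {}
    builds: dict[str, GeneBuild] = {}

    for gi in range(n_genes):
        gene_id = f"GENE{gi:03d}"
        tid = f"{gene_id}.t1"
        chrom = f"chr{(gi % n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        exon_lens = [
            int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            for _ in range(n_ex)
        ]
        intron_lens = [
            int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
            for _ in range(n_ex - 1)
        ]
        # ensure one intron can host the cryptic exon
        host_intron = int(np.argmax(intron_lens)) if intron_lens else None
        if host_intron is not None and intron_lens[host_intron] < _CRYPTIC_EXON_LEN + 40:
            intron_lens[host_intron] = _CRYPTIC_EXON_LEN + 40

        exon_seqs = [_rand_dna(rng, L) for L in exon_lens]

        # CDS: central ORF over the spliced sequence
        spliced_len = sum(exon_lens)
        c0 = 30
        c_len = ((spliced_len - c0 - 30) // 3) * 3
        if c_len < 60:
            raise ValueError("exon ranges too small to fit a CDS")
        c1 = c0 + c_len
        n_codons = c_len // 3
        body = [
            "ATG",
            *(
                _CODONS[i]
                for i in rng.integers(0, len(_CODONS), n_codons - 2)
            ),
            "TAA",
        ]
        cds_seq = "".join(body)

        def splice_overwrite(exseqs: list[str], lens: list[int], start: int, text: str):
            """Overwrite spliced positions [start, start+len(text)) in place."""
            off = 0
            pos = start
            remaining = text
            out = list(exseqs)
            for j, L in enumerate(lens):
                if not remaining:
                    break
                if pos < off + L and pos + len(remaining) > off:
                    a = max(pos, off) - off
                    take = min(off + L, pos + len(remaining)) - (off + a)
                    chunk = remaining[:take]
                    out[j] = out[j][:a] + chunk + out[j][a + take :]
                    remaining = remaining[take:]
                    pos += take
                off += L
            return out

        exon_seqs = splice_overwrite(exon_seqs, exon_lens, c0, cds_seq)

        # cryptic intron inside the widest exon
        ci_exon = int(np.argmax(exon_lens))
        ci_off = exon_lens[ci_exon] // 2 - _CRYPTIC_INTRON_LEN // 2
        ci = (
            "GT" + _rand_dna(rng, _CRYPTIC_INTRON_LEN - 4) + "AG"
        )
        exon_seqs[ci_exon] = (
            exon_seqs[ci_exon][:ci_off]
            + ci
            + exon_seqs[ci_exon][ci_off + _CRYPTIC_INTRON_LEN :]
        )

        # microsatellite tract inside a different exon
        rp_exon = 0 if ci_exon != 0 else 1
        unit = _REPEAT_UNITS[int(rng.integers(0, len(_REPEAT_UNITS)))]
        copies = 6
        tract = unit * copies
        rp_off = exon_lens[rp_exon] // 3
        ex = exon_seqs[rp_exon]
        # keep the tract's minimal-unit decomposition unambiguous: the bases
        # flanking the tract must not extend the repeat
        pre = "C" if unit[-1] != "C" else "G"
        post = "C" if unit[0] != "C" else "G"
        exon_seqs[rp_exon] = (
            ex[: rp_off - 1] + pre + tract + post + ex[rp_off + len(tract) + 1 :]
        )

        # intron sequences (transcript orientation): canonical GT..AG
        intron_seqs = []
        cryptic_exon = None
        for ii, L in enumerate(intron_lens):
            if ii == host_intron:
                f1 = 16
                f2 = L - 8 - f1 - _CRYPTIC_EXON_LEN
                seg = _rand_dna(rng, _CRYPTIC_EXON_LEN)
                intron_seqs.append(
                    "GT" + _rand_dna(rng, f1) + "AG" + seg
                    + "GT" + _rand_dna(rng, f2) + "AG"
                )
                cryptic_exon = (ii, 4 + f1, _CRYPTIC_EXON_LEN)
            else:
                intron_seqs.append("GT" + _rand_dna(rng, L - 4) + "AG")

        # assemble gene text and local coordinates (transcript orientation)
        parts = []
        exon_local = []
        cursor = 0
        for j in range(n_ex):
            exon_local.append((cursor, cursor + exon_lens[j]))
            parts.append(exon_seqs[j])
            cursor += exon_lens[j]
            if j < n_ex - 1:
                parts.append(intron_seqs[j])
                cursor += intron_lens[j]
        gene_text = "".join(parts)
        glen = len(gene_text)

        spacer = int(rng.integers(*intergenic_range))
        chrom_parts[chrom].append(_rand_dna(rng, spacer))
        chrom_cursor[chrom] += spacer
        g0 = chrom_cursor[chrom]
        chrom_parts[chrom].append(gene_text if strand == "+" else revcomp(gene_text))
        chrom_cursor[chrom] += glen

        build = GeneBuild(
            gene_id=gene_id,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            g0=g0,
            length=glen,
            exon_local=exon_local,
            cds_t=(c0, c1),
            repeat=(rp_exon, rp_off, unit, copies),
            cryptic_intron=(ci_exon, ci_off, _CRYPTIC_INTRON_LEN),
            cryptic_exon=cryptic_exon,
        )
        builds[gene_id] = build

        exon_givs = sorted(build.exon_genome_iv(j) for j in range(n_ex))
        # CDS genomic bounds from the spliced CDS endpoints
        def _sp_to_local(s: int) -> int:
            off = 0
            for (a, b) in exon_local:
                if s < off + (b - a):
                    return a + (s - off)
                off += b - a
            raise IndexError(s)

        l_first = _sp_to_local(c0)
        l_last = _sp_to_local(c1 - 1)
        g_first = build.local_iv_to_genome(l_first, l_first + 1)[0]
        g_last = build.local_iv_to_genome(l_last, l_last + 1)[0]
        cds_gs, cds_ge = min(g_first, g_last), max(g_first, g_last) + 1

        tm = TranscriptModel(
            transcript_id=tid,
            exons=exon_givs,
            strand=strand,
            cds_start=cds_gs,
            cds_end=cds_ge,
        )
        gms.genes[gene_id] = GeneModel(
            gene_id=gene_id,
            gene_name=gene_id,
            chrom=chrom,
            strand=strand,
            transcripts=[tm],
        )
        transcripts[tid] = "".join(exon_seqs)

    for chrom in chrom_parts:
        tail = int(rng.integers(*intergenic_range))
        chrom_parts[chrom].append(_rand_dna(rng, tail))
    genome = {c: "".join(p) for c, p in chrom_parts.items()}
    return Reference(genome=genome, gms=gms, transcripts=transcripts, builds=builds)


# ---------------------------------------------------------------------------
# transcript-space helpers


def segment_text(genome: dict[str, str], seg: Segment) -> str:
    if seg.kind == "break":
        return ""
    if seg.kind == "ins":
        return seg.seq
    s = genome[seg.chrom][seg.gstart : seg.gend]
    return s if seg.strand == "+" else revcomp(s)


def contig_sequence(genome: dict[str, str], segments: Sequence[Segment]) -> str:
    return "".join(segment_text(genome, s) for s in segments)


def _exon_segments(
    build: GeneBuild,
    first_exon: int,
    last_exon: int,
    trim_start: int = 0,
    trim_end: int = 0,
) -> list[Segment]:
    """Ref segments for transcript exons [first..last] (1-based, inclusive),
    optionally trimming bases off the transcript-orientation start/end."""
    segs = []
    for j1 in range(first_exon, last_exon + 1):
        a, b = build.exon_local[j1 - 1]
        if j1 == first_exon:
            a += trim_start
        if j1 == last_exon:
            b -= trim_end
        gs, ge = build.local_iv_to_genome(a, b)
        segs.append(Segment("ref", build.chrom, gs, ge, build.strand))
    return segs


def _t_end_breakpoint(build: GeneBuild, seg: Segment) -> tuple[str, int, str]:
    """Breakpoint at the transcript-orientation END of a ref segment."""
    if seg.strand == "+":
        return seg.chrom, seg.gend - 1, "L"
    return seg.chrom, seg.gstart, "R"


def _t_start_breakpoint(build: GeneBuild, seg: Segment) -> tuple[str, int, str]:
    """Breakpoint at the transcript-orientation START of a ref segment."""
    if seg.strand == "+":
        return seg.chrom, seg.gstart, "R"
    return seg.chrom, seg.gend - 1, "L"


def translated_frame_oracle(
    reference: Reference,
    gene5: str,
    t5_junction: int,
    gene3: str,
    t3_junction: int,
    insert_seq: str = "",
) -> Optional[bool]:
    """Frame status of a chimeric transcript by direct translation.

    Builds the chimeric coding sequence (5' CDS start through the junction,
    the untemplated insert, then the 3' transcript through its CDS end),
    translates it, and reports whether the tail of the 3' partner's
    reference protein is reproduced in frame.  Independent of the phase
    arithmetic used by the caller.

    ``t5_junction``/``t3_junction`` are spliced-transcript coordinates: the
    junction base included from the 5' side, and the first base retained on
    the 3' side.
    """
    from Bio.Seq import Seq

    b5 = reference.builds[gene5]
    b3 = reference.builds[gene3]
    s5 = reference.transcripts[b5.transcript_id]
    s3 = reference.transcripts[b3.transcript_id]
    c5, c5e = b5.cds_t
    c3s, c3e = b3.cds_t
    if not (c5 <= t5_junction < c5e) or not (c3s <= t3_junction < c3e):
        return None  # junction outside either CDS: frame undetermined
    chimera = s5[c5 : t5_junction + 1] + insert_seq + s3[t3_junction:c3e]
    prot = str(Seq(chimera[: len(chimera) // 3 * 3]).translate())
    ref3 = str(Seq(s3[c3s : c3e - (c3e - c3s) % 3]).translate())
    tail = ref3[-6:]
    return prot.endswith(tail)


# ---------------------------------------------------------------------------
# event planting


def plant_event(
    reference: Reference, spec: EventSpec, rng_seed: int = 0
) -> PlantedContig:
    """Build the variant spliced transcript for one event specification.

    Returns the contig (sequence plus its transcript-space construction
    trace) and the exact expected call(s).  Raises when the specification
    is inconsistent with the gene structure.
    """
    rng = np.random.default_rng(rng_seed)
    kind = spec.kind
    if kind in ("fusion", "read_through"):
        return _plant_chimeric(reference, spec, rng)
    build = reference.builds[spec.gene]
    handlers = {
        "ITD": _plant_itd,
        "PTD": _plant_ptd,
        "insertion": _plant_insertion,
        "deletion": _plant_deletion,
        "repeat_expansion": _plant_repeat_expansion,
        "repeat_contraction": _plant_repeat_contraction,
        "skipped_exon": _plant_skipped_exon,
        "novel_exon": _plant_novel_exon,
        "novel_intron": _plant_novel_intron,
        "retained_intron": _plant_retained_intron,
        "novel_donor": _plant_novel_donor,
        "novel_acceptor": _plant_novel_acceptor,
    }
    if kind not in handlers:
        raise ValueError(f"unknown event kind: {kind}")
    return handlers[kind](reference, build, spec, rng)


def _contig_id(kind: str, *genes: str) -> str:
    return f"ctg_{kind}_{'_'.join(genes)}"


def _plant_chimeric(
    reference: Reference, spec: EventSpec, rng: np.random.Generator
) -> PlantedContig:
    b5 = reference.builds[spec.gene]
    b3 = reference.builds[spec.gene3]
    if b5.gene_id == b3.gene_id:
        raise ValueError("chimeric events need two distinct genes")
    exon5 = spec.exon if spec.exon else b5.n_exons
    exon3 = spec.exon3
    if exon5 > b5.n_exons or exon3 > b3.n_exons:
        raise ValueError("exon index beyond gene structure")
    off5 = 0 if spec.boundary5 else spec.offset5
    off3 = 0 if spec.boundary3 else spec.offset3
    segs5 = _exon_segments(b5, 1, exon5, trim_end=off5)
    segs3 = _exon_segments(b3, exon3, b3.n_exons, trim_start=off3)
    insert = _rand_dna(rng, spec.insert_len) if spec.insert_len else ""
    segments = (
        segs5
        + ([Segment("ins", seq=insert)] if insert else [])
        + [Segment("break")]
        + segs3
    )

    c1, p1, o1 = _t_end_breakpoint(b5, segs5[-1])
    c2, p2, o2 = _t_start_breakpoint(b3, segs3[0])

    # expected class: adjacent same-strand genes joined at boundaries in
    # genomic transcription order are read-throughs
    expected = "fusion"
    if (
        b5.chrom == b3.chrom
        and b5.strand == b3.strand
        and spec.boundary5
        and spec.boundary3
        and _genes_adjacent(reference, b5, b3)
        and ((b5.strand == "+" and p1 < p2) or (b5.strand == "-" and p1 > p2))
    ):
        expected = "read_through"
    if spec.kind == "read_through" and expected != "read_through":
        raise ValueError(
            f"{b5.gene_id}/{b3.gene_id} cannot form a read-through "
            "(not adjacent same-strand in transcription order)"
        )

    # junction coordinates in spliced-transcript space for the oracle
    t5_junction = sum(
        b - a for a, b in b5.exon_local[:exon5]
    ) - off5 - 1
    t3_junction = sum(b - a for a, b in b3.exon_local[: exon3 - 1]) + off3
    in_frame = translated_frame_oracle(
        reference, b5.gene_id, t5_junction, b3.gene_id, t3_junction, insert
    )

    cid = _contig_id(spec.kind, b5.gene_id, b3.gene_id)
    n_bound = int(spec.boundary5) + int(spec.boundary3)
    truth = TruthRecord(
        event_type=expected,
        contig_id=cid,
        gene5=b5.gene_id,
        gene3=b3.gene_id,
        chrom1=c1,
        pos1=p1,
        orient1=o1,
        chrom2=c2,
        pos2=p2,
        orient2=o2,
        in_frame=in_frame,
        at_exon_boundary={2: "both", 1: "one", 0: "none"}[n_bound],
        exons_involved=[exon5, exon3],
        novel_seq=insert,
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segments), segments, [truth]
    )


def _genes_adjacent(reference: Reference, b1: GeneBuild, b2: GeneBuild) -> bool:
    if b1.chrom != b2.chrom:
        return False
    lo = min(b1.g0 + b1.length, b2.g0 + b2.length)
    hi = max(b1.g0, b2.g0)
    for b in reference.builds.values():
        if b.gene_id in (b1.gene_id, b2.gene_id) or b.chrom != b1.chrom:
            continue
        if b.strand == b1.strand and b.g0 >= lo and b.g0 + b.length <= hi:
            return False
    return True


def find_read_through_pair(reference: Reference) -> Optional[tuple[str, str]]:
    """An adjacent same-strand gene pair in transcription order, if any."""
    by_chrom: dict[str, list[GeneBuild]] = {}
    for b in reference.builds.values():
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in sorted(by_chrom):
        bs = sorted(by_chrom[chrom], key=lambda b: b.g0)
        for x, y in zip(bs, bs[1:]):
            if x.strand == y.strand:
                return (x.gene_id, y.gene_id) if x.strand == "+" else (
                    y.gene_id,
                    x.gene_id,
                )
    return None


def _split_exon_with_insert(
    build: GeneBuild, exon1: int, local_break: int, insert_seq: str
) -> list[Segment]:
    """Segments for the whole transcript with ``insert_seq`` placed at
    gene-local coordinate ``local_break`` inside exon ``exon1`` (1-based)."""
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        a, b = build.exon_local[j1 - 1]
        if j1 == exon1:
            gs1 = build.local_iv_to_genome(a, local_break)
            gs2 = build.local_iv_to_genome(local_break, b)
            segs.append(Segment("ref", build.chrom, *gs1, build.strand))
            segs.append(Segment("ins", seq=insert_seq))
            segs.append(Segment("ref", build.chrom, *gs2, build.strand))
        else:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(a, b), build.strand)
            )
    return segs


def _gap_truth_positions(build: GeneBuild, local_point: int) -> tuple[int, int]:
    """(pos1, pos2) the gapped caller reports for an insertion at a
    transcript-space point: the genome coordinate where the I op occurs."""
    gpos = build.local_iv_to_genome(local_point, local_point)[0]
    return gpos - 1, gpos


def _in_cds(build: GeneBuild, *spliced_positions: int) -> bool:
    c0, c1 = build.cds_t
    return all(c0 <= p < c1 for p in spliced_positions)


def _local_to_spliced(build: GeneBuild, local: int) -> int:
    off = 0
    for a, b in build.exon_local:
        if a <= local < b:
            return off + (local - a)
        off += b - a
    raise ValueError(f"local position {local} not exonic")


def _plant_itd(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    exon1 = spec.exon
    a, b = build.exon_local[exon1 - 1]
    L = spec.length
    if b - a < L + 12:
        raise ValueError(f"exon {exon1} too short for an ITD of {L} bases")
    off = (b - a - L) // 2
    dup_gs, dup_ge = build.local_iv_to_genome(a + off, a + off + L)
    genome_seq = reference.genome[build.chrom][dup_gs:dup_ge]
    dup_t = genome_seq if build.strand == "+" else revcomp(genome_seq)
    segments = _split_exon_with_insert(build, exon1, a + off + L, dup_t)
    pos1, pos2 = _gap_truth_positions(build, a + off + L)
    sp = _local_to_spliced(build, a + off)
    cid = _contig_id("ITD", build.gene_id)
    truth = TruthRecord(
        event_type="ITD",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        pos1=pos1,
        orient1="L",
        chrom2=build.chrom,
        pos2=pos2,
        orient2="R",
        in_frame=(L % 3 == 0) if _in_cds(build, sp, sp + L - 1) else None,
        exons_involved=[exon1],
        novel_seq=genome_seq,
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segments), segments, [truth]
    )


def _plant_ptd(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    e_from, e_to = spec.exons if spec.exons else (2, min(3, build.n_exons))
    if not (1 <= e_from <= e_to <= build.n_exons):
        raise ValueError("PTD span exceeds exon count")
    segments = _exon_segments(build, 1, e_to) + _exon_segments(
        build, e_from, build.n_exons
    )
    last5 = _exon_segments(build, e_to, e_to)[0]
    first3 = _exon_segments(build, e_from, e_from)[0]
    c1, p1, o1 = _t_end_breakpoint(build, last5)
    c2, p2, o2 = _t_start_breakpoint(build, first3)
    dup_spliced = sum(
        b - a for a, b in build.exon_local[e_from - 1 : e_to]
    )
    sp_lo = _local_to_spliced(build, build.exon_local[e_from - 1][0])
    sp_hi = _local_to_spliced(build, build.exon_local[e_to - 1][1] - 1)
    cid = _contig_id("PTD", build.gene_id)
    truth = TruthRecord(
        event_type="PTD",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=c1,
        pos1=p1,
        orient1=o1,
        chrom2=c2,
        pos2=p2,
        orient2=o2,
        in_frame=(dup_spliced % 3 == 0) if _in_cds(build, sp_lo, sp_hi) else None,
        at_exon_boundary="both",
        exons_involved=[e_from, e_to],
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segments), segments, [truth]
    )


def _plant_insertion(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    exon1 = spec.exon
    a, b = build.exon_local[exon1 - 1]
    L = spec.length if spec.length else 4
    off = (b - a) // 2
    point = a + off
    gpos = build.local_iv_to_genome(point, point)[0]
    genome = reference.genome[build.chrom]
    from .sv_caller import _minimal_unit

    while True:
        ins_t = _rand_dna(rng, L)
        fwd = ins_t if build.strand == "+" else revcomp(ins_t)
        if fwd in (genome[gpos - L : gpos], genome[gpos : gpos + L]):
            continue
        u = _minimal_unit(fwd, 6) or fwd
        if genome[gpos - len(u) : gpos] == u or genome[gpos : gpos + len(u)] == u:
            continue
        break
    segments = _split_exon_with_insert(build, exon1, point, ins_t)
    sp = _local_to_spliced(build, point)
    cid = _contig_id("insertion", build.gene_id)
    truth = TruthRecord(
        event_type="insertion",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        pos1=gpos - 1,
        orient1="L",
        chrom2=build.chrom,
        pos2=gpos,
        orient2="R",
        in_frame=(L % 3 == 0) if _in_cds(build, sp) else None,
        exons_involved=[exon1],
        novel_seq=fwd,
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segments), segments, [truth]
    )


def _plant_deletion(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    exon1 = spec.exon
    a, b = build.exon_local[exon1 - 1]
    L = spec.length if spec.length else 5
    if L >= 20:
        raise ValueError("deletions must stay below the intron-size threshold")
    genome = reference.genome[build.chrom]
    from .sv_caller import _minimal_unit

    off = (b - a) // 2
    for attempt in range(50):
        point = a + off + attempt  # slide until the removed text is not a repeat
        gs, ge = build.local_iv_to_genome(point, point + L)
        removed = genome[gs:ge]
        u = _minimal_unit(removed, 6) or removed
        if genome[gs - len(u) : gs] != u and genome[ge : ge + len(u)] != u:
            break
    else:
        raise ValueError("could not find a non-repetitive deletion site")
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        ea, eb = build.exon_local[j1 - 1]
        if j1 == exon1:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, point), build.strand)
            )
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(point + L, eb), build.strand)
            )
        else:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, eb), build.strand)
            )
    sp = _local_to_spliced(build, point)
    cid = _contig_id("deletion", build.gene_id)
    truth = TruthRecord(
        event_type="deletion",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        pos1=gs - 1,
        orient1="L",
        chrom2=build.chrom,
        pos2=ge,
        orient2="R",
        in_frame=(L % 3 == 0) if _in_cds(build, sp) else None,
        exons_involved=[exon1],
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


def _plant_repeat_expansion(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    rp_exon, rp_off, unit, copies = build.repeat
    m = spec.copies
    a, b = build.exon_local[rp_exon]
    point = a + rp_off + copies * len(unit)  # transcript-space tract end
    ins_t = unit * m
    segments = _split_exon_with_insert(build, rp_exon + 1, point, ins_t)
    pos1, pos2 = _gap_truth_positions(build, point)
    sp = _local_to_spliced(build, point)
    fwd = ins_t if build.strand == "+" else revcomp(ins_t)
    cid = _contig_id("repeat_expansion", build.gene_id)
    truth = TruthRecord(
        event_type="repeat_expansion",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        pos1=pos1,
        orient1="L",
        chrom2=build.chrom,
        pos2=pos2,
        orient2="R",
        in_frame=(len(ins_t) % 3 == 0) if _in_cds(build, sp) else None,
        exons_involved=[rp_exon + 1],
        novel_seq=fwd,
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segments), segments, [truth]
    )


def _plant_repeat_contraction(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    rp_exon, rp_off, unit, copies = build.repeat
    m = min(spec.copies, copies - 1)
    a, b = build.exon_local[rp_exon]
    point = a + rp_off  # delete m copies from the tract's transcript start
    L = m * len(unit)
    gs, ge = build.local_iv_to_genome(point, point + L)
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        ea, eb = build.exon_local[j1 - 1]
        if j1 == rp_exon + 1:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, point), build.strand)
            )
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(point + L, eb), build.strand)
            )
        else:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, eb), build.strand)
            )
    sp = _local_to_spliced(build, point)
    cid = _contig_id("repeat_contraction", build.gene_id)
    truth = TruthRecord(
        event_type="repeat_contraction",
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        pos1=gs - 1,
        orient1="L",
        chrom2=build.chrom,
        pos2=ge,
        orient2="R",
        in_frame=(L % 3 == 0) if _in_cds(build, sp) else None,
        exons_involved=[rp_exon + 1],
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


def _splice_truth(build: GeneBuild, kind, cid, coords, motif, canonical) -> TruthRecord:
    return TruthRecord(
        event_type=kind,
        contig_id=cid,
        gene5=build.gene_id,
        gene3=build.gene_id,
        chrom1=build.chrom,
        coords=coords,
        splice_motif=motif,
        canonical=canonical,
    )


def _plant_skipped_exon(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    skipped = spec.exons or [2]
    if skipped != list(range(skipped[0], skipped[-1] + 1)):
        raise ValueError("skipped exons must be consecutive")
    if skipped[0] <= 1 or skipped[-1] >= build.n_exons:
        raise ValueError("cannot skip terminal exons")
    donor_exon = skipped[0] - 1 - (1 if spec.donor_shift else 0)
    if donor_exon < 1:
        raise ValueError("no exon available for the donor displacement")

    segs: list[Segment] = []
    truths: list[TruthRecord] = []
    cid = _contig_id("skipped_exon", build.gene_id)
    for j1 in range(1, build.n_exons + 1):
        if j1 in skipped:
            continue
        trim_end = spec.donor_shift if (spec.donor_shift and j1 == donor_exon) else 0
        segs.extend(_exon_segments(build, j1, j1, trim_end=trim_end))

    coords = sorted(build.exon_genome_iv(j - 1) for j in skipped)
    truths.append(_splice_truth(build, "skipped_exon", cid, coords, "GT-AG", True))
    if spec.donor_shift:
        a, b = build.exon_local[donor_exon - 1]
        na, nb = build.exon_local[donor_exon]  # next retained exon
        iv = build.local_iv_to_genome(b - spec.donor_shift, na)
        truths.append(
            _splice_truth(build, "novel_donor", cid, [iv], "", None)
        )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, truths
    )


def _plant_novel_exon(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    if build.cryptic_exon is None:
        raise ValueError("gene has no intron able to host a novel exon")
    ii, off, L = build.cryptic_exon
    p, q = build.intron_local()[ii]
    seg_iv = build.local_iv_to_genome(p + off, p + off + L)
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        segs.extend(_exon_segments(build, j1, j1))
        if j1 == ii + 1:
            segs.append(Segment("ref", build.chrom, *seg_iv, build.strand))
    segs_sorted = segs  # transcript order already correct
    cid = _contig_id("novel_exon", build.gene_id)
    truth = _splice_truth(
        build, "novel_exon", cid, [seg_iv], "GT-AG,GT-AG", True
    )
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs_sorted), segs_sorted, [truth]
    )


def _plant_novel_intron(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    ei, off, L = build.cryptic_intron
    a, b = build.exon_local[ei]
    point = a + off
    iv = build.local_iv_to_genome(point, point + L)
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        ea, eb = build.exon_local[j1 - 1]
        if j1 == ei + 1:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, point), build.strand)
            )
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(point + L, eb), build.strand)
            )
        else:
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(ea, eb), build.strand)
            )
    cid = _contig_id("novel_intron", build.gene_id)
    truth = _splice_truth(build, "novel_intron", cid, [iv], "GT-AG", True)
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


def _plant_retained_intron(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    i1 = spec.intron
    if not (1 <= i1 <= build.n_exons - 1):
        raise ValueError("intron index out of range")
    segs: list[Segment] = []
    j1 = 1
    while j1 <= build.n_exons:
        if j1 == i1:
            a = build.exon_local[j1 - 1][0]
            b = build.exon_local[j1][1]
            segs.append(
                Segment("ref", build.chrom, *build.local_iv_to_genome(a, b), build.strand)
            )
            j1 += 2
        else:
            segs.extend(_exon_segments(build, j1, j1))
            j1 += 1
    p, q = build.intron_local()[i1 - 1]
    iv = build.local_iv_to_genome(p, q)
    cid = _contig_id("retained_intron", build.gene_id)
    truth = _splice_truth(build, "retained_intron", cid, [iv], "GT-AG", None)
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


def _plant_novel_donor(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    e1 = spec.exon
    if e1 >= build.n_exons:
        raise ValueError("donor displacement needs a following intron")
    d = spec.shift
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        segs.extend(
            _exon_segments(build, j1, j1, trim_end=d if j1 == e1 else 0)
        )
    a, b = build.exon_local[e1 - 1]
    na, _ = build.exon_local[e1]
    iv = build.local_iv_to_genome(b - d, na)
    cid = _contig_id("novel_donor", build.gene_id)
    truth = _splice_truth(build, "novel_donor", cid, [iv], "", None)
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


def _plant_novel_acceptor(reference, build: GeneBuild, spec: EventSpec, rng) -> PlantedContig:
    e1 = spec.exon
    if e1 <= 1:
        raise ValueError("acceptor displacement needs a preceding intron")
    d = spec.shift
    segs: list[Segment] = []
    for j1 in range(1, build.n_exons + 1):
        segs.extend(
            _exon_segments(build, j1, j1, trim_start=d if j1 == e1 else 0)
        )
    _, pb = build.exon_local[e1 - 2]
    a, b = build.exon_local[e1 - 1]
    iv = build.local_iv_to_genome(pb, a + d)
    cid = _contig_id("novel_acceptor", build.gene_id)
    truth = _splice_truth(build, "novel_acceptor", cid, [iv], "", None)
    return PlantedContig(
        cid, contig_sequence(reference.genome, segs), segs, [truth]
    )


# ---------------------------------------------------------------------------
# oracle SAM emission


def _segments_to_fragments(
    segments: Sequence[Segment], min_intron_size: int = 20
) -> list[dict]:
    """Group transcript-space segments into single-record fragments.

    A fragment holds CIGAR ops in transcript orientation plus its genome
    and contig spans.  Chromosome/strand changes and backward genome jumps
    (tandem duplications) start a new fragment; untemplated inserts between
    fragments stay unaligned.
    """
    frags: list[dict] = []
    cur: Optional[dict] = None
    pending: list[tuple[int, str]] = []  # (tpos, seq) inserts awaiting a ref
    t = 0

    def close():
        nonlocal cur
        if cur is not None:
            frags.append(cur)
            cur = None

    for seg in segments:
        if seg.kind == "break":
            close()
            pending = []
            continue
        if seg.kind == "ins":
            pending.append((t, seg.seq))
            t += len(seg.seq)
            continue
        glen = seg.gend - seg.gstart
        joinable = False
        gap = 0
        if cur is not None and seg.chrom == cur["chrom"] and seg.strand == cur["strand"]:
            if seg.strand == "+" and seg.gstart >= cur["g_hi"]:
                gap = seg.gstart - cur["g_hi"]
                joinable = True
            elif seg.strand == "-" and seg.gend <= cur["g_lo"]:
                gap = cur["g_lo"] - seg.gend
                joinable = True
        if not joinable:
            close()
            pending = []  # inserts before a fragment boundary stay unaligned
            cur = {
                "chrom": seg.chrom,
                "strand": seg.strand,
                "g_lo": seg.gstart,
                "g_hi": seg.gend,
                "c_start": t,
                "c_end": t + glen,
                "ops": [("M", glen)],
            }
            t += glen
            continue
        for _, iseq in pending:
            cur["ops"].append(("I", len(iseq)))
        pending = []
        if gap > 0:
            cur["ops"].append(("N" if gap >= min_intron_size else "D", gap))
        if cur["ops"] and cur["ops"][-1][0] == "M" and gap == 0:
            cur["ops"][-1] = ("M", cur["ops"][-1][1] + glen)
        else:
            cur["ops"].append(("M", glen))
        if seg.strand == "+":
            cur["g_hi"] = seg.gend
        else:
            cur["g_lo"] = seg.gstart
        cur["c_end"] = t + glen
        t += glen
    close()
    return frags


_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}


def emit_contig_alignments(
    contigs: Sequence[PlantedContig],
    reference: Reference,
    contig_fasta_path: str,
    sam_path: str,
    min_intron_size: int = 20,
) -> None:
    """Write contig FASTA and the oracle contig-to-genome SAM.

    CIGARs (M/I/D/N) and split records come straight from each contig's
    construction trace.  The first fragment of a chimeric contig is the
    primary record (soft clips, full sequence); later fragments are
    supplementary records with hard clips, exercising the full-contig
    coordinate reconstruction on the parsing side.
    """
    write_fasta([(c.contig_id, c.seq) for c in contigs], contig_fasta_path)
    chroms = sorted(reference.genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference.genome[c])} for c in chroms],
    }
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for contig in contigs:
            frags = _segments_to_fragments(contig.segments, min_intron_size)
            L = len(contig.seq)
            for fi, fr in enumerate(frags):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = contig.contig_id
                rec.reference_id = chroms.index(fr["chrom"])
                rec.reference_start = fr["g_lo"]
                rec.mapping_quality = 60
                rev = fr["strand"] == "-"
                supp = fi > 0
                rec.flag = (16 if rev else 0) | (2048 if supp else 0)
                ops = fr["ops"] if not rev else list(reversed(fr["ops"]))
                clip_op = "H" if supp else "S"
                lead = fr["c_start"] if not rev else L - fr["c_end"]
                trail = L - fr["c_end"] if not rev else fr["c_start"]
                cig = []
                if lead:
                    cig.append((_OP_CODE[clip_op], lead))
                cig.extend((_OP_CODE[o], n) for o, n in ops)
                if trail:
                    cig.append((_OP_CODE[clip_op], trail))
                rec.cigartuples = cig
                frag_seq = contig.seq[fr["c_start"] : fr["c_end"]]
                if supp:
                    rec.query_sequence = revcomp(frag_seq) if rev else frag_seq
                else:
                    rec.query_sequence = revcomp(contig.seq) if rev else contig.seq
                out.write(rec)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedPair:
    name: str
    seq1: str
    seq2: str
    source: str
    frag_start: int
    frag_end: int


def simulate_read_pairs(
    sequences: dict[str, str],
    coverage: float,
    read_len: int = 100,
    insert_mean: int = 250,
    insert_sd: float = 25.0,
    sub_error_rate: float = 0.0037,
    rng_seed: int = 0,
    abundances: Optional[dict[str, float]] = None,
) -> list[SimulatedPair]:
    """Simulate paired-end reads with independent substitution errors.

    Fragments are sampled uniformly along each sequence with normal insert
    sizes; read 1 is the fragment 5' end forward, read 2 the 3' end
    reverse-complemented.  Sequences shorter than the mean insert size are
    skipped with a warning.  Deterministic under ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pairs: list[SimulatedPair] = []
    for name in sorted(sequences):
        seq = sequences[name]
        slen = len(seq)
        if slen < insert_mean:
            warnings.warn(f"{name}: length {slen} < insert size {insert_mean}, skipped")
            continue
        ab = 1.0 if abundances is None else abundances.get(name, 1.0)
        n = int(round(coverage * ab * slen / (2 * read_len)))
        if n <= 0:
            continue
        frag = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, n)).astype(int),
            read_len,
            slen,
        )
        start = np.floor(rng.random(n) * (slen - frag + 1)).astype(int)
        end = start + frag
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(n):
            s1 = arr[start[i] : start[i] + read_len]
            s2 = arr[end[i] - read_len : end[i]]
            r1 = s1.tobytes().decode()
            r2 = revcomp(s2.tobytes().decode())
            if sub_error_rate > 0:
                r1 = _mutate(r1, sub_error_rate, rng, bases)
                r2 = _mutate(r2, sub_error_rate, rng, bases)
            pairs.append(
                SimulatedPair(
                    name=f"{name}:{i}",
                    seq1=r1,
                    seq2=r2,
                    source=name,
                    frag_start=int(start[i]),
                    frag_end=int(end[i]),
                )
            )
    return pairs


def _mutate(read: str, rate: float, rng: np.random.Generator, bases: np.ndarray) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(read), size=n_err, replace=False)
    for p in pos:
        choices = bases[bases != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def write_pairs_fastq(
    pairs: Sequence[SimulatedPair], fq1_path: str, fq2_path: str
) -> None:
    from .io_formats import write_fastq

    write_fastq([(f"{p.name}/1", p.seq1) for p in pairs], fq1_path)
    write_fastq([(f"{p.name}/2", p.seq2) for p in pairs], fq2_path)


def write_r2c_sam(
    pairs: Sequence[SimulatedPair],
    contig_lengths: dict[str, int],
    sam_path: str,
    read_len: int = 100,
) -> None:
    """Oracle reads-to-contig SAM: each read at its true source placement."""
    names = sorted(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": contig_lengths[n]} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for p in pairs:
            if p.source not in idx:
                continue
            for mate, (seq, flag, pos) in enumerate(
                [
                    (p.seq1, 0x1 | 0x2 | 0x20 | 0x40, p.frag_start),
                    (p.seq2, 0x1 | 0x2 | 0x10 | 0x80, p.frag_end - read_len),
                ]
            ):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = p.name
                rec.reference_id = idx[p.source]
                rec.reference_start = pos
                rec.mapping_quality = 60
                rec.flag = flag
                rec.cigartuples = [(0, len(seq))]
                rec.query_sequence = revcomp(seq) if flag & 0x10 else seq
                out.write(rec)


def slice_segments(
    segments: Sequence[Segment], t_start: int, t_end: int
) -> list[Segment]:
    """Transcript-space window [t_start, t_end) of a segment list."""
    out: list[Segment] = []
    t = 0
    for seg in segments:
        if seg.kind == "break":
            if t_start < t < t_end:
                out.append(Segment("break"))
            continue
        L = seg.tlen()
        a, b = max(t_start, t), min(t_end, t + L)
        if a < b:
            la, lb = a - t, b - t
            if seg.kind == "ins":
                out.append(Segment("ins", seq=seg.seq[la:lb]))
            elif seg.strand == "+":
                out.append(
                    Segment(
                        "ref", seg.chrom, seg.gstart + la, seg.gstart + lb, "+"
                    )
                )
            else:
                out.append(
                    Segment(
                        "ref", seg.chrom, seg.gend - lb, seg.gend - la, "-"
                    )
                )
        t += L
    return out


def run_titration_and_evaluate(design, workdir: Optional[str] = None, config=None):
    """Coverage-titration benchmark of fusion calling (see `benchmark`)."""
    from .benchmark import run_titration_and_evaluate as _run

    return _run(design, workdir=workdir, config=config)
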