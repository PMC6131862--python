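"""Core domain types shared across the caller modules.

All coordinates held in these types are 0-based half-open on the genome
forward strand unless a field name says otherwise.  SAM (1-based) and GTF
(1-based inclusive) are converted at the I/O boundary; TSV output re-emits
1-based positions and BEDPE 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

# ---------------------------------------------------------------------------
# gene models


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]  # sorted ascending by genomic start
    strand: str
    cds_start: Optional[int] = None  # genomic, 0-based
    cds_end: Optional[int] = None  # genomic, half-open

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exon_number(self, idx: int) -> int:
        """1-based exon number in transcript (5'->3') orientation."""
        n = len(self.exons)
        return idx + 1 if self.strand == "+" else n - idx

    def genome_to_transcript(self, gpos: int) -> Optional[int]:
        """Map a genomic base coordinate to a spliced transcript coordinate.

        Returns None when ``gpos`` falls in an intron or outside the
        transcript span.
        """
        if self.strand == "+":
            off = 0
            for s, e in self.exons:
                if s <= gpos < e:
                    return off + (gpos - s)
                off += e - s
            return None
        off = 0
        for s, e in reversed(self.exons):
            if s <= gpos < e:
                return off + (e - 1 - gpos)
            off += e - s
        return None

    def transcript_to_genome(self, tpos: int) -> int:
        if tpos < 0 or tpos >= self.spliced_length:
            raise IndexError(f"transcript position {tpos} out of range")
        if self.strand == "+":
            off = 0
            for s, e in self.exons:
                if tpos < off + (e - s):
                    return s + (tpos - off)
                off += e - s
        else:
            off = 0
            for s, e in reversed(self.exons):
                if tpos < off + (e - s):
                    return e - 1 - (tpos - off)
                off += e - s
        raise AssertionError("unreachable")

    def cds_start_tpos(self) -> Optional[int]:
        """Spliced coordinate of the first coding base (None without CDS)."""
        if self.cds_start is None:
            return None
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        return self.genome_to_transcript(g)

    def cds_end_tpos(self) -> Optional[int]:
        """Spliced coordinate one past the last coding base."""
        if self.cds_start is None:
            return None
        g = self.cds_end - 1 if self.strand == "+" else self.cds_start
        t = self.genome_to_transcript(g)
        return None if t is None else t + 1


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class GeneModelSet:
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def transcripts(self):
        for g in self.genes.values():
            yield from g.transcripts

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return t
        raise KeyError(transcript_id)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class GapRecord:
    kind: str  # "insertion" | "deletion"
    genome_pos: int
    contig_pos: int
    length: int
    inserted_seq: str = ""


@dataclass
class ContigAlignment:
    """One decoded SAM record: ordered aligned blocks plus gap records.

    Contig coordinates are in the original contig orientation (as the
    sequence appears in the contig FASTA), including clipped prefixes, so
    that split records of one contig share one coordinate system.  Blocks
    are ordered ascending by contig coordinate; on the minus strand that
    means descending genome coordinates.
    """

    contig_id: str
    contig_len: int
    chrom: str
    strand: str
    blocks: list[tuple[int, int, int, int]]  # (gstart, gend, cstart, cend)
    gaps: list[GapRecord] = field(default_factory=list)
    mapq: int = 60
    is_supplementary: bool = False
    alignment_order_on_contig: int = 0

    @property
    def contig_start(self) -> int:
        return self.blocks[0][2]

    @property
    def contig_end(self) -> int:
        return self.blocks[-1][3]

    @property
    def genome_start(self) -> int:
        return min(b[0] for b in self.blocks)

    @property
    def genome_end(self) -> int:
        return max(b[1] for b in self.blocks)

    @property
    def aligned_len(self) -> int:
        return sum(ce - cs for _, _, cs, ce in self.blocks)


# ---------------------------------------------------------------------------
# events


@dataclass
class Breakpoint:
    chrom: str
    pos: int  # 0-based coordinate of the terminal aligned base
    orient: str  # "L": reference continues to lower coords; "R": higher


@dataclass
class Adjacency:
    """A novel junction joining two reference loci on one contig."""

    contig_id: str
    breakpoint1: Breakpoint
    breakpoint2: Breakpoint
    contig_break1: int
    contig_break2: int
    novel_seq: str = ""
    homology_seq: str = ""


#: structural classes; splice classes live on SpliceEventCall
SV_TYPES = (
    "fusion",
    "read_through",
    "ITD",
    "PTD",
    "duplication",
    "insertion",
    "deletion",
    "repeat_expansion",
    "repeat_contraction",
)

SPLICE_TYPES = (
    "skipped_exon",
    "novel_exon",
    "novel_intron",
    "retained_intron",
    "novel_donor",
    "novel_acceptor",
)


@dataclass
class EventCall:
    event_type: str
    contig_ids: list[str]
    adjacency: Optional[Adjacency] = None
    chrom1: str = ""
    pos1: int = -1
    orient1: str = ""
    chrom2: str = ""
    pos2: int = -1
    orient2: str = ""
    gene5: Optional[str] = None
    gene3: Optional[str] = None
    transcript5: Optional[str] = None
    transcript3: Optional[str] = None
    exons_involved: list[int] = field(default_factory=list)
    in_frame: Optional[bool] = None
    at_exon_boundary: str = "none"  # both | one | none
    novel_seq: str = ""
    homology_seq: str = ""
    # contig-space junction interval for read support
    contig_break1: int = -1
    contig_break2: int = -1
    spanning_reads: int = -1
    filter_status: str = "PASS"

    def key(self) -> tuple:
        return (self.event_type, self.chrom1, self.pos1, self.chrom2, self.pos2)


@dataclass
class SpliceEventCall:
    event_type: str
    gene: str
    transcript: str
    chrom: str
    coords: list[tuple[int, int]]  # event-specific genomic interval(s)
    splice_motif: str = "NA"
    canonical: Optional[bool] = None
    contig_ids: list[str] = field(default_factory=list)
    # contig-space junction point for depth counting
    contig_break: int = -1
    junction_depth: int = -1
    filter_status: str = "PASS"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default.

    Unknown keys are rejected on load; the effective configuration is
    echoed to the log and a sidecar file by the CLI.
    """

    min_support: int = 4
    min_overhang: int = 4
    min_fragment_len: int = 30
    max_novel_seq: int = 50
    max_homology: int = 10
    min_itd_len: int = 9
    min_intron_size: int = 20
    exon_boundary_tolerance: int = 0
    restrict_exon_boundary: bool = True
    canonical_motifs: tuple[str, ...] = ("GT-AG",)
    max_junction_shift: int = 300
    max_repeat_unit: int = 6
    k: int = 25
    n_seeds: int = 5
    allowed_miss: int = 2
    seed_care_fraction: float = 0.7
    fpr: float = 1e-3
    min_frames: int = 1
    rng_seed: int = 0

    def updated(self, **kwargs) -> "PipelineConfig":
        for k in kwargs:
            if not hasattr(self, k):
                raise KeyError(f"unknown config key: {k}")
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load a flat key=value config file; unknown keys raise."""
        kwargs = {}
        defaults = cls()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if not hasattr(defaults, key):
                    raise KeyError(f"{path}:{ln}: unknown config key: {key}")
                cur = getattr(defaults, key)
                if isinstance(cur, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes", "on")
                elif isinstance(cur, int):
                    kwargs[key] = int(val)
                elif isinstance(cur, float):
                    kwargs[key] = float(val)
                elif isinstance(cur, tuple):
                    kwargs[key] = tuple(v.strip() for v in val.split(","))
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d
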