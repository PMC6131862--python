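"""Read-level evidence: breakpoint-spanning read counts from r2c alignments.

Support for every event is quantified from reads aligned back to the
contigs (r2c).  A spanning read must cover the contig junction interval
with at least ``min_overhang`` aligned bases on each side; only primary,
non-duplicate records are counted.  Events with fewer than ``min_support``
spanning reads (default 4) are kept in the output but flagged
"low_support".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pysam

from .models import EventCall, PipelineConfig, SpliceEventCall


@dataclass
class SupportEvidence:
    event_ref: Optional[object] = None
    spanning_reads: int = 0
    depth_at_breakpoint: int = 0
    contributing_read_ids: list[str] = field(default_factory=list)
    missing_contig: bool = False


def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate
    )


def count_spanning_reads(
    r2c: Union[str, pysam.AlignmentFile],
    contig_id: str,
    contig_break1: int,
    contig_break2: Optional[int] = None,
    min_overhang: int = 4,
    collect_ids: bool = False,
) -> SupportEvidence:
    """Count reads whose contig alignment spans a junction interval.

    A read spans when its aligned interval covers
    ``[contig_break1 - min_overhang, contig_break2 + min_overhang)``
    (``contig_break2`` defaults to ``contig_break1`` for point junctions).
    A read ending exactly at the breakpoint has zero overhang and does not
    count.  ``depth_at_breakpoint`` is the number of usable reads merely
    overlapping the junction point.
    """
    if contig_break2 is None:
        contig_break2 = contig_break1
    lo = contig_break1 - min_overhang
    hi = contig_break2 + min_overhang

    own = False
    if isinstance(r2c, (str,)):
        mode = "rb" if str(r2c).endswith(".bam") else "r"
        r2c = pysam.AlignmentFile(r2c, mode, check_sq=False)
        own = True
    try:
        ev = SupportEvidence()
        if contig_id not in (r2c.references or ()):
            warnings.warn(f"contig {contig_id} absent from r2c alignments")
            ev.missing_contig = True
            return ev
        try:
            it = r2c.fetch(contig_id)
        except ValueError:  # no index (plain SAM): scan everything
            it = (
                rec
                for rec in r2c.fetch(until_eof=True)
                if rec.reference_name == contig_id
            )
        for rec in it:
            if not _usable(rec):
                continue
            s, e = rec.reference_start, rec.reference_end
            if s < contig_break2 and e > contig_break1:
                ev.depth_at_breakpoint += 1
            if s <= lo and e >= hi:
                ev.spanning_reads += 1
                if collect_ids:
                    ev.contributing_read_ids.append(rec.query_name)
        return ev
    finally:
        if own:
            r2c.close()


def attach_support(
    events: Sequence[Union[EventCall, SpliceEventCall]],
    r2c_path: str,
    config: Optional[PipelineConfig] = None,
) -> None:
    """Fill spanning-read counts for every event, in place.

    For adjacency events the junction interval is
    ``[contig_break1, contig_break2]``; splice-event junction depth uses
    the same machinery on the contig junction point.  When an event merged
    from contigs of several assemblies, support is pooled at the read
    level: distinct spanning read names are counted once across contigs.
    """
    cfg = config or PipelineConfig()
    mode = "rb" if str(r2c_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(r2c_path, mode, check_sq=False) as fh:
        # r2c SAM may be unindexed; build an in-memory interval pool
        pool: dict[str, list[tuple[int, int, str]]] = {}
        for rec in fh:
            if not _usable(rec):
                continue
            # key by (name, mate): mates share a query name but are
            # separate reads for support counting
            mate = 2 if rec.is_read2 else 1
            pool.setdefault(rec.reference_name, []).append(
                (rec.reference_start, rec.reference_end, (rec.query_name, mate))
            )
    for ev in events:
        if isinstance(ev, SpliceEventCall):
            contigs = ev.contig_ids
            b1 = b2 = ev.contig_break
        else:
            contigs = ev.contig_ids
            b1, b2 = ev.contig_break1, ev.contig_break2
            if b1 < 0:
                continue
            if b2 < b1:
                b2 = b1
        lo, hi = b1 - cfg.min_overhang, b2 + cfg.min_overhang
        names = {
            name
            for cid in contigs
            for s, e, name in pool.get(cid, ())
            if s <= lo and e >= hi
        }
        if isinstance(ev, SpliceEventCall):
            ev.junction_depth = len(names)
        else:
            ev.spanning_reads = len(names)


def apply_support_filter(
    events: Sequence[Union[EventCall, SpliceEventCall]],
    min_support: int = 4,
) -> list[Union[EventCall, SpliceEventCall]]:
    """Flag events with fewer than ``min_support`` spanning reads.

    The threshold is inclusive: exactly ``min_support`` reads pass.  No
    event is deleted; failures get filter_status "low_support".
    """
    for ev in events:
        n = ev.junction_depth if isinstance(ev, SpliceEventCall) else ev.spanning_reads
        if n < min_support and ev.filter_status == "PASS":
            ev.filter_status = "low_support"
    return list(events)
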