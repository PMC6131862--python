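"""End-to-end orchestration: parse inputs, call, support, filter, write."""
from __future__ import annotations

import json
import logging
import os
from collections import Counter
from typing import Optional

from .annotation import GeneIndex
from .io_formats import (
    parse_contig_alignments,
    parse_gene_models,
    read_fasta,
    write_events,
)
from .models import EventCall, PipelineConfig, SpliceEventCall
from .splice_caller import call_splice_events, match_transcript
from .support import apply_support_filter, attach_support
from .sv_caller import (
    call_gapped_events,
    classify_adjacency,
    find_adjacencies,
    merge_and_filter,
)

log = logging.getLogger("contigsv")


def _merge_splice(events: list[SpliceEventCall]) -> list[SpliceEventCall]:
    merged: dict[tuple, SpliceEventCall] = {}
    for ev in events:
        key = (ev.event_type, ev.gene, ev.chrom, tuple(ev.coords))
        if key in merged:
            merged[key].contig_ids = sorted(
                set(merged[key].contig_ids) | set(ev.contig_ids)
            )
        else:
            ev.contig_ids = sorted(set(ev.contig_ids))
            merged[key] = ev
    return [merged[k] for k in sorted(merged)]


def run_call(
    contig_fasta: str,
    c2g_path: str,
    gtf_path: str,
    genome_fasta: str,
    r2c_path: Optional[str] = None,
    config: Optional[PipelineConfig] = None,
    out_prefix: Optional[str] = None,
) -> dict:
    """Run structural and splice variant calling over all contigs.

    Returns a dict with the final event list and per-type/per-filter
    counts; when ``out_prefix`` is given, writes ``<prefix>.events.tsv``,
    ``<prefix>.adjacencies.bedpe``, ``<prefix>.junctions.tsv`` (splice
    junction depth report) and ``<prefix>.config.json`` (effective
    configuration echo).  Zero contigs yield valid empty outputs.
    """
    cfg = config or PipelineConfig()
    gms = parse_gene_models(gtf_path)
    index = GeneIndex(gms)
    genome = read_fasta(genome_fasta)
    contigs = read_fasta(contig_fasta)
    groups = parse_contig_alignments(c2g_path, contigs, cfg.min_intron_size)

    sv_events: list[EventCall] = []
    splice_events: list[SpliceEventCall] = []
    for cid in sorted(groups):
        alns = groups[cid]
        seq = contigs[cid]
        for adj in find_adjacencies(alns, seq, cfg):
            sv_events.append(classify_adjacency(adj, index, cfg, genome))
        for aln in alns:
            sv_events.extend(call_gapped_events(aln, seq, genome, index, cfg))
            corr = match_transcript(aln, index)
            if corr:
                splice_events.extend(
                    call_splice_events(corr, aln, genome, index, cfg)
                )

    sv_events = merge_and_filter(sv_events, cfg.restrict_exon_boundary)
    splice_events = _merge_splice(splice_events)
    events = [*sv_events, *splice_events]

    if r2c_path is not None:
        attach_support(events, r2c_path, cfg)
        apply_support_filter(events, cfg.min_support)

    type_counts = Counter(ev.event_type for ev in events)
    filter_counts = Counter(ev.filter_status for ev in events)
    log.info("events by type: %s", dict(type_counts))
    log.info("events by filter: %s", dict(filter_counts))
    log.info("effective config: %s", cfg.as_dict())

    if out_prefix is not None:
        os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
        write_events(
            events, f"{out_prefix}.events.tsv", f"{out_prefix}.adjacencies.bedpe"
        )
        with open(f"{out_prefix}.junctions.tsv", "w") as fh:
            fh.write("event_type\tgene\tchrom\tcoords\tjunction_depth\tfilter_status\n")
            for ev in sorted(
                splice_events, key=lambda e: (e.chrom, e.coords, e.event_type)
            ):
                coords = ",".join(f"{s + 1}-{e}" for s, e in ev.coords)
                fh.write(
                    f"{ev.event_type}\t{ev.gene}\t{ev.chrom}\t{coords}\t"
                    f"{ev.junction_depth}\t{ev.filter_status}\n"
                )
        with open(f"{out_prefix}.config.json", "w") as fh:
            json.dump(cfg.as_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    return {
        "events": events,
        "type_counts": dict(type_counts),
        "filter_counts": dict(filter_counts),
        "config": cfg,
    }
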