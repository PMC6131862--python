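"""Convenience harness: plant one event of every supported class.

Used by the simulation CLI and the validation suite to build a universe
exercising the full event taxonomy with per-class truth records.
"""
from __future__ import annotations

from typing import Optional

from .synthetic_data import (
    EventSpec,
    PlantedContig,
    Reference,
    find_read_through_pair,
    plant_event,
)

ALL_EVENT_KINDS = (
    "fusion",
    "read_through",
    "ITD",
    "PTD",
    "insertion",
    "deletion",
    "repeat_expansion",
    "repeat_contraction",
    "skipped_exon",
    "novel_exon",
    "novel_intron",
    "retained_intron",
    "novel_donor",
    "novel_acceptor",
)


def default_spec_for(
    kind: str, reference: Reference, used: set[str]
) -> Optional[EventSpec]:
    """A workable specification of ``kind`` on a not-yet-used gene."""
    gids = [g for g in reference.gene_ids() if g not in used]
    if kind == "read_through":
        pair = find_read_through_pair(reference)
        if pair is None:
            return None
        return EventSpec(kind=kind, gene=pair[0], gene3=pair[1])
    if kind == "fusion":
        # pick two genes on different chromosomes so the pair can never be
        # mistaken for a read-through
        for g5 in gids:
            for g3 in gids:
                if (
                    g3 != g5
                    and reference.builds[g5].chrom != reference.builds[g3].chrom
                ):
                    return EventSpec(kind=kind, gene=g5, gene3=g3, exon=2, exon3=2)
        return None
    if not gids:
        gids = reference.gene_ids()
    g = gids[0]
    b = reference.builds[g]
    if kind == "PTD":
        return EventSpec(kind=kind, gene=g, exons=[2, min(3, b.n_exons)])
    if kind == "skipped_exon":
        return EventSpec(kind=kind, gene=g, exons=[2])
    if kind in ("novel_donor",):
        return EventSpec(kind=kind, gene=g, exon=1, shift=13)
    if kind in ("novel_acceptor",):
        return EventSpec(kind=kind, gene=g, exon=2, shift=13)
    if kind == "retained_intron":
        return EventSpec(kind=kind, gene=g, intron=1)
    if kind == "ITD":
        return EventSpec(kind=kind, gene=g, exon=2, length=45)
    if kind == "insertion":
        return EventSpec(kind=kind, gene=g, exon=2, length=4)
    if kind == "deletion":
        return EventSpec(kind=kind, gene=g, exon=2, length=5)
    return EventSpec(kind=kind, gene=g)


def mirror_reference(reference: Reference) -> Reference:
    """The same gene universe on the opposite strand of a mirrored genome.

    Every chromosome is reverse-complemented and every gene's strand is
    flipped, with genomic coordinates mirrored (an interval (s, e) on a
    chromosome of length L maps to (L - e, L - s)).  Transcript-orientation
    structures (exon layout, CDS, cryptic features) are untouched, so
    planting the same event spec on both references must yield the same
    event at mirrored coordinates.
    """
    import copy

    from contigsv.io_formats import revcomp
    from contigsv.models import GeneModel, GeneModelSet, TranscriptModel

    genome = {c: revcomp(s) for c, s in reference.genome.items()}
    clen = {c: len(s) for c, s in reference.genome.items()}
    gms = GeneModelSet()
    builds = {}
    for gid, b in reference.builds.items():
        L = clen[b.chrom]
        nb = copy.deepcopy(b)
        nb.strand = "-" if b.strand == "+" else "+"
        nb.g0 = L - (b.g0 + b.length)
        builds[gid] = nb
        old_t = reference.gms.genes[gid].transcripts[0]
        exons = sorted((L - e, L - s) for s, e in old_t.exons)
        tm = TranscriptModel(
            transcript_id=old_t.transcript_id,
            exons=exons,
            strand=nb.strand,
            cds_start=L - old_t.cds_end if old_t.cds_end is not None else None,
            cds_end=L - old_t.cds_start if old_t.cds_start is not None else None,
        )
        gms.genes[gid] = GeneModel(
            gene_id=gid,
            gene_name=gid,
            chrom=b.chrom,
            strand=nb.strand,
            transcripts=[tm],
        )
    return Reference(
        genome=genome,
        gms=gms,
        transcripts=dict(reference.transcripts),
        builds=builds,
    )


def plant_all_classes(
    reference: Reference, rng_seed: int = 0, kinds=ALL_EVENT_KINDS
) -> list[PlantedContig]:
    """One planted contig per event class, each on fresh genes."""
    used: set[str] = set()
    out: list[PlantedContig] = []
    for i, kind in enumerate(kinds):
        spec = default_spec_for(kind, reference, used)
        if spec is None:
            raise ValueError(f"reference cannot host a {kind} event")
        pc = plant_event(reference, spec, rng_seed=rng_seed * 100 + i)
        out.append(pc)
        used.update(g for g in (spec.gene, spec.gene3) if g)
    return out
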