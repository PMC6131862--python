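"""Novel splicing-variant detection and splice-motif lookup."""
import pytest

from contigsv.annotation import GeneIndex
from contigsv.models import (
    ContigAlignment,
    GeneModel,
    GeneModelSet,
    PipelineConfig,
    TranscriptModel,
)
from contigsv.splice_caller import (
    call_splice_events,
    check_splice_motif,
    match_transcript,
)

CFG = PipelineConfig()


class TestSpliceMotif:
    def test_plus_strand_canonical(self):
        genome = {"c": "AAAA" + "GT" + "C" * 20 + "AG" + "TTTT"}
        motif, canon = check_splice_motif(genome, "c", 4, 28, "+")
        assert (motif, canon) == ("GT-AG", True)

    def test_minus_strand_reverse_complement(self):
        # plus-strand text CT...AC reads GT...AG on the minus strand
        genome = {"c": "AAAA" + "CT" + "C" * 20 + "AC" + "TTTT"}
        motif, canon = check_splice_motif(genome, "c", 4, 28, "-")
        assert (motif, canon) == ("GT-AG", True)

    def test_gc_ag_needs_extended_set(self):
        genome = {"c": "AAAA" + "GC" + "C" * 20 + "AG" + "TTTT"}
        motif, canon = check_splice_motif(genome, "c", 4, 28, "+")
        assert (motif, canon) == ("GC-AG", False)
        _, canon2 = check_splice_motif(
            genome, "c", 4, 28, "+", canonical_set=("GT-AG", "GC-AG", "AT-AC")
        )
        assert canon2 is True

    def test_degenerate_intron_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            check_splice_motif({"c": "ACGTACGT"}, "c", 2, 5, "+")

    def test_lookup_equals_direct_extraction_on_reference(self, reference):
        """Motif lookup agrees with direct substring extraction from the
        generated genome for every annotated intron."""
        from contigsv.io_formats import revcomp

        for g in reference.gms.genes.values():
            t = g.transcripts[0]
            for s, e in t.introns():
                motif, canon = check_splice_motif(reference.genome, g.chrom, s, e, g.strand)
                raw = reference.genome[g.chrom][s:e]
                if g.strand == "-":
                    raw = revcomp(raw)
                assert motif == f"{raw[:2]}-{raw[-2:]}" == "GT-AG"
                assert canon is True


def _two_isoform_models():
    gms = GeneModelSet()
    # isoform A: exons 1,2,3; isoform B: exons 1,3 (skips exon 2)
    tA = TranscriptModel("G.a", [(100, 200), (300, 400), (500, 600)], "+")
    tB = TranscriptModel("G.b", [(100, 200), (500, 600)], "+")
    gms.genes["G"] = GeneModel("G", "G", "c", "+", [tA, tB])
    return gms


def _aln(blocks, contig_len=None, strand="+", chrom="c", cid="ctg"):
    if contig_len is None:
        contig_len = max(b[3] for b in blocks)
    return ContigAlignment(
        contig_id=cid,
        contig_len=contig_len,
        chrom=chrom,
        strand=strand,
        blocks=blocks,
    )


class TestMatchTranscript:
    def test_identity_alignment_matches_all_exons(self):
        index = GeneIndex(_two_isoform_models())
        aln = _aln([(100, 200, 0, 100), (300, 400, 100, 200), (500, 600, 200, 300)])
        corr = match_transcript(aln, index)
        assert corr.transcript_id == "G.a"
        assert [(m[0], m[1]) for m in corr.matches] == [(0, 0), (1, 1), (2, 2)]
        assert all(m[2] and m[3] for m in corr.matches)
        assert corr.unmatched_blocks == [] and corr.unmatched_exons_in_span == []

    def test_missing_middle_block_reports_unmatched_exon(self):
        index = GeneIndex(_two_isoform_models())
        # force isoform A by removing isoform B from the gene
        gms = _two_isoform_models()
        gms.genes["G"].transcripts = [t for t in gms.genes["G"].transcripts if t.transcript_id == "G.a"]
        index = GeneIndex(gms)
        aln = _aln([(100, 200, 0, 100), (500, 600, 100, 200)])
        corr = match_transcript(aln, index)
        assert corr.unmatched_exons_in_span == [1]

    def test_isoform_choice_by_exhaustive_scoring(self):
        """The junction structure selects the matching isoform; exhaustive
        scoring over both isoforms confirms the tie-break order."""
        index = GeneIndex(_two_isoform_models())
        aln = _aln([(100, 200, 0, 100), (500, 600, 100, 200)])
        corr = match_transcript(aln, index)
        # independent check: the contig's only junction is an annotated
        # intron of isoform B and of no other isoform
        junction = (200, 500)
        explains = {
            t.transcript_id: junction in t.introns()
            for t in index.gms.genes["G"].transcripts
        }
        assert explains == {"G.a": False, "G.b": True}
        assert corr.transcript_id == "G.b"

    def test_no_overlapping_gene_gives_empty(self):
        index = GeneIndex(_two_isoform_models())
        corr = match_transcript(_aln([(5000, 5100, 0, 100)]), index)
        assert not corr

    def test_junction_matching_other_isoform_never_novel(self):
        """A contig using isoform B's exon1-exon3 junction produces no
        splice events even when isoform A scores equally on overlap."""
        index = GeneIndex(_two_isoform_models())
        aln = _aln([(100, 200, 0, 100), (500, 600, 100, 200)])
        corr = match_transcript(aln, index)
        genome = {"c": "A" * 700}
        assert call_splice_events(corr, aln, genome, index, CFG) == []


class TestPlantedSpliceClasses:
    """Each planted splicing class is recovered with exact coordinates and
    the motif the generator wrote into the genome."""

    def _event(self, universe, etype):
        evs = [e for e in universe["events"] if getattr(e, "coords", None) is not None]
        return [e for e in evs if e.event_type == etype]

    @pytest.mark.parametrize(
        "etype",
        ["skipped_exon", "novel_exon", "novel_intron", "retained_intron",
         "novel_donor", "novel_acceptor"],
    )
    def test_class_recovered_exactly(self, universe, etype):
        truths = [t for t in universe["truths"] if t.event_type == etype]
        assert truths, f"no planted {etype}"
        calls = self._event(universe, etype)
        assert len(calls) == len(truths)
        for t in truths:
            [match] = [c for c in calls if c.coords == t.coords]
            assert match.gene == t.gene5
            if t.splice_motif:
                assert match.splice_motif == t.splice_motif
            if t.canonical is not None:
                assert match.canonical == t.canonical

    def test_skipped_exon_junction_depth_counted(self, universe):
        [ev] = self._event(universe, "skipped_exon")
        assert ev.junction_depth > 0

    def test_novel_donor_motif_from_genome(self, universe, reference):
        """The shifted junction's motif equals direct extraction."""
        from contigsv.io_formats import revcomp

        [ev] = self._event(universe, "novel_donor")
        (s, e) = ev.coords[0]
        raw = reference.genome[ev.chrom][s:e]
        strand = reference.gms.genes[ev.gene].strand
        if strand == "-":
            raw = revcomp(raw)
        assert ev.splice_motif == f"{raw[:2]}-{raw[-2:]}"

    def test_variant_free_contigs_produce_no_events(self, universe):
        null_ids = {c for e in universe["events"] for c in e.contig_ids}
        assert not any(c.startswith("null_") for c in null_ids)


class TestStrandSymmetry:
    def test_mirrored_locus_yields_mirrored_events(self, tmp_path):
        """Flipping the whole universe to the opposite strand preserves
        every event class at mirrored coordinates."""
        from contigsv import synthetic_data as sd
        from contigsv.pipeline import run_call
        from contigsv.testkit import mirror_reference, plant_all_classes

        ref = sd.generate_reference(n_genes=16, rng_seed=12)
        mir = mirror_reference(ref)
        results = {}
        for tag, r in (("fwd", ref), ("mir", mir)):
            contigs = plant_all_classes(r, rng_seed=8)
            d = tmp_path / tag
            d.mkdir()
            paths = r.write(str(d / "ref"))
            fa, sam = str(d / "c.fa"), str(d / "c.sam")
            sd.emit_contig_alignments(contigs, r, fa, sam)
            res = run_call(fa, sam, paths["gtf"], paths["genome"])
            results[tag] = res["events"]
        clen = {c: len(s) for c, s in ref.genome.items()}

        def canon(events):
            out = set()
            for ev in events:
                if hasattr(ev, "coords"):
                    out.add((ev.event_type, ev.gene, tuple(ev.coords)))
                else:
                    out.add(
                        (ev.event_type, ev.gene5, ev.gene3,
                         frozenset({(ev.chrom1, ev.pos1), (ev.chrom2, ev.pos2)}))
                    )
            return out

        def mirror_canon(events):
            out = set()
            for ev in events:
                if hasattr(ev, "coords"):
                    L = clen[ev.chrom]
                    coords = tuple(sorted((L - e, L - s) for s, e in ev.coords))
                    out.add((ev.event_type, ev.gene, coords))
                else:
                    L1, L2 = clen[ev.chrom1], clen[ev.chrom2]
                    out.add(
                        (ev.event_type, ev.gene5, ev.gene3,
                         frozenset({(ev.chrom1, L1 - 1 - ev.pos1),
                                    (ev.chrom2, L2 - 1 - ev.pos2)}))
                    )
            return out

        assert canon(results["fwd"]) == mirror_canon(results["mir"])
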