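"""Adjacency discovery, event classification and frame arithmetic."""
import numpy as np
import pytest

from contigsv.annotation import GeneIndex
from contigsv.models import (
    Adjacency,
    Breakpoint,
    ContigAlignment,
    GapRecord,
    GeneModel,
    GeneModelSet,
    PipelineConfig,
    TranscriptModel,
)
from contigsv.sv_caller import (
    _fusion_frame,
    _minimal_unit,
    call_gapped_events,
    classify_adjacency,
    find_adjacencies,
    merge_and_filter,
)

CFG = PipelineConfig()


def _aln(contig_id, chrom, strand, blocks, contig_len=2000):
    return ContigAlignment(
        contig_id=contig_id,
        contig_len=contig_len,
        chrom=chrom,
        strand=strand,
        blocks=blocks,
    )


class TestFindAdjacencies:
    def test_clean_split(self):
        a = _aln("c1", "chrA", "+", [(9500, 10000, 0, 500)])
        b = _aln("c1", "chrB", "+", [(50000, 50400, 500, 900)])
        [adj] = find_adjacencies([a, b], "A" * 900, CFG)
        assert (adj.breakpoint1.chrom, adj.breakpoint1.pos, adj.breakpoint1.orient) == (
            "chrA", 9999, "L",
        )
        assert (adj.breakpoint2.chrom, adj.breakpoint2.pos, adj.breakpoint2.orient) == (
            "chrB", 50000, "R",
        )
        assert adj.novel_seq == "" and adj.homology_seq == ""

    def test_single_alignment_yields_nothing(self):
        a = _aln("c1", "chrA", "+", [(9500, 10000, 0, 500)])
        assert find_adjacencies([a], "A" * 500, CFG) == []

    def test_untemplated_insert_carried_as_novel_seq(self):
        contig = "A" * 500 + "TTGGCCAA" + "G" * 392
        a = _aln("c1", "chrA", "+", [(9500, 10000, 0, 500)])
        b = _aln("c1", "chrB", "+", [(50000, 50392, 508, 900)])
        [adj] = find_adjacencies([a, b], contig, CFG)
        assert adj.novel_seq == "TTGGCCAA"
        assert adj.contig_break2 - adj.contig_break1 == 8

    def test_microhomology_left_aligned_against_enumeration(self):
        """All breakpoint placements consistent with a 6-base overlap are
        enumerated by brute force; the reported pair must be the one with
        the lowest genome coordinate on breakpoint1's side."""
        a = _aln("c1", "chrA", "+", [(9000, 9506, 0, 506)])
        b = _aln("c1", "chrB", "+", [(50000, 50406, 500, 906)])
        [adj] = find_adjacencies([a, b], "C" * 906, CFG)
        assert len(adj.homology_seq) == 6
        placements = []
        for s in range(500, 507):  # every consistent contig split point
            t_a, t_b = 506 - s, s - 500
            placements.append((9505 - t_a, 50000 + t_b))
        best = min(placements)
        assert (adj.breakpoint1.pos, adj.breakpoint2.pos) == best

    def test_short_fragments_ignored(self):
        a = _aln("c1", "chrA", "+", [(9000, 9020, 0, 20)])  # < min_fragment_len
        b = _aln("c1", "chrB", "+", [(50000, 50400, 20, 420)])
        assert find_adjacencies([a, b], "A" * 420, CFG) == []

    def test_input_order_invariance(self):
        a = _aln("c1", "chrA", "+", [(9500, 10000, 0, 500)])
        b = _aln("c1", "chrB", "-", [(50000, 50400, 500, 900)])
        r1 = find_adjacencies([a, b], "A" * 900, CFG)
        r2 = find_adjacencies([b, a], "A" * 900, CFG)
        assert r1 == r2


def _toy_models() -> GeneModelSet:
    gms = GeneModelSet()

    def add(gid, chrom, strand, exons, cds=None):
        t = TranscriptModel(
            transcript_id=f"{gid}.t1",
            exons=exons,
            strand=strand,
            cds_start=cds[0] if cds else None,
            cds_end=cds[1] if cds else None,
        )
        gms.genes[gid] = GeneModel(gid, gid, chrom, strand, [t])

    add(
        "GX", "chrM", "+",
        [(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700),
         (3000, 3200), (3500, 3700)],
        cds=(1050, 3650),
    )
    add("GY", "chrM", "+", [(50000, 50200), (50500, 50700)], cds=(50060, 50660))
    add("P", "chrM", "+", [(20000, 20200), (20500, 20700)])
    add("Q", "chrM", "+", [(21000, 21200), (21500, 21700)])
    return gms


@pytest.fixture(scope="module")
def toy_index():
    return GeneIndex(_toy_models())


def _adj(c1, p1, o1, c2, p2, o2, novel=""):
    return Adjacency(
        contig_id="c1",
        breakpoint1=Breakpoint(c1, p1, o1),
        breakpoint2=Breakpoint(c2, p2, o2),
        contig_break1=100,
        contig_break2=100 + len(novel),
        novel_seq=novel,
    )


class TestClassifyAdjacency:
    def test_ptd_whole_exons_at_boundaries(self, toy_index):
        """Duplication of exons 2-6 with both breakpoints on annotated
        boundaries is a partial tandem duplication."""
        ev = classify_adjacency(_adj("chrM", 3699, "L", "chrM", 1500, "R"), toy_index, CFG)
        assert ev.event_type == "PTD"
        assert ev.exons_involved == [2, 6]
        assert ev.at_exon_boundary == "both"
        assert ev.gene5 == ev.gene3 == "GX"

    def test_itd_interior_to_one_exon(self, toy_index):
        ev = classify_adjacency(_adj("chrM", 2150, "L", "chrM", 2100, "R"), toy_index, CFG)
        assert ev.event_type == "ITD"
        assert ev.exons_involved == [3]
        # 51 duplicated bases: frame preserved
        assert ev.in_frame is True

    def test_fusion_one_boundary(self, toy_index):
        """Junction from an exon boundary of one gene into the interior of
        another gene's exon 10 Mb away on the same chromosome."""
        ev = classify_adjacency(_adj("chrM", 1699, "L", "chrM", 50100, "R"), toy_index, CFG)
        assert ev.event_type == "fusion"
        assert ev.at_exon_boundary == "one"
        assert (ev.gene5, ev.gene3) == ("GX", "GY")

    def test_read_through_adjacent_same_strand(self, toy_index):
        ev = classify_adjacency(_adj("chrM", 20699, "L", "chrM", 21000, "R"), toy_index, CFG)
        assert ev.event_type == "read_through"
        assert (ev.gene5, ev.gene3) == ("P", "Q")

    def test_non_adjacent_boundary_junction_is_fusion(self, toy_index):
        # GX -> GY junction at boundaries: P/Q sit closer, but GX/GY are
        # still "adjacent" only if no same-strand gene lies between; P does
        ev = classify_adjacency(_adj("chrM", 3699, "L", "chrM", 50500, "R"), toy_index, CFG)
        assert ev.event_type == "fusion"

    def test_intergenic_breakpoints_filtered(self, toy_index):
        ev = classify_adjacency(_adj("chrM", 70000, "L", "chrM", 75000, "R"), toy_index, CFG)
        assert ev.filter_status == "intergenic"

    def test_antisense_gene_order_flips_five_prime(self, toy_index):
        """When both fragments align antisense to their genes, the contig
        is the reverse complement of the chimeric transcript and the
        second locus contributes the 5' side."""
        # R-then-L with '+' genes means both fragments aligned '-'
        ev = classify_adjacency(_adj("chrM", 50500, "R", "chrM", 1699, "L"), toy_index, CFG)
        assert (ev.gene5, ev.gene3) == ("GX", "GY")


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60000)])
    # plant an AG tract ending at position 2100 inside GX exon 3
    seq = seq[:2088] + "C" + "AG" * 5 + "C" + seq[2100:]
    return {"chrM": seq}


class TestGappedEvents:
    def _aln_with_gap(self, gap):
        return ContigAlignment(
            contig_id="c1",
            contig_len=300,
            chrom="chrM",
            strand="+",
            blocks=[(gap.genome_pos - 100, gap.genome_pos, 0, 100)],
            gaps=[gap],
        )

    def test_plain_insertion(self, toy_index, genome):
        ins = "TTAC"  # does not match flanks at 2150
        gap = GapRecord("insertion", 2150, 100, 4, ins)
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.event_type == "insertion"
        assert ev.in_frame is False  # 4 % 3 != 0 inside the CDS

    def test_flank_duplication_promoted_to_itd(self, toy_index, genome):
        dup = genome["chrM"][2105:2150]
        gap = GapRecord("insertion", 2150, 100, 45, dup)
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.event_type == "ITD"
        assert ev.in_frame is True

    def test_short_duplication_stays_duplication(self, toy_index, genome):
        dup = genome["chrM"][2145:2150]
        gap = GapRecord("insertion", 2150, 100, 5, dup)
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.event_type == "duplication"  # below min_itd_len

    def test_repeat_expansion_minimal_unit(self, toy_index, genome):
        """An AGAGAG insertion next to an AG tract decomposes into the
        minimal unit rather than a whole-length duplication."""
        gap = GapRecord("insertion", 2099, 100, 6, "AGAGAG")
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.event_type == "repeat_expansion"

    def test_repeat_contraction(self, toy_index, genome):
        gap = GapRecord("deletion", 2093, 100, 4)  # removes AGAG within tract
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.event_type == "repeat_contraction"

    def test_intronic_gap_flagged(self, toy_index, genome):
        gap = GapRecord("insertion", 1300, 100, 4, "TTAC")  # GX intron 1
        [ev] = call_gapped_events(self._aln_with_gap(gap), "", genome, toy_index, CFG)
        assert ev.filter_status == "intronic"

    def test_agrees_with_bruteforce_oracle_on_random_cases(self, toy_index, genome):
        """Classification matches a brute-force oracle that slides every
        candidate unit length over both flanks, on randomised insertions."""

        def oracle(pos, seq):
            n = len(seq)
            g = genome["chrM"]
            for u in range(1, min(6, n - 1) + 1):
                if n % u == 0 and seq == seq[:u] * (n // u):
                    if g[pos - u : pos] == seq[:u] or g[pos : pos + u] == seq[:u]:
                        return "repeat_expansion"
                    break  # minimal unit not flanking; try duplication
            if seq in (g[pos - n : pos], g[pos : pos + n]):
                return "duplication"
            return "insertion"

        rng = np.random.default_rng(5)
        g = genome["chrM"]
        for _ in range(200):
            pos = int(rng.integers(2010, 2190))  # inside GX exon 3
            style = rng.integers(0, 4)
            if style == 0:
                L = int(rng.integers(1, 10))
                seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            elif style == 1:  # exact flank copy
                L = int(rng.integers(2, 30))
                seq = g[pos - L : pos]
            elif style == 2:  # repeat of the immediate left flank unit
                u = int(rng.integers(1, 4))
                seq = g[pos - u : pos] * int(rng.integers(2, 4))
            else:  # following-flank copy
                L = int(rng.integers(2, 20))
                seq = g[pos : pos + L]
            gap = GapRecord("insertion", pos, 100, len(seq), seq)
            [ev] = call_gapped_events(
                self._aln_with_gap(gap), "", genome, toy_index, CFG
            )
            want = oracle(pos, seq)
            got = "duplication" if ev.event_type == "ITD" else ev.event_type
            assert got == want, (pos, seq, got, want)


class TestFrame:
    def test_minimal_unit_decomposition(self):
        assert _minimal_unit("AGAGAG", 6) == "AG"
        assert _minimal_unit("AAAA", 6) == "A"
        assert _minimal_unit("AGC", 6) is None  # not decomposable
        assert _minimal_unit("AGCAGC", 2) is None  # unit above limit

    def test_fusion_frame_phase_arithmetic(self, toy_index):
        gms = toy_index.gms
        t5 = gms.get_transcript("GX.t1")
        t3 = gms.get_transcript("GY.t1")
        # 150 coding bases upstream (1050..1199), downstream at phase 0
        assert _fusion_frame(t5, 1199, t3, 50063, 0) is True
        # a 1-base untemplated insert breaks the frame
        assert _fusion_frame(t5, 1199, t3, 50063, 1) is False
        # downstream phase 1 does not complete the codon
        assert _fusion_frame(t5, 1199, t3, 50064, 0) is False

    def test_na_outside_cds(self, toy_index):
        gms = toy_index.gms
        t5 = gms.get_transcript("GX.t1")
        t3 = gms.get_transcript("GY.t1")
        assert _fusion_frame(t5, 1020, t3, 50063, 0) is None  # 5' UTR
        tP = gms.get_transcript("P.t1")  # no CDS annotated
        assert _fusion_frame(tP, 80100, t3, 50063, 0) is None

    def test_translation_oracle_agreement_on_random_fusions(
        self, reference, tmp_path
    ):
        """The caller's phase arithmetic must agree with direct translation
        of the reconstructed chimeric CDS on >= 100 random fusions."""
        import os

        from contigsv import synthetic_data as sd
        from contigsv.pipeline import run_call
        from contigsv.synthetic_data import EventSpec, plant_event

        rng = np.random.default_rng(17)
        gids = reference.gene_ids()
        chrom_of = {g: reference.builds[g].chrom for g in gids}
        contigs = []
        for i in range(110):
            g5, g3 = rng.choice(gids, size=2, replace=False)
            if chrom_of[g5] == chrom_of[g3]:
                g3 = next(g for g in gids if chrom_of[g] != chrom_of[g5])
            b5, b3 = reference.builds[g5], reference.builds[g3]
            spec = EventSpec(
                kind="fusion",
                gene=g5,
                gene3=g3,
                exon=int(rng.integers(2, b5.n_exons + 1)),
                exon3=int(rng.integers(1, b3.n_exons)),
                boundary5=bool(rng.integers(0, 2)),
                boundary3=bool(rng.integers(0, 2)),
                offset5=int(rng.integers(5, 40)),
                offset3=int(rng.integers(5, 40)),
                insert_len=int(rng.choice([0, 0, 1, 2, 3, 6])),
            )
            pc = plant_event(reference, spec, rng_seed=1000 + i)
            pc.contig_id = f"{pc.contig_id}_{i}"
            for t in pc.truths:
                t.contig_id = pc.contig_id
            contigs.append(pc)
        paths = reference.write(str(tmp_path / "ref"))
        fa, sam = str(tmp_path / "c.fa"), str(tmp_path / "c.sam")
        sd.emit_contig_alignments(contigs, reference, fa, sam)
        cfg = PipelineConfig(restrict_exon_boundary=False)
        res = run_call(fa, sam, paths["gtf"], paths["genome"], config=cfg)
        by_contig = {}
        for ev in res["events"]:
            if not hasattr(ev, "coords") and ev.event_type == "fusion":
                for cid in ev.contig_ids:
                    by_contig[cid] = ev
        checked = 0
        for pc in contigs:
            truth = pc.truths[0]
            ev = by_contig.get(pc.contig_id)
            assert ev is not None, pc.contig_id
            assert ev.in_frame == truth.in_frame, (
                pc.contig_id, ev.in_frame, truth.in_frame,
            )
            checked += 1
        assert checked >= 100


class TestMergeAndFilter:
    def _fusion(self, cid, pos1=1699, boundary="both"):
        return classify_adjacency(
            _adj("chrM", pos1, "L", "chrM", 50500, "R"),
            GeneIndex(_toy_models()),
            CFG,
        )

    def test_same_breakpoint_two_assemblies_merges(self, toy_index):
        e1 = classify_adjacency(_adj("chrM", 1699, "L", "chrM", 50500, "R"), toy_index, CFG)
        e2 = classify_adjacency(_adj("chrM", 1699, "L", "chrM", 50500, "R"), toy_index, CFG)
        e1.contig_ids, e2.contig_ids = ["k32"], ["k52"]
        [m] = merge_and_filter([e1, e2], restrict_exon_boundary=True)
        assert m.contig_ids == ["k32", "k52"]

    def test_distinct_breakpoint_alleles_stay_separate(self, toy_index):
        e1 = classify_adjacency(_adj("chrM", 1699, "L", "chrM", 50500, "R"), toy_index, CFG)
        e2 = classify_adjacency(_adj("chrM", 1199, "L", "chrM", 50500, "R"), toy_index, CFG)
        assert len(merge_and_filter([e1, e2], True)) == 2

    def test_exon_boundary_restriction_flag(self, toy_index):
        mid = classify_adjacency(_adj("chrM", 1650, "L", "chrM", 50100, "R"), toy_index, CFG)
        assert mid.at_exon_boundary == "none"
        [flagged] = merge_and_filter([mid], restrict_exon_boundary=True)
        assert flagged.filter_status == "not_exon_boundary"
        mid2 = classify_adjacency(_adj("chrM", 1650, "L", "chrM", 50100, "R"), toy_index, CFG)
        [passed] = merge_and_filter([mid2], restrict_exon_boundary=False)
        assert passed.filter_status == "PASS"
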