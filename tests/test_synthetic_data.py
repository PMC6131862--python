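"""Determinism and fidelity of the synthetic-data generator."""
import numpy as np
import pytest

from contigsv import synthetic_data as sd
from contigsv.io_formats import parse_contig_alignments, read_fasta, revcomp
from contigsv.sv_caller import find_adjacencies


class TestGenerateReference:
    def test_byte_identical_for_fixed_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            sd.generate_reference(n_genes=4, rng_seed=7).write(str(d))
        for name in ("genome.fa", "genes.gtf", "transcripts.fa"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self):
        r1 = sd.generate_reference(n_genes=3, rng_seed=1)
        r2 = sd.generate_reference(n_genes=3, rng_seed=2)
        assert r1.genome != r2.genome

    def test_every_intron_canonical_strand_adjusted(self, reference):
        for b in reference.builds.values():
            for p, q in b.intron_local():
                gs, ge = b.local_iv_to_genome(p, q)
                txt = reference.genome[b.chrom][gs:ge]
                if b.strand == "-":
                    txt = revcomp(txt)
                assert txt.startswith("GT") and txt.endswith("AG")

    def test_cds_is_an_orf(self, reference):
        from Bio.Seq import Seq

        for b in reference.builds.values():
            s = reference.transcripts[b.transcript_id]
            c0, c1 = b.cds_t
            cds = s[c0:c1]
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            prot = str(Seq(cds).translate())
            assert prot.endswith("*")

    def test_unworkable_ranges_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_reference(n_genes=2, exon_len_range=(30, 50))
        with pytest.raises(ValueError):
            sd.generate_reference(n_genes=1)

    def test_genes_on_both_strands(self, reference):
        strands = {b.strand for b in reference.builds.values()}
        assert strands == {"+", "-"}


class TestPlantEvent:
    def test_inconsistent_spec_raises(self, reference):
        g = reference.gene_ids()[0]
        n_ex = reference.builds[g].n_exons
        with pytest.raises(ValueError, match="exceeds exon count"):
            sd.plant_event(reference, sd.EventSpec(kind="PTD", gene=g, exons=[2, n_ex + 3]))
        with pytest.raises(ValueError, match="terminal"):
            sd.plant_event(reference, sd.EventSpec(kind="skipped_exon", gene=g, exons=[1]))

    def test_itd_plants_tandem_copy(self, reference):
        g = reference.gene_ids()[0]
        pc = sd.plant_event(reference, sd.EventSpec(kind="ITD", gene=g, exon=2, length=45))
        t = pc.truths[0]
        assert t.event_type == "ITD" and t.in_frame is True
        # the contig contains the duplicated 45-mer twice in tandem
        dup = t.novel_seq if reference.builds[g].strand == "+" else revcomp(t.novel_seq)
        assert dup * 2 in pc.seq

    def test_fusion_truth_roundtrips_through_alignment(self, reference, tmp_path):
        """Emitting the oracle SAM for a fusion contig and re-deriving the
        adjacency reproduces the planted breakpoints exactly."""
        gids = reference.gene_ids()
        g5 = gids[0]
        g3 = next(
            g for g in gids if reference.builds[g].chrom != reference.builds[g5].chrom
        )
        pc = sd.plant_event(
            reference,
            sd.EventSpec(kind="fusion", gene=g5, gene3=g3, exon=2, exon3=2, insert_len=5),
            rng_seed=3,
        )
        fa, sam = str(tmp_path / "c.fa"), str(tmp_path / "c.sam")
        sd.emit_contig_alignments([pc], reference, fa, sam)
        contigs = read_fasta(fa)
        groups = parse_contig_alignments(sam, contigs)
        [adjs] = [find_adjacencies(alns, contigs[cid]) for cid, alns in groups.items()]
        [adj] = adjs
        t = pc.truths[0]
        assert (adj.breakpoint1.chrom, adj.breakpoint1.pos, adj.breakpoint1.orient) == (
            t.chrom1, t.pos1, t.orient1,
        )
        assert (adj.breakpoint2.chrom, adj.breakpoint2.pos, adj.breakpoint2.orient) == (
            t.chrom2, t.pos2, t.orient2,
        )
        assert adj.novel_seq == t.novel_seq or revcomp(adj.novel_seq) == t.novel_seq


class TestReadSimulation:
    def test_pair_count_matches_coverage(self, reference):
        seq = "A" * 3000
        pairs = sd.simulate_read_pairs({"c": seq}, coverage=30, read_len=100, rng_seed=1)
        assert abs(len(pairs) - 450) <= 45  # 30x * 3000 / 200 = 450 +/- 10%

    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        pairs = sd.simulate_read_pairs({"c": seq}, coverage=5, sub_error_rate=0, rng_seed=2)
        assert pairs
        for p in pairs:
            assert p.seq1 in seq
            assert revcomp(p.seq2) in seq

    def test_substitution_rate_within_binomial_bounds(self):
        """Measured mismatch fraction at the default error rate agrees with
        the binomial expectation over >= 1e5 bases."""
        rng = np.random.default_rng(4)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        rate = 0.0037
        pairs = sd.simulate_read_pairs(
            {"c": seq}, coverage=50, sub_error_rate=rate, rng_seed=5
        )
        mism = total = 0
        for p in pairs:
            ref1 = seq[p.frag_start : p.frag_start + 100]
            ref2 = revcomp(seq[p.frag_end - 100 : p.frag_end])
            for a, b in zip(p.seq1 + p.seq2, ref1 + ref2):
                total += 1
                mism += a != b
        assert total >= 1e5
        se = (rate * (1 - rate) / total) ** 0.5
        assert abs(mism / total - rate) <= 3 * se

    def test_short_sequence_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            pairs = sd.simulate_read_pairs({"c": "A" * 150}, coverage=10, rng_seed=1)
        assert pairs == []

    def test_deterministic_under_seed(self):
        seq = "ACGT" * 500
        p1 = sd.simulate_read_pairs({"c": seq}, coverage=10, rng_seed=9)
        p2 = sd.simulate_read_pairs({"c": seq}, coverage=10, rng_seed=9)
        assert [(p.seq1, p.seq2) for p in p1] == [(p.seq1, p.seq2) for p in p2]


class TestSegmentSlicing:
    def test_window_preserves_junction_break(self, reference):
        gids = reference.gene_ids()
        g5 = gids[0]
        g3 = next(
            g for g in gids if reference.builds[g].chrom != reference.builds[g5].chrom
        )
        pc = sd.plant_event(
            reference, sd.EventSpec(kind="fusion", gene=g5, gene3=g3, exon=2, exon3=2)
        )
        jc = sum(b - a for a, b in reference.builds[g5].exon_local[:2])
        win = sd.slice_segments(pc.segments, jc - 50, jc + 50)
        assert any(s.kind == "break" for s in win)
        assert sum(s.tlen() for s in win) == 100
        left = sd.slice_segments(pc.segments, jc - 50, jc)
        assert not any(s.kind == "break" for s in left)
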