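"""Coverage-titration benchmark of fusion calling on synthetic data.

Reads are simulated at a grid of breakpoint coverages from windows around
planted fusion junctions, mixed with background reads from non-fusion
transcripts at a second coverage grid.  Assembly is not re-implemented:
its coverage dependence is emulated by truncating the oracle contig at the
junction whenever fewer than a reconstructibility threshold of simulated
reads span it (default: the same four-read rule used for event support).
Per cell, a true positive is a PASS fusion call whose gene pair matches a
planted pair; false positives are counted against all background
transcript pairs.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import pandas as pd

from .models import PipelineConfig
from .pipeline import run_call
from .synthetic_data import (
    EventSpec,
    PlantedContig,
    Reference,
    SimulatedPair,
    _exon_segments,
    emit_contig_alignments,
    generate_reference,
    plant_event,
    simulate_read_pairs,
    slice_segments,
    write_r2c_sam,
)


@dataclass
class TitrationDesign:
    n_fusion_events: int = 20
    n_background: int = 40
    breakpoint_coverages: tuple[int, ...] = tuple(range(4, 21, 2))
    background_coverages: tuple[int, ...] = tuple(range(10, 41, 10))
    insert_size_mean: int = 250
    insert_size_sd: float = 25.0
    read_length: int = 100
    error_rate: float = 0.0037
    rng_seed: int = 0
    min_support: int = 4
    full_length_contigs: bool = False

    def __post_init__(self):
        if not self.breakpoint_coverages or not self.background_coverages:
            raise ValueError("coverage grids must be non-empty")
        if any(c <= 0 for c in self.breakpoint_coverages + self.background_coverages):
            raise ValueError("coverages must be positive")


@dataclass
class FusionUniverse:
    reference: Reference
    fusions: list[PlantedContig]
    junction_offsets: dict[str, int]  # contig_id -> junction tpos
    truth_pairs: set[frozenset]
    background: list[PlantedContig]


def build_fusion_universe(
    n_fusions: int,
    n_background: int,
    rng_seed: int = 0,
    exon5: int = 2,
    exon3: int = 2,
) -> FusionUniverse:
    """A reference with planted inter-chromosomal fusions plus background.

    Gene 2i fuses to gene 2i+1 (always on different chromosomes, at exon
    boundaries, so every planted event is an unambiguous fusion);
    the remaining genes contribute whole transcripts as background.
    """
    n_genes = 2 * n_fusions + n_background
    ref = generate_reference(n_genes=max(2, n_genes), rng_seed=rng_seed, n_chroms=2)
    gids = ref.gene_ids()
    fusions: list[PlantedContig] = []
    offsets: dict[str, int] = {}
    pairs: set[frozenset] = set()
    for i in range(n_fusions):
        g5, g3 = gids[2 * i], gids[2 * i + 1]
        b5 = ref.builds[g5]
        e5 = min(exon5, b5.n_exons - 1)
        spec = EventSpec(kind="fusion", gene=g5, gene3=g3, exon=e5, exon3=exon3)
        pc = plant_event(ref, spec, rng_seed=rng_seed * 1000 + i)
        pc.contig_id = f"{pc.contig_id}_{i}"
        for t in pc.truths:
            t.contig_id = pc.contig_id
        fusions.append(pc)
        offsets[pc.contig_id] = sum(
            b - a for a, b in b5.exon_local[:e5]
        )
        pairs.add(frozenset((g5, g3)))
    background = []
    for g in gids[2 * n_fusions :]:
        b = ref.builds[g]
        segs = _exon_segments(b, 1, b.n_exons)
        from .synthetic_data import contig_sequence

        background.append(
            PlantedContig(f"ctg_bg_{g}", contig_sequence(ref.genome, segs), segs, [])
        )
    return FusionUniverse(ref, fusions, offsets, pairs, background)


def _spanning_pairs(
    pairs: list[SimulatedPair], junction: int, read_len: int, overhang: int = 4
) -> int:
    n = 0
    lo, hi = junction - overhang, junction + overhang
    for p in pairs:
        r1 = (p.frag_start, p.frag_start + read_len)
        r2 = (p.frag_end - read_len, p.frag_end)
        if (r1[0] <= lo and r1[1] >= hi) or (r2[0] <= lo and r2[1] >= hi):
            n += 1
    return n


def _run_cell(
    uni: FusionUniverse,
    design: TitrationDesign,
    bp_cov: int,
    bg_cov: int,
    cell_seed: int,
    workdir: str,
    config: PipelineConfig,
) -> dict:
    ref = uni.reference
    win = design.insert_size_mean
    rl = design.read_length

    # breakpoint windows and their reads
    contigs: list[PlantedContig] = []
    all_pairs: list[SimulatedPair] = []
    windows: dict[str, tuple[int, int, int]] = {}  # cid -> (ws, we, junction_local)
    win_seqs = {}
    for pc in uni.fusions:
        jc = uni.junction_offsets[pc.contig_id]
        ws, we = max(0, jc - win), min(len(pc.seq), jc + win)
        windows[pc.contig_id] = (ws, we, jc - ws)
        win_seqs[f"{pc.contig_id}|w"] = pc.seq[ws:we]
    bp_pairs = simulate_read_pairs(
        win_seqs,
        coverage=bp_cov,
        read_len=rl,
        insert_mean=design.insert_size_mean,
        insert_sd=design.insert_size_sd,
        sub_error_rate=design.error_rate,
        rng_seed=cell_seed,
    )
    for pc in uni.fusions:
        ws, we, jloc = windows[pc.contig_id]
        wid = f"{pc.contig_id}|w"
        pairs_here = [p for p in bp_pairs if p.source == wid]
        if design.full_length_contigs:
            # full-length contig: reads shift by the window offset
            contigs.append(pc)
            for p in pairs_here:
                p.source = pc.contig_id
                p.frag_start += ws
                p.frag_end += ws
            all_pairs.extend(pairs_here)
            continue
        spanning = _spanning_pairs(pairs_here, jloc, rl, config.min_overhang)
        if spanning >= design.min_support:
            segs = slice_segments(pc.segments, ws, we)
            contigs.append(
                PlantedContig(wid, pc.seq[ws:we], segs, pc.truths)
            )
            all_pairs.extend(pairs_here)
        else:
            # junction not reconstructible at this coverage: only the 5'
            # side of the window is recovered
            jc_abs = ws + jloc
            segs = slice_segments(pc.segments, ws, jc_abs)
            contigs.append(
                PlantedContig(wid + "5", pc.seq[ws:jc_abs], segs, [])
            )
            kept = []
            for p in pairs_here:
                if p.frag_end <= jloc:
                    p.source = wid + "5"
                    kept.append(p)
            all_pairs.extend(kept)

    contigs.extend(uni.background)
    bg_pairs = simulate_read_pairs(
        {pc.contig_id: pc.seq for pc in uni.background},
        coverage=bg_cov,
        read_len=rl,
        insert_mean=design.insert_size_mean,
        insert_sd=design.insert_size_sd,
        sub_error_rate=design.error_rate,
        rng_seed=cell_seed + 1,
    )
    all_pairs.extend(bg_pairs)

    # write inputs and run the caller
    paths = ref.write(os.path.join(workdir, "ref"))
    contig_fa = os.path.join(workdir, "contigs.fa")
    c2g = os.path.join(workdir, "c2g.sam")
    r2c = os.path.join(workdir, "r2c.sam")
    emit_contig_alignments(contigs, ref, contig_fa, c2g, config.min_intron_size)
    write_r2c_sam(
        all_pairs, {c.contig_id: len(c.seq) for c in contigs}, r2c, read_len=rl
    )
    result = run_call(
        contig_fa, c2g, paths["gtf"], paths["genome"], r2c_path=r2c, config=config
    )
    called_pairs = {
        frozenset((ev.gene5, ev.gene3))
        for ev in result["events"]
        if getattr(ev, "event_type", "") in ("fusion", "read_through")
        and ev.filter_status == "PASS"
        and ev.gene5
        and ev.gene3
    }
    return score_fusion_calls(called_pairs, uni.truth_pairs, len(uni.background))


def score_fusion_calls(
    called_pairs: set[frozenset],
    truth_pairs: set[frozenset],
    n_background: int,
) -> dict:
    """Sensitivity and false-positive rate of a set of fusion gene pairs.

    Order-invariant: pairs are unordered sets of gene ids.  The FPR
    denominator is the number of evaluable background transcript pairs.
    """
    tp = len(called_pairs & truth_pairs)
    fp = len(called_pairs - truth_pairs)
    n_eval = max(1, len(list(combinations(range(n_background), 2))))
    sens = 100.0 * tp / len(truth_pairs) if truth_pairs else float("nan")
    fpr = 100.0 * fp / n_eval
    return {"tp": tp, "fp": fp, "sensitivity_pct": sens, "fpr_pct": fpr}


def run_titration_and_evaluate(
    design: TitrationDesign,
    workdir: Optional[str] = None,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Run the full coverage grid and tabulate sensitivity/FPR per cell."""
    cfg = (config or PipelineConfig()).updated(min_support=design.min_support)
    uni = build_fusion_universe(
        design.n_fusion_events, design.n_background, rng_seed=design.rng_seed
    )
    rows = []
    own_tmp = workdir is None
    tmp = tempfile.mkdtemp(prefix="titration_") if own_tmp else workdir
    try:
        for bp_cov in design.breakpoint_coverages:
            for bg_cov in design.background_coverages:
                cell_seed = (design.rng_seed * 10007 + bp_cov * 101 + bg_cov) % (2**31)
                cell_dir = os.path.join(tmp, f"cell_{bp_cov}_{bg_cov}")
                os.makedirs(cell_dir, exist_ok=True)
                res = _run_cell(uni, design, bp_cov, bg_cov, cell_seed, cell_dir, cfg)
                rows.append(
                    {"breakpoint_cov": bp_cov, "background_cov": bg_cov, **res}
                )
    finally:
        if own_tmp:
            import shutil

            shutil.rmtree(tmp, ignore_errors=True)
    return pd.DataFrame(rows)


def binning_accuracy_benchmark(
    n_target: int = 40,
    n_nontarget: int = 40,
    coverages: tuple[int, ...] = tuple(range(10, 101, 10)),
    error_rate: float = 0.0037,
    read_len: int = 100,
    insert_mean: int = 250,
    rng_seed: int = 3,
    k: int = 25,
    fpr: float = 1e-3,
    allowed_miss: int = 2,
) -> dict:
    """Read-classification accuracy of the spaced-seed filter.

    A synthetic panel of target and non-target genes is generated, the
    filter is built from the target transcripts only, and paired reads are
    simulated from every transcript at each coverage with substitution
    errors.  Sensitivity is the fraction of target-origin reads classified
    to their true gene; specificity is the fraction of non-target-origin
    reads left unclassified; both are pooled over the coverage grid.
    """
    from .read_binning import SpacedSeedSet, build_filter, classify_batch

    ref = generate_reference(
        n_genes=n_target + n_nontarget, rng_seed=rng_seed, n_chroms=2
    )
    gids = ref.gene_ids()
    target_genes = gids[:n_target]
    targets = {
        g: [ref.transcripts[ref.builds[g].transcript_id]] for g in target_genes
    }
    seeds = SpacedSeedSet.generate(k=k, allowed_miss=allowed_miss)
    filt = build_filter(targets, k=k, seeds=seeds, fpr=fpr)

    all_seqs = {
        ref.builds[g].transcript_id: ref.transcripts[ref.builds[g].transcript_id]
        for g in gids
    }
    tid_gene = {ref.builds[g].transcript_id: g for g in gids}
    target_set = set(target_genes)

    tp = t_total = tn = n_total = 0
    for ci, cov in enumerate(coverages):
        pairs = simulate_read_pairs(
            all_seqs,
            coverage=cov,
            read_len=read_len,
            insert_mean=insert_mean,
            sub_error_rate=error_rate,
            rng_seed=(rng_seed * 7919 + ci) % (2**31),
        )
        reads = [p.seq1 for p in pairs] + [p.seq2 for p in pairs]
        origins = [tid_gene[p.source] for p in pairs] * 2
        assigned = classify_batch(reads, filt)
        for origin, got in zip(origins, assigned):
            if origin in target_set:
                t_total += 1
                if got == origin:
                    tp += 1
            else:
                n_total += 1
                if got is None:
                    tn += 1
    return {
        "sensitivity_pct": 100.0 * tp / max(1, t_total),
        "specificity_pct": 100.0 * tn / max(1, n_total),
        "n_target_reads": t_total,
        "n_nontarget_reads": n_total,
    }


def fusion_sensitivity_fulllength(
    n_fusions: int = 20,
    n_background: int = 40,
    coverage: int = 20,
    rng_seed: int = 1,
    config: Optional[PipelineConfig] = None,
    workdir: Optional[str] = None,
) -> dict:
    """Fusion-calling sensitivity with fully reconstructed oracle contigs.

    Every planted fusion contig is emitted full-length, reads are simulated
    onto the contigs for support, and the caller runs with the standard
    four-spanning-read rule.
    """
    design = TitrationDesign(
        n_fusion_events=n_fusions,
        n_background=n_background,
        breakpoint_coverages=(coverage,),
        background_coverages=(coverage,),
        rng_seed=rng_seed,
        full_length_contigs=True,
    )
    cfg = config or PipelineConfig()
    uni = build_fusion_universe(n_fusions, n_background, rng_seed=rng_seed)
    own_tmp = workdir is None
    tmp = tempfile.mkdtemp(prefix="fus_sens_") if own_tmp else workdir
    try:
        cell_seed = (rng_seed * 10007 + coverage) % (2**31)
        res = _run_cell(uni, design, coverage, coverage, cell_seed, tmp, cfg)
    finally:
        if own_tmp:
            import shutil

            shutil.rmtree(tmp, ignore_errors=True)
    return res
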