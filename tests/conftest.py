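import os

import pytest

from contigsv import synthetic_data as sd
from contigsv.annotation import GeneIndex
from contigsv.pipeline import run_call
from contigsv.synthetic_data import PlantedContig, _exon_segments, contig_sequence
from contigsv.testkit import plant_all_classes

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50)
    settings.load_profile("suite")
except ImportError:
    pass


@pytest.fixture(scope="session")
def reference():
    return sd.generate_reference(n_genes=16, rng_seed=7)


@pytest.fixture(scope="session")
def gene_index(reference):
    return GeneIndex(reference.gms)


@pytest.fixture(scope="session")
def planted(reference):
    """One contig per event class plus variant-free control contigs."""
    contigs = plant_all_classes(reference, rng_seed=3)
    for g in reference.gene_ids()[:4]:
        b = reference.builds[g]
        segs = _exon_segments(b, 1, b.n_exons)
        contigs.append(
            PlantedContig(f"null_{g}", contig_sequence(reference.genome, segs), segs, [])
        )
    return contigs


@pytest.fixture(scope="session")
def universe(reference, planted, tmp_path_factory):
    """Reference + planted contigs written to disk, reads simulated at 20x,
    and the full pipeline run once."""
    tmp = tmp_path_factory.mktemp("universe")
    paths = reference.write(str(tmp / "ref"))
    contig_fa = str(tmp / "contigs.fa")
    c2g = str(tmp / "c2g.sam")
    r2c = str(tmp / "r2c.sam")
    sd.emit_contig_alignments(planted, reference, contig_fa, c2g)
    pairs = sd.simulate_read_pairs(
        {pc.contig_id: pc.seq for pc in planted},
        coverage=20,
        sub_error_rate=0.0,
        rng_seed=11,
    )
    sd.write_r2c_sam(pairs, {pc.contig_id: len(pc.seq) for pc in planted}, r2c)
    result = run_call(
        contig_fa, c2g, paths["gtf"], paths["genome"], r2c_path=r2c,
        out_prefix=str(tmp / "out" / "run"),
    )
    return {
        "dir": str(tmp),
        "paths": paths,
        "contig_fa": contig_fa,
        "c2g": c2g,
        "r2c": r2c,
        "pairs": pairs,
        "result": result,
        "events": result["events"],
        "truths": [t for pc in planted for t in pc.truths],
        "out_prefix": str(tmp / "out" / "run"),
    }


def match_sv(truth, events):
    """Events matching a planted SV truth record on type/contig/breakpoints."""
    out = []
    for ev in events:
        if hasattr(ev, "coords"):
            continue
        if truth.contig_id not in ev.contig_ids or ev.event_type != truth.event_type:
            continue
        got = {(ev.chrom1, ev.pos1), (ev.chrom2, ev.pos2)}
        want = {(truth.chrom1, truth.pos1), (truth.chrom2, truth.pos2)}
        if got == want:
            out.append(ev)
    return out


def match_splice(truth, events):
    out = []
    for ev in events:
        if not hasattr(ev, "coords"):
            continue
        if (
            truth.contig_id in ev.contig_ids
            and ev.event_type == truth.event_type
            and ev.coords == truth.coords
        ):
            out.append(ev)
    return out
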