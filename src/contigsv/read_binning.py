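"""Alignment-free read binning with a multi-index spaced-seed Bloom filter.

Reads are classified to target genes by sliding k-mer frames over each
read and looking up spaced-seed projections of every frame in a single
hashed ID array built from the target transcript sequences (both strands).
Spaced seeds (binary care/don't-care masks) let a frame match despite
substitutions at don't-care positions, and a frame counts as hitting a
gene when at least ``n_seeds - allowed_miss`` of its seed projections are
found for that gene.  The structure keeps the classical Bloom-filter
contract: zero false negatives for inserted frames, false positives
bounded by the configured rate.

The ID array stores, per hashed slot, either empty (0), a gene index, or
an ambiguity sentinel for projections shared between genes; shared frames
count toward the classification of either gene.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import iter_fastq, revcomp

_AMBIG = np.int32(-1)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

_SPLIT1 = np.uint64(0xBF58476D1CE4E5B9)
_SPLIT2 = np.uint64(0x94D049BB133111EB)


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _salt(i: int) -> np.uint64:
    return np.uint64((0x9E3779B97F4A7C15 * i) % (1 << 64))


def _mix(x: np.ndarray, salt: np.uint64) -> np.ndarray:
    # splitmix64-style finaliser; uint64 arithmetic wraps by design
    with np.errstate(over="ignore"):
        x = (x + salt).astype(np.uint64)
        x ^= x >> np.uint64(30)
        x *= _SPLIT1
        x ^= x >> np.uint64(27)
        x *= _SPLIT2
        x ^= x >> np.uint64(31)
    return x


@dataclass
class SpacedSeedSet:
    """A fixed set of binary care/don't-care patterns of length k.

    By default five seeds with ~70% care positions are generated from a
    fixed internal seed, so the patterns are stable across runs; frame
    matching tolerates ``allowed_miss`` seeds failing.
    """

    k: int = 25
    patterns: list[np.ndarray] = field(default_factory=list)  # care indices
    allowed_miss: int = 2

    @classmethod
    def generate(
        cls,
        k: int = 25,
        n_seeds: int = 5,
        care_fraction: float = 0.7,
        allowed_miss: int = 2,
        pattern_seed: int = 20170915,
    ) -> "SpacedSeedSet":
        rng = np.random.default_rng(pattern_seed)
        n_care = max(2, int(round(k * care_fraction)))
        pats = []
        for _ in range(n_seeds):
            interior = rng.choice(np.arange(1, k - 1), size=n_care - 2, replace=False)
            pats.append(np.sort(np.concatenate(([0], interior, [k - 1]))))
        return cls(k=k, patterns=pats, allowed_miss=allowed_miss)

    @property
    def n_seeds(self) -> int:
        return len(self.patterns)

    @property
    def min_hits(self) -> int:
        return self.n_seeds - self.allowed_miss

    def masks(self) -> list[str]:
        out = []
        for p in self.patterns:
            m = ["0"] * self.k
            for i in p:
                m[i] = "1"
            out.append("".join(m))
        return out


class MultiIndexFilter:
    """Hashed ID array mapping spaced-seed k-mer projections to gene indices."""

    def __init__(
        self,
        size: int,
        n_hashes: int,
        seeds: SpacedSeedSet,
        target_ids: Sequence[str],
        configured_fpr: float,
    ):
        self.ids = np.zeros(size, dtype=np.int32)
        self.n_hashes = n_hashes
        self.seeds = seeds
        self.k = seeds.k
        self.target_ids = list(target_ids)
        self.configured_fpr = configured_fpr
        self._weights = [
            (np.uint64(4) ** np.arange(len(p), dtype=np.uint64)) for p in seeds.patterns
        ]

    # -- hashing ------------------------------------------------------------

    def _keys(self, frames: np.ndarray, seed_idx: int) -> np.ndarray:
        """Pack the care positions of each frame into a uint64 key.

        ``frames``: (n, k) uint8 base codes; frames containing non-ACGT
        bases get the sentinel key 2**63 (never inserted, rarely queried).
        """
        pat = self.seeds.patterns[seed_idx]
        proj = frames[:, pat].astype(np.uint64)
        bad = (proj > 3).any(axis=1)
        with np.errstate(over="ignore"):
            keys = proj @ self._weights[seed_idx]
        # offset by seed index so identical projections of different seeds
        # occupy distinct key spaces
        keys = _mix(keys, _salt(seed_idx + 1))
        keys[bad] = np.uint64(1) << np.uint64(63)
        return keys

    def _positions(self, keys: np.ndarray, hash_idx: int) -> np.ndarray:
        return (
            _mix(keys, _salt(101 + hash_idx)) % np.uint64(len(self.ids))
        ).astype(np.int64)

    # -- construction ---------------------------------------------------------

    def insert(self, frames: np.ndarray, gene_idx: int) -> None:
        gid = np.int32(gene_idx + 1)
        for s in range(self.seeds.n_seeds):
            keys = self._keys(frames, s)
            keys = keys[keys != np.uint64(1) << np.uint64(63)]
            for h in range(self.n_hashes):
                pos = self._positions(keys, h)
                cur = self.ids[pos]
                self.ids[pos] = np.where(
                    cur == 0, gid, np.where(cur == gid, gid, _AMBIG)
                )

    # -- query ----------------------------------------------------------------

    def lookup_frames(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame gene assignment.

        Returns an int32 array over frames: 0 = no hit, -1 = ambiguous,
        g+1 = gene index g.  A frame hits when at least ``min_hits`` seed
        projections are present with a consistent gene.
        """
        n = frames.shape[0]
        res = np.zeros((self.seeds.n_seeds, n), dtype=np.int32)
        big = np.int32(2**31 - 1)
        for s in range(self.seeds.n_seeds):
            keys = self._keys(frames, s)
            vals = np.empty((self.n_hashes, n), dtype=np.int32)
            for h in range(self.n_hashes):
                vals[h] = self.ids[self._positions(keys, h)]
            present = (vals != 0).all(axis=0)
            pos_vals = np.where(vals > 0, vals, big)
            mn = pos_vals.min(axis=0)
            mx = np.where(vals > 0, vals, 0).max(axis=0)
            out = np.zeros(n, dtype=np.int32)
            concrete = present & (mx > 0) & (mn == mx)
            out[concrete] = mx[concrete]
            out[present & ~concrete] = _AMBIG
            res[s] = out

        n_ambig = (res == _AMBIG).sum(axis=0)
        gene = res.max(axis=0)  # highest concrete gene id per frame (or <=0)
        hits = (res == gene[None, :]).sum(axis=0) + n_ambig
        frame_gene = np.zeros(n, dtype=np.int32)
        ok = (gene > 0) & (hits >= self.seeds.min_hits)
        frame_gene[ok] = gene[ok]
        amb_only = (gene <= 0) & (n_ambig >= self.seeds.min_hits)
        frame_gene[amb_only] = _AMBIG
        return frame_gene


def build_filter(
    target_transcripts_by_gene: dict[str, list[str]],
    k: int = 25,
    seeds: Optional[SpacedSeedSet] = None,
    fpr: float = 1e-3,
) -> MultiIndexFilter:
    """Build the multi-index filter from target transcript sequences.

    Every k-mer frame of every transcript, on both strands, is inserted
    under its gene's index; projections shared between genes become
    ambiguous.  The array is sized from the total inserted key count and
    the configured false-positive rate.
    """
    if seeds is None:
        seeds = SpacedSeedSet.generate(k=k)
    if seeds.k != k:
        raise ValueError("seed pattern length must equal k")
    genes = sorted(target_transcripts_by_gene)
    total_frames = 0
    for g in genes:
        for seq in target_transcripts_by_gene[g]:
            total_frames += max(0, len(seq) - k + 1)
    if total_frames == 0:
        raise ValueError(f"no transcript reaches k={k} bases")
    n_keys = total_frames * 2 * seeds.n_seeds
    m = max(64, int(math.ceil(-n_keys * math.log(fpr) / (math.log(2) ** 2))))
    n_hashes = max(1, round(m / n_keys * math.log(2)))
    filt = MultiIndexFilter(m, n_hashes, seeds, genes, fpr)
    for gi, g in enumerate(genes):
        frames_list = []
        for seq in target_transcripts_by_gene[g]:
            if len(seq) < k:
                continue
            for s in (seq, revcomp(seq)):
                enc = _encode(s)
                frames_list.append(np.lib.stride_tricks.sliding_window_view(enc, k))
        filt.insert(np.concatenate(frames_list), gi)
    return filt


def classify_frames(read_seq: str, filt: MultiIndexFilter) -> np.ndarray:
    if len(read_seq) < filt.k:
        return np.zeros(0, dtype=np.int32)
    enc = _encode(read_seq)
    frames = np.lib.stride_tricks.sliding_window_view(enc, filt.k)
    return filt.lookup_frames(frames)


def classify_read(
    read_seq: str, filt: MultiIndexFilter, min_frames: int = 1
) -> dict[str, int]:
    """Gene hits with frame-hit counts for one read.

    The read's frames are looked up; the result maps gene ids to the
    number of hitting frames (ambiguous frames count toward every reported
    gene).  Empty when nothing reaches ``min_frames``.
    """
    fg = classify_frames(read_seq, filt)
    if fg.size == 0:
        return {}
    amb = int((fg == _AMBIG).sum())
    counts = np.bincount(fg[fg > 0], minlength=len(filt.target_ids) + 1)
    out = {
        filt.target_ids[g - 1]: int(c) + amb
        for g, c in enumerate(counts)
        if g > 0 and c > 0
    }
    return {g: c for g, c in out.items() if c >= min_frames}


def best_gene(hits: dict[str, int]) -> Optional[str]:
    """Gene with the most hitting frames; lexicographic tie-break."""
    if not hits:
        return None
    return min(hits, key=lambda g: (-hits[g], g))


def classify_batch(
    reads: Sequence[str],
    filt: MultiIndexFilter,
    min_frames: int = 1,
    chunk: int = 8192,
) -> list[Optional[str]]:
    """Vectorised classification of many same-length reads.

    Returns the winning gene id per read (None for unclassified).  Reads
    of differing lengths are grouped by length; groups are processed in
    chunks to bound the size of intermediate arrays.
    """
    out: list[Optional[str]] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        if len(r) >= filt.k:
            by_len.setdefault(len(r), []).append(i)
    for L, all_idxs in by_len.items():
        for c0 in range(0, len(all_idxs), chunk):
            _classify_group(reads, filt, min_frames, all_idxs[c0 : c0 + chunk], L, out)
    return out


def _classify_group(reads, filt, min_frames, idxs, L, out):
    """Classify one chunk of equal-length reads, writing winners to out."""
    n_frames = L - filt.k + 1
    enc = np.empty((len(idxs), L), dtype=np.uint8)
    for row, i in enumerate(idxs):
        enc[row] = _encode(reads[i])
    frames = np.lib.stride_tricks.sliding_window_view(enc, filt.k, axis=1)
    flat = frames.reshape(-1, filt.k)
    fg = filt.lookup_frames(flat).reshape(len(idxs), n_frames)
    amb = (fg == _AMBIG).sum(axis=1)
    for row, i in enumerate(idxs):
        row_fg = fg[row]
        counts = np.bincount(row_fg[row_fg > 0], minlength=len(filt.target_ids) + 1)
        if counts[1:].any():
            order = np.argsort(-counts[1:], kind="stable")
            g = int(order[0]) + 1
            if counts[g] + amb[row] >= min_frames:
                out[i] = filt.target_ids[g - 1]


def bin_read_pairs(
    fastq1: str,
    fastq2: str,
    filt: MultiIndexFilter,
    out_dir: str,
    min_frames: int = 1,
    batch_size: int = 20000,
) -> dict[str, int]:
    """Segregate read pairs into per-gene FASTQ bins.

    A pair lands in gene G's bin when either mate classifies to G (a pair
    may enter two bins when the mates hit different genes); unclassified
    pairs are dropped.  Returns per-gene pair counts.
    """
    os.makedirs(out_dir, exist_ok=True)
    counts: dict[str, int] = {}
    handles: dict[str, tuple] = {}

    def flush_batch(batch: list[tuple[str, str, str, str]]):
        g1 = classify_batch([b[1] for b in batch], filt, min_frames)
        g2 = classify_batch([b[3] for b in batch], filt, min_frames)
        for (n1, s1, n2, s2), a, b in zip(batch, g1, g2):
            for g in sorted({x for x in (a, b) if x is not None}):
                if g not in handles:
                    handles[g] = (
                        open(os.path.join(out_dir, f"{g}_1.fastq"), "w"),
                        open(os.path.join(out_dir, f"{g}_2.fastq"), "w"),
                    )
                h1, h2 = handles[g]
                h1.write(f"@{n1}\n{s1}\n+\n{'I' * len(s1)}\n")
                h2.write(f"@{n2}\n{s2}\n+\n{'I' * len(s2)}\n")
                counts[g] = counts.get(g, 0) + 1

    it1, it2 = iter_fastq(fastq1), iter_fastq(fastq2)
    batch: list[tuple[str, str, str, str]] = []
    recno = 0
    _END = object()
    while True:
        r1 = next(it1, _END)
        r2 = next(it2, _END)
        if r1 is _END and r2 is _END:
            break
        recno += 1
        if r1 is _END or r2 is _END:
            raise ValueError(f"mate files out of sync at record {recno}")
        batch.append((r1[0], r1[1], r2[0], r2[1]))
        if len(batch) >= batch_size:
            flush_batch(batch)
            batch = []
    if batch:
        flush_batch(batch)
    for h1, h2 in handles.values():
        h1.close()
        h2.close()
    return counts
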