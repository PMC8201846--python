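"""Desk-scale exact/near-exact read mapper: k-mer anchoring + Hamming verify.

Substitution-only semantics: an alignment of a read of length L at reference
position p (on either strand) is the comparison of the read against the
L reference bases starting at p; its cost is the Hamming distance.  A read
with at most ``max_mismatches`` substitutions relative to its source is
guaranteed to be found because the read is split into ``max_mismatches + 1``
disjoint k-mer anchor blocks, at least one of which must be error-free
(pigeonhole), and every anchor hit is verified.

Verification is exact but mostly avoids byte-level comparison: the read is
tiled with k-mer blocks covering every base, and a candidate placement is
compared block-code against precomputed per-position reference codes.  Zero
mismatching blocks proves a perfect match; the number of mismatching blocks
is a lower bound on the Hamming distance, so candidates exceeding the
mismatch budget are rejected outright and only the narrow boundary cases
fall back to a full base-by-base comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import dna
from .reads import ReadSet


class ReferenceIndex:
    """Sorted k-mer position index over a set of sequences (forward strand)."""

    def __init__(self, sequences: Mapping[str, str], k: int = 10, pad: int = 100):
        if not sequences:
            raise ValueError("empty reference")
        self.k = int(k)
        self.pad = int(pad)
        self.names = list(sequences)
        self.lengths = np.array([len(sequences[n]) for n in self.names], dtype=np.int64)
        if (self.lengths < self.k).any():
            raise ValueError("all reference sequences must be at least k long")
        parts, offsets = [], []
        pos = 0
        sep = np.full(pad, dna.N_CODE, dtype=np.uint8)
        for name in self.names:
            offsets.append(pos)
            enc = dna.encode(sequences[name])
            parts.append(enc)
            parts.append(sep)
            pos += enc.size + pad
        self.enc = np.concatenate(parts)
        self.offsets = np.array(offsets, dtype=np.int64)

        codes, valid = _kmer_codes(self.enc, self.k)
        self.codes_by_pos = codes
        self.valid_by_pos = valid
        positions = np.flatnonzero(valid)
        sub = codes[positions]
        order = np.argsort(sub, kind="stable")
        self.sorted_codes = sub[order]
        self.sorted_pos = positions[order].astype(np.int64)

    @property
    def total_len(self) -> int:
        return int(self.enc.size)

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global concat positions to (sequence index, local position)."""
        gpos = np.asarray(gpos, dtype=np.int64)
        seq_idx = np.searchsorted(self.offsets, gpos, side="right") - 1
        return seq_idx, gpos - self.offsets[seq_idx]

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (range_start, hit_count) into sorted_pos for each code."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi - lo


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Horner-encode every k-window; valid = window free of non-ACGT codes."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = (enc >= 4).astype(np.int32)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    codes = np.zeros(n, dtype=np.uint64)
    masked = np.where(enc < 4, enc, 0).astype(np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + masked[i: i + n]
    return codes, valid


def _ranges_to_indices(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Flatten variable-length ranges [s, s+c) into one index array."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    out = np.ones(total, dtype=np.int64)
    out[0] = starts[0]
    out[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1]) + 1
    return np.cumsum(out)


@dataclass
class AlignmentCounts:
    """Per-read two-strand alignment counts and unique placements.

    ``counts`` is the exact number of alignments, capped at ``count_cap``;
    when it equals one, (gpos, strand) holds the single placement.
    """
    counts: np.ndarray          # int64, capped
    gpos: np.ndarray            # global concat position, valid if counts == 1
    strand: np.ndarray          # +1 / -1, valid if counts == 1


def count_alignments(reads: ReadSet, index: ReferenceIndex, max_mismatches: int,
                     count_cap: int = 11) -> AlignmentCounts:
    """Exact ≤max_mismatches alignment counts of every read on both strands."""
    n = reads.n
    counts = np.zeros(n, dtype=np.int64)
    gpos = np.full(n, -1, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)

    for L in np.unique(reads.lengths):
        L = int(L)
        if (max_mismatches + 1) * index.k > L:
            raise ValueError(
                f"read length {L} too short for {max_mismatches + 1} anchors of k={index.k}"
            )
        sel = np.flatnonzero(reads.lengths == L)
        block = reads.seqs[sel, :L]
        for sgn in (1, -1):
            mat = block if sgn == 1 else dna.complement_codes(block)[:, ::-1]
            c, p = _count_one_strand(mat, index, max_mismatches, count_cap)
            new_unique = (counts[sel] == 0) & (c == 1)
            counts[sel] = np.minimum(counts[sel] + c, count_cap)
            gpos[sel[new_unique]] = p[new_unique]
            strand[sel[new_unique]] = sgn
    # a placement recorded while scanning is only reported when the read's
    # final two-strand total is exactly one
    not_unique = counts != 1
    gpos[not_unique] = -1
    strand[not_unique] = 0
    return AlignmentCounts(counts, gpos, strand)


def _count_one_strand(mat: np.ndarray, index: ReferenceIndex, max_mm: int,
                      cap: int) -> tuple[np.ndarray, np.ndarray]:
    n, L = mat.shape
    k = index.k
    n_anchors = max_mm + 1

    # k-blocks tiling the read (last block re-anchored to cover the tail);
    # the first n_anchors blocks double as the candidate-generating anchors
    block_offsets = list(range(0, L - k + 1, k))
    if block_offsets[-1] != L - k:
        block_offsets.append(L - k)
    nb = len(block_offsets)

    rcodes = np.zeros((nb, n), dtype=np.uint64)
    rvalid = np.zeros((nb, n), dtype=bool)
    for j, off in enumerate(block_offsets):
        sub = mat[:, off: off + k]
        rvalid[j] = (sub < 4).all(axis=1)
        masked = np.where(sub < 4, sub, 0).astype(np.uint64)
        c = np.zeros(n, dtype=np.uint64)
        for i in range(k):
            c = c * np.uint64(4) + masked[:, i]
        rcodes[j] = c

    # candidate placements from the anchor blocks
    cand_read, cand_pos = [], []
    for j in range(n_anchors):
        lo, cnt = index.lookup(rcodes[j])
        cnt = np.where(rvalid[j], cnt, 0)
        has = np.flatnonzero(cnt > 0)
        if has.size == 0:
            continue
        idx = _ranges_to_indices(lo[has], cnt[has])
        cand_pos.append(index.sorted_pos[idx] - block_offsets[j])
        cand_read.append(np.repeat(has, cnt[has]))
    counts = np.zeros(n, dtype=np.int64)
    best = np.full(n, -1, dtype=np.int64)
    if not cand_read:
        return counts, best

    read_ids = np.concatenate(cand_read)
    positions = np.concatenate(cand_pos)
    ok = (positions >= 0) & (positions + L <= index.total_len)
    read_ids, positions = read_ids[ok], positions[ok]

    if n_anchors > 1:
        # dedupe (read, pos) pairs via a combined sort key; the resulting
        # order is (read asc, pos asc) which makes "first placement"
        # deterministic.  With a single anchor the candidates already come
        # out in that order with no duplicates.
        key = read_ids * np.int64(index.total_len + 1) + positions
        order = np.argsort(key, kind="stable")
        read_ids, positions, key = read_ids[order], positions[order], key[order]
        keep = np.ones(read_ids.size, dtype=bool)
        keep[1:] = key[1:] != key[:-1]
        read_ids, positions = read_ids[keep], positions[keep]

    # block-code screen: running lower bound on mismatches per candidate,
    # dropping candidates as soon as the bound exceeds the budget
    alive = np.arange(read_ids.size)
    lb = np.zeros(read_ids.size, dtype=np.int16)
    for j, off in enumerate(block_offsets):
        pos_a = positions[alive]
        refc = index.codes_by_pos[pos_a + off]
        refv = index.valid_by_pos[pos_a + off]
        r_a = read_ids[alive]
        lb_a = lb[alive] + ((~refv) | (~rvalid[j, r_a]) | (refc != rcodes[j, r_a]))
        lb[alive] = lb_a
        alive = alive[lb_a <= max_mm]
        if alive.size == 0:
            break
    accepted = np.zeros(read_ids.size, dtype=bool)
    accepted[alive[lb[alive] == 0]] = True   # blocks cover the read: exact match
    boundary = alive[lb[alive] >= 1]
    if boundary.size:
        for s in range(0, boundary.size, 2_000_000):
            part = boundary[s: s + 2_000_000]
            windows = index.enc[positions[part, None] + np.arange(L)]
            mm = (windows != mat[read_ids[part]]).sum(axis=1)
            accepted[part[mm <= max_mm]] = True

    hit_reads = read_ids[accepted]
    counts = np.bincount(hit_reads, minlength=n).astype(np.int64)
    first_reads, first_idx = np.unique(hit_reads, return_index=True)
    best[first_reads] = positions[accepted][first_idx]
    return np.minimum(counts, cap), best


def brute_force_alignments(read: str, sequences: Mapping[str, str],
                           max_mismatches: int) -> list[tuple[str, int, str]]:
    """All-positions Hamming scan oracle: every (seq, pos, strand) placement."""
    out = []
    for strand, q in (("+", read), ("-", dna.revcomp(read))):
        eq = dna.encode(q)
        for name, seq in sequences.items():
            es = dna.encode(seq)
            L = eq.size
            if es.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(es, L)
            mm = (windows != eq).sum(axis=1)
            for p in np.flatnonzero(mm <= max_mismatches):
                out.append((name, int(p), strand))
    return sorted(out)
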