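"""Low-pass single-end read simulation per deletion line.

Reads are drawn uniformly from the line's effective genome: every A
segment repeated at its dosage plus the retained B intervals at the line's
B copy number.  Errors are i.i.d. substitutions; a configurable fraction
of reads carries an artificial 3' poly-G or poly-N tail (overwriting the
3' end so read length stays constant) to exercise the trimmer.  Defaults
follow the sequencing design the pipeline targets: 75-bp single-end reads
at ~6x coverage.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .. import dna
from ..reads import ReadSet
from .genome import GenomeModel
from .panel import LineSpec


def line_genome_pieces(genome: GenomeModel, line: LineSpec
                       ) -> list[tuple[str, int, str]]:
    """(source chrom, source start, sequence) pieces of the line's genome.

    A-segment pieces appear once per dosage copy; B pieces once per
    retained interval per B copy.
    """
    pieces = []
    segs = genome.a_segments()
    a_seqs = genome.a_sequences()
    for _, row in segs.iterrows():
        copies = line.dosage(row["name"])
        seq = a_seqs[row["chrom"]][row["start"]: row["end"]]
        for _ in range(copies):
            pieces.append((row["chrom"], int(row["start"]), seq))
    for _ in range(line.b_copies):
        for s, e in line.retained:
            pieces.append(("chrB", int(s), genome.b_chromosome[s:e]))
    return pieces


def simulate_reads(genome: GenomeModel, line: LineSpec, coverage: float = 6.0,
                   read_len: int = 75, error_rate: float = 0.0, seed: int = 0,
                   tail_fraction: float = 0.05, tail_min: int = 3,
                   tail_max: int = 10) -> ReadSet:
    """Simulate a line's whole-genome single-end read set (deterministic per seed)."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    if not (0 <= error_rate < 0.1):
        raise ValueError("error_rate must be in [0, 0.1)")

    pieces = [p for p in line_genome_pieces(genome, line) if len(p[2]) >= read_len]
    total = sum(len(p[2]) for p in pieces)
    if total == 0:
        raise ValueError("line genome is empty")
    rng = np.random.default_rng(seed)
    n_reads = int(round(total * coverage / read_len))

    piece_len = np.array([len(p[2]) for p in pieces], dtype=np.float64)
    piece_idx = rng.choice(len(pieces), size=n_reads, p=piece_len / piece_len.sum())
    starts = np.floor(rng.random(n_reads) * (piece_len[piece_idx] - read_len + 1)
                      ).astype(np.int64)
    minus = rng.random(n_reads) < 0.5

    enc_pieces = [dna.encode(p[2]) for p in pieces]
    # gather read windows piece by piece (few pieces, vectorised within each)
    mat = np.empty((n_reads, read_len), dtype=np.uint8)
    for pi in range(len(pieces)):
        sel = np.flatnonzero(piece_idx == pi)
        if sel.size == 0:
            continue
        mat[sel] = enc_pieces[pi][starts[sel, None] + np.arange(read_len)]
    rc_rows = np.flatnonzero(minus)
    mat[rc_rows] = dna.complement_codes(mat[rc_rows])[:, ::-1]

    if error_rate > 0:
        hits = rng.random(mat.shape) < error_rate
        shifts = rng.integers(1, 4, int(hits.sum()), dtype=np.uint8)
        mat[hits] = (mat[hits] + shifts) % 4

    if tail_fraction > 0:
        n_tail = int(round(tail_fraction * n_reads))
        tail_rows = rng.choice(n_reads, size=n_tail, replace=False)
        tail_lens = rng.integers(tail_min, tail_max + 1, n_tail)
        tail_is_n = rng.random(n_tail) < 0.5
        col = np.arange(read_len)
        for r, tl, is_n in zip(tail_rows, tail_lens, tail_is_n):
            mat[r, read_len - tl:] = dna.N_CODE if is_n else 2  # G = code 2

    truth = pd.DataFrame({
        "chrom": [pieces[i][0] for i in piece_idx],
        "start": np.array([pieces[i][1] for i in piece_idx]) + starts,
        "strand": np.where(minus, "-", "+"),
    })
    lengths = np.full(n_reads, read_len, dtype=np.int32)
    ids = [f"{line.name}:{i}" for i in range(n_reads)]
    return ReadSet(mat, lengths, ids=ids, truth=truth)
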