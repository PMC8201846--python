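"""Read container used throughout the pipeline.

Reads are stored as a dense uint8 code matrix plus a length vector rather
than per-record objects: the simulator, trimmer and mapper are all
vectorised over this layout.  Hidden simulation truth (source sequence,
start, strand per read) rides along as a pandas DataFrame and is only ever
used by tests and truth-comparison workflows, never by the inference code.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dna

DEFAULT_QUALITY = "I"  # constant PHRED-33 placeholder


@dataclass
class ReadSet:
    seqs: np.ndarray              # (n, max_len) uint8 codes, PAD_CODE beyond length
    lengths: np.ndarray           # (n,) int32
    ids: list[str] | None = None
    truth: pd.DataFrame | None = None   # columns: chrom, start, strand

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.int32)
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D code matrix")
        if self.seqs.shape[0] != self.lengths.size:
            raise ValueError("lengths do not match seqs")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    def __len__(self) -> int:
        return self.n

    def read_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"read{i}"

    def sequence(self, i: int) -> str:
        return dna.decode(self.seqs[i, : self.lengths[i]])

    def to_strings(self) -> list[str]:
        return [self.sequence(i) for i in range(self.n)]

    @classmethod
    def from_strings(cls, seqs: list[str], ids: list[str] | None = None,
                     truth: pd.DataFrame | None = None) -> "ReadSet":
        n = len(seqs)
        max_len = max((len(s) for s in seqs), default=0)
        mat = np.full((n, max_len), dna.PAD_CODE, dtype=np.uint8)
        lengths = np.zeros(n, dtype=np.int32)
        for i, s in enumerate(seqs):
            enc = dna.encode(s)
            mat[i, : enc.size] = enc
            lengths[i] = enc.size
        return cls(mat, lengths, ids=ids, truth=truth)

    def subset(self, mask_or_index) -> "ReadSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ids = [self.read_id(i) for i in idx] if self.ids is not None else None
        truth = self.truth.iloc[idx].reset_index(drop=True) if self.truth is not None else None
        return ReadSet(self.seqs[idx], self.lengths[idx], ids=ids, truth=truth)


@dataclass
class PairedReads:
    """Mate pairs oriented toward each other (R2 is the reverse strand mate)."""
    r1: ReadSet
    r2: ReadSet
    truth: pd.DataFrame | None = None   # e.g. fragment midpoints for ChIP simulations

    @property
    def n(self) -> int:
        return self.r1.n


def write_fastq(path, reads: ReadSet, quality_char: str = DEFAULT_QUALITY) -> None:
    with open(path, "w") as fh:
        for i in range(reads.n):
            seq = reads.sequence(i)
            fh.write(f"@{reads.read_id(i)}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> ReadSet:
    seqs: list[str] = []
    ids: list[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            ids.append(header.strip()[1:])
            seqs.append(seq)
    return ReadSet.from_strings(seqs, ids=ids)
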