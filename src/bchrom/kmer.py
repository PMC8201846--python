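"""K-mer profiling and chromosome assignment of assembly scaffolds.

A scaffold is profiled position-by-position against two k-mer indexes:
the A-genome (host complement) index, whose occurrence counts also define
a repetitive mask, and an index of reads enriched for the supernumerary
chromosome.  Scaffolds whose non-repetitive positions are well covered by
the enriched-read index but absent from the host index are assigned to the
supernumerary chromosome.  K-mers are canonicalised (lexicographic minimum
of a k-mer and its reverse complement) because sequencing reads are
unstranded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import dna
from .mapping import _kmer_codes
from .reads import ReadSet

DEFAULT_K = 49
DEFAULT_REPEAT_THRESHOLD = 4
DEFAULT_MIN_LEN = 10_000


def canonical(kmer: str) -> str:
    rc = dna.revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    k: int
    counts: dict
    source: str = ""

    def get(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def __len__(self) -> int:
        return len(self.counts)


def _iter_sequences(sequences) -> Iterable[str]:
    if isinstance(sequences, Mapping):
        yield from sequences.values()
    elif isinstance(sequences, ReadSet):
        yield from sequences.to_strings()
    else:
        yield from sequences


def build_index(sequences, k: int = DEFAULT_K, min_count: int = 1,
                source: str = "") -> KmerIndex:
    """Count every canonical k-mer window; windows with non-ACGT bases drop."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[str, int] = {}
    n_seqs = 0
    for seq in _iter_sequences(sequences):
        n_seqs += 1
        if len(seq) < k:
            raise ValueError("all sequences must be at least k long")
        rc = dna.revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i: i + k]
            rck = rc[n - k - i: n - i]
            can = kmer if kmer <= rck else rck
            if "N" in can:
                continue
            counts[can] = counts.get(can, 0) + 1
    if n_seqs == 0:
        raise ValueError("empty input")
    if min_count > 1:
        counts = {kk: v for kk, v in counts.items() if v >= min_count}
    return KmerIndex(k=k, counts=counts, source=source)


@dataclass
class KmerProfile:
    scaffold_id: str
    k: int
    a_count: np.ndarray          # per start position: occurrences in the A index
    b_covered: np.ndarray        # per start position: present in the enriched-read index
    repeat_threshold: int = DEFAULT_REPEAT_THRESHOLD
    valid: np.ndarray = field(default=None)  # window free of non-ACGT bases

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(self.a_count.size, dtype=bool)

    @property
    def length(self) -> int:
        return self.a_count.size + self.k - 1

    @property
    def repetitive_mask(self) -> np.ndarray:
        return self.valid & (self.a_count >= self.repeat_threshold)

    @property
    def nonrepetitive(self) -> np.ndarray:
        return self.valid & (self.a_count < self.repeat_threshold)


def profile_scaffold(scaffold: str, a_index: KmerIndex, b_index: KmerIndex,
                     repeat_threshold: int = DEFAULT_REPEAT_THRESHOLD,
                     scaffold_id: str = "scaffold") -> KmerProfile:
    if a_index.k != b_index.k:
        raise ValueError("index k mismatch between a_index and b_index")
    k = a_index.k
    if len(scaffold) < k:
        raise ValueError("scaffold shorter than k")
    n = len(scaffold) - k + 1
    rc = dna.revcomp(scaffold)
    m = len(scaffold)
    a_count = np.zeros(n, dtype=np.int64)
    b_cov = np.zeros(n, dtype=bool)
    valid = np.ones(n, dtype=bool)
    a_get = a_index.counts.get
    b_has = b_index.counts.__contains__
    for i in range(n):
        kmer = scaffold[i: i + k]
        rck = rc[m - k - i: m - i]
        can = kmer if kmer <= rck else rck
        if "N" in can:
            valid[i] = False
            continue
        a_count[i] = a_get(can, 0)
        b_cov[i] = b_has(can)
    return KmerProfile(scaffold_id, k, a_count, b_cov,
                       repeat_threshold=repeat_threshold, valid=valid)


def classify_scaffolds(profiles: Iterable[KmerProfile],
                       min_len: int = DEFAULT_MIN_LEN,
                       min_b_covered_frac: float = 0.8,
                       a_align_frac: float = 0.5) -> pd.DataFrame:
    """Label each scaffold A / B / ambiguous (plus short and repeat-only routes).

    A scaffold is called A when at least ``a_align_frac`` of its
    non-repetitive positions hit the host index at all, replacing the
    whole-scaffold host-alignment screen with the same containment decision;
    otherwise B when the enriched-read index covers at least
    ``min_b_covered_frac`` of the non-repetitive positions.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("profiles must be nonempty")
    rows = []
    for p in profiles:
        nonrep = p.nonrepetitive
        n_nonrep = int(nonrep.sum())
        length = p.length
        if length < min_len:
            rows.append((p.scaffold_id, length, np.nan, np.nan, "short", n_nonrep))
            continue
        if n_nonrep == 0:
            rows.append((p.scaffold_id, length, np.nan, np.nan, "repeat-only", 0))
            continue
        a_frac = float((p.a_count[nonrep] >= 1).mean())
        b_frac = float(p.b_covered[nonrep].mean())
        if a_frac >= a_align_frac:
            label = "A"
        elif b_frac >= min_b_covered_frac:
            label = "B"
        else:
            label = "ambiguous"
        rows.append((p.scaffold_id, length, a_frac, b_frac, label, n_nonrep))
    return pd.DataFrame(
        rows, columns=["scaffold", "length", "a_hit_frac", "b_covered_frac",
                       "label", "nonrepetitive_positions"],
    )


def repeat_mask(sequences: Mapping[str, str], extra: Mapping[str, str] | None = None,
                k: int = 31, threshold: int = DEFAULT_REPEAT_THRESHOLD
                ) -> dict[str, np.ndarray]:
    """Fast per-position repetitive mask over a corpus (canonical k-mers, k<=31).

    A k-mer start position is masked when its canonical k-mer occurs at
    least ``threshold`` times in ``sequences`` plus ``extra`` combined.
    Used to flag windows that unique-read coverage cannot inform.
    """
    if k > 31:
        raise ValueError("fast mask supports k <= 31")
    corpus = dict(sequences)
    if extra:
        for name, seq in extra.items():
            corpus[f"__extra__{name}"] = seq

    all_codes = []
    per_seq = {}
    for name, seq in corpus.items():
        enc = dna.encode(seq)
        fwd, valid_f = _kmer_codes(enc, k)
        rev, valid_r = _kmer_codes(dna.revcomp_codes(enc), k)
        rc_aligned = rev[::-1]
        canon = np.minimum(fwd, rc_aligned)
        valid = valid_f & valid_r[::-1]
        per_seq[name] = (canon, valid)
        all_codes.append(canon[valid])
    pool = np.concatenate(all_codes) if all_codes else np.empty(0, np.uint64)
    uniq, cnt = np.unique(pool, return_counts=True)
    repetitive = uniq[cnt >= threshold]

    out = {}
    for name in sequences:
        canon, valid = per_seq[name]
        idx = np.searchsorted(repetitive, canon)
        idx = np.minimum(idx, max(repetitive.size - 1, 0))
        hit = repetitive.size > 0
        mask = valid & hit & (repetitive[idx] == canon) if hit else np.zeros_like(valid)
        out[name] = mask
    return out


def mask_to_intervals(mask: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Merge masked k-mer start positions into base intervals [i, i+k)."""
    starts = np.flatnonzero(mask)
    if starts.size == 0:
        return []
    intervals = []
    s = prev = int(starts[0])
    for p in starts[1:]:
        p = int(p)
        if p <= prev + k:
            prev = p
        else:
            intervals.append((s, prev + k))
            s = prev = p
    intervals.append((s, prev + k))
    return intervals
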