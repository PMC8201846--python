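"""Tandem-repeat monomer scanning and nucleosome-midpoint profiling.

Covers the centromeric-repeat analyses: detecting monomer units against a
consensus with percent identity, merging overlapping mate pairs, mapping
merged fragments onto a small multimer (trimer by default) of the
consensus and folding fragment midpoints modulo the monomer length, peak
calling on the ChIP/input ratio, and identity-to-consensus statistics
between read groups.  The midpoint offset is invariant to which tandem
copy a fragment is placed on, which makes placement ambiguity on the
multimer harmless.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import dna
from .reads import PairedReads, ReadSet

logger = logging.getLogger(__name__)

MIN_IDENTITY = 70.0
MERGE_MIN_OVERLAP = 10
SMOOTH_WINDOW = 5
MIN_PROMINENCE = 0.1


# --- monomer scanning ------------------------------------------------------

@dataclass
class RepeatHit:
    sequence_id: str
    start: int
    end: int
    strand: str
    identity: float


def _best_infix(consensus: str, target: str):
    """Best infix (HW) alignment of consensus into target via edlib."""
    import edlib

    res = edlib.align(consensus, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    matches = mismatches = gaps = 0
    from .dna import _parse_cigar

    for n_, op in _parse_cigar(res["cigar"]):
        if op == "=":
            matches += n_
        elif op == "X":
            mismatches += n_
        else:
            gaps += n_
    start, end = res["locations"][0]
    cols = matches + mismatches + gaps
    identity = 100.0 * matches / cols if cols else 0.0
    return start, end + 1, identity


def scan_monomers(sequence: str, consensus: str, min_identity: float = MIN_IDENTITY,
                  sequence_id: str = "seq") -> list[RepeatHit]:
    """Non-overlapping monomer hits >= min_identity on both strands.

    Iterative greedy search: repeatedly take the best remaining infix
    alignment of the consensus (on either strand) and mask it out, until
    identity falls below the threshold.
    """
    if len(consensus) < 20:
        raise ValueError("consensus must be >= 20 bp")
    work = {"+": sequence, "-": sequence}
    rc_cons = dna.revcomp(consensus)
    hits: list[RepeatHit] = []
    occupied = np.zeros(len(sequence), dtype=bool)
    while True:
        candidates = []
        for strand, cons in (("+", consensus), ("-", rc_cons)):
            res = _best_infix(cons, work[strand])
            if res is not None:
                candidates.append((res[2], -res[0], strand, res))
        if not candidates:
            break
        candidates.sort(reverse=True)          # best identity, then leftmost
        identity, _, strand, (start, end, _) = candidates[0]
        if identity < min_identity:
            break
        if not occupied[start:end].any():
            hits.append(RepeatHit(sequence_id, start, end, strand, identity))
            occupied[start:end] = True
        # mask the span on both strands so the search advances
        for st in work:
            work[st] = work[st][:start] + "N" * (end - start) + work[st][end:]
    hits.sort(key=lambda h: h.start)
    return hits


def hits_to_bed(hits: list[RepeatHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.sequence_id, h.start, h.end, "monomer", round(h.identity, 2), h.strand)
         for h in hits],
        columns=["chrom", "start", "end", "name", "score", "strand"])


# --- read-pair merging -----------------------------------------------------

def merge_read_pairs(pairs: PairedReads, min_overlap: int = MERGE_MIN_OVERLAP
                     ) -> ReadSet:
    """Merge inward-facing mates by their best 3' overlap.

    An overlap of o bases is acceptable when it has at most one mismatch
    per 10 bp (floor(o / 10)); among acceptable overlaps the one with the
    highest matches-minus-mismatches score wins (larger o on ties).  The
    merged fragment is R1's prefix plus the reverse complement of R2;
    unmergeable pairs are dropped and counted.
    """
    r1, r2 = pairs.r1, pairs.r2
    n = pairs.n
    merged: list[str] = []
    kept_idx = []
    L1 = r1.lengths
    L2 = r2.lengths
    for i in range(n):
        a = r1.seqs[i, : L1[i]]
        b_rc = dna.revcomp_codes(r2.seqs[i, : L2[i]])
        best = None
        max_o = min(L1[i], L2[i])
        for o in range(min_overlap, max_o + 1):
            mism = int((a[-o:] != b_rc[:o]).sum())
            if mism > o // 10:
                continue
            score = (o - mism) - mism
            if best is None or score >= best[0]:
                best = (score, o)
        if best is None:
            continue
        o = best[1]
        frag = np.concatenate([a, b_rc[o:]])
        merged.append(dna.decode(frag))
        kept_idx.append(i)
    dropped = n - len(kept_idx)
    if dropped:
        logger.info("merge: dropped %d / %d unmergeable pairs", dropped, n)
    truth = pairs.truth.iloc[kept_idx].reset_index(drop=True) if pairs.truth is not None else None
    out = ReadSet.from_strings(merged, ids=[r1.read_id(i) for i in kept_idx])
    out.truth = truth
    return out


# --- midpoint profiling ----------------------------------------------------

@dataclass
class MidpointProfile:
    monomer_len: int
    chip: np.ndarray              # counts per monomer offset
    input: np.ndarray
    n_chip: int
    n_input: int

    def chip_cpm(self) -> np.ndarray:
        return self.chip / max(self.n_chip, 1) * 1e6

    def input_cpm(self) -> np.ndarray:
        return self.input / max(self.n_input, 1) * 1e6

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": np.arange(self.monomer_len),
            "chip": self.chip, "input": self.input,
            "chip_cpm": self.chip_cpm(), "input_cpm": self.input_cpm(),
        })


def midpoint_counts(merged: ReadSet, consensus: str, copies: int = 3
                    ) -> np.ndarray:
    """Fold merged-fragment midpoints onto monomer offsets (mod monomer length).

    Each fragment is placed at its best location on the ``copies``-mer of
    the consensus (exact search first, edit-distance infix alignment as
    fallback); the midpoint offset mod monomer length is invariant to the
    tandem copy chosen.
    """
    if copies < 2:
        raise ValueError("need at least a dimer for unambiguous folding")
    L = len(consensus)
    multimer = consensus * copies
    counts = np.zeros(L, dtype=np.int64)
    skipped = 0
    for i in range(merged.n):
        seq = merged.sequence(i)
        if len(seq) > len(multimer):
            skipped += 1
            continue
        start = multimer.find(seq)
        if start >= 0:
            end = start + len(seq)
        else:
            res = _best_infix(seq, multimer)
            if res is None:
                skipped += 1
                continue
            start, end, _ = res
        counts[((start + end) // 2) % L] += 1
    if skipped:
        logger.info("midpoints: skipped %d unplaceable fragments", skipped)
    return counts


def midpoint_profile(chip_merged: ReadSet, input_merged: ReadSet,
                     consensus: str, copies: int = 3) -> MidpointProfile:
    chip = midpoint_counts(chip_merged, consensus, copies)
    inp = midpoint_counts(input_merged, consensus, copies)
    return MidpointProfile(len(consensus), chip, inp,
                           int(chip.sum()), int(inp.sum()))


def _circular_smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    ext = np.concatenate([x[-(window - 1):], x, x[: window - 1]]).astype(float)
    sm = np.convolve(ext, kernel, mode="same")
    return sm[window - 1: window - 1 + x.size]


def call_peaks(profile: MidpointProfile, smoothing: int = SMOOTH_WINDOW,
               min_prominence: float = MIN_PROMINENCE) -> pd.DataFrame:
    """Ranked peaks of the smoothed chip/input enrichment with a 2-means
    major/minor split of peak heights."""
    if profile.chip.sum() == 0:
        raise ValueError("empty chip profile")
    inp = profile.input_cpm()
    if profile.input.sum() == 0:
        logger.warning("all-zero input profile; applying pseudocount")
    ratio = profile.chip_cpm() / np.where(inp > 0, inp, 1.0)
    sm = _circular_smooth(ratio, smoothing)

    from scipy.signal import find_peaks

    L = sm.size
    tiled = np.concatenate([sm, sm, sm])
    peaks, props = find_peaks(tiled, prominence=min_prominence * sm.max())
    sel = (peaks >= L) & (peaks < 2 * L)
    offsets = peaks[sel] - L
    heights = tiled[peaks[sel]]
    order = np.argsort(-heights)
    offsets, heights = offsets[order], heights[order]

    klass = _two_means_split(heights)
    return pd.DataFrame({
        "offset": offsets, "height": heights,
        "rank": np.arange(1, offsets.size + 1),
        "class": klass,
    })


def _two_means_split(heights: np.ndarray) -> list[str]:
    """1-D 2-means on descending heights: boundary minimising within-class SSE."""
    n = heights.size
    if n == 0:
        return []
    if n == 1 or np.allclose(heights, heights[0]):
        return ["major"] * n
    best_cut, best_sse = 1, np.inf
    for cut in range(1, n):
        a, b = heights[:cut], heights[cut:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best_sse:
            best_cut, best_sse = cut, sse
    return ["major"] * best_cut + ["minor"] * (n - best_cut)


def flatness_test(counts: np.ndarray) -> float:
    """Chi-square goodness-of-fit p-value against a uniform profile."""
    total = counts.sum()
    expected = np.full(counts.size, total / counts.size)
    stat, p = sstats.chisquare(counts, expected)
    return float(p)


# --- identity statistics ---------------------------------------------------

def identity_stats(groups: dict[str, np.ndarray | list]) -> tuple[pd.DataFrame,
                                                                  pd.DataFrame]:
    """Per-group summaries and pairwise Welch two-sided t tests on identities."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    summary = pd.DataFrame([
        {"group": g, "n": v.size, "mean": v.mean(), "median": np.median(v),
         "q25": np.percentile(v, 25), "q75": np.percentile(v, 75)}
        for g, v in clean.items()])
    rows = []
    names = list(clean)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = clean[names[i]], clean[names[j]]
            if a.std() == 0 and b.std() == 0:
                if np.isclose(a.mean(), b.mean()):
                    t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
                else:
                    t, p, df = np.inf, 0.0, float(a.size + b.size - 2)
                flagged = True
            else:
                res = sstats.ttest_ind(a, b, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                df = float(res.df)
                flagged = False
            rows.append({"group_a": names[i], "group_b": names[j],
                         "t": t, "df": df, "p": p, "zero_variance": flagged})
    return summary, pd.DataFrame(rows)


def read_identity(read: str, reference_hit: str) -> float:
    """Percent identity of a read to its matched reference stretch."""
    return dna.global_identity(read, reference_hit)
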