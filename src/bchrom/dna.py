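"""Low-level DNA utilities: encoding, mutation models, pairwise identity.

Sequences are handled in two forms: plain Python strings over {A,C,G,T,N}
and numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4, pad=5).  The code
form is what the seed-and-verify mapper and the read simulator operate on.
"""
from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
N_CODE = 4
PAD_CODE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN.", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (unknown chars become N)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def point_mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``p``.

    A hit site is replaced by one of the three other bases, uniformly,
    which is the per-site transition kernel of the Jukes-Cantor model.
    """
    codes = encode(seq)
    hits = rng.random(codes.size) < p
    n_hit = int(hits.sum())
    if n_hit:
        codes[hits] = (codes[hits] + rng.integers(1, 4, n_hit, dtype=np.uint8)) % 4
    return decode(codes)


def jc_divergence_to_p(d: float) -> float:
    """Expected fraction of differing sites after ``d`` substitutions/site (JC69)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def jc_mutate(seq: str, d: float, rng: np.random.Generator) -> str:
    """Evolve ``seq`` along a JC69 branch of length ``d`` substitutions/site."""
    return point_mutate(seq, jc_divergence_to_p(d), rng)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((encode(a) != encode(b)).sum())


def _parse_cigar(cigar: str):
    for n, op in _CIGAR_RE.findall(cigar):
        yield int(n), op


def alignment_columns(query: str, target: str, mode: str = "NW"):
    """Global ("NW") or infix ("HW") alignment column counts via edlib.

    Returns (matches, mismatches, gaps, (target_start, target_end)).
    """
    import edlib

    res = edlib.align(query, target, mode=mode, task="path")
    matches = mismatches = gaps = 0
    for n, op in _parse_cigar(res["cigar"]):
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        else:
            gaps += n
    start, end = res["locations"][0]
    return matches, mismatches, gaps, (start, end + 1)


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment: matches / alignment columns."""
    m, x, g, _ = alignment_columns(a, b, mode="NW")
    cols = m + x + g
    return 100.0 * m / cols if cols else 0.0


def aligned_base_pairs(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Code arrays of the ungapped columns of the global alignment of a and b."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    ea, eb = encode(a), encode(b)
    ia = ib = 0
    cols_a, cols_b = [], []
    for n, op in _parse_cigar(res["cigar"]):
        if op in "=XM":
            cols_a.append(ea[ia:ia + n])
            cols_b.append(eb[ib:ib + n])
            ia += n
            ib += n
        elif op == "I":  # insertion in query a
            ia += n
        else:  # deletion: gap in a, bases in b
            ib += n
    if not cols_a:
        return np.empty(0, np.uint8), np.empty(0, np.uint8)
    return np.concatenate(cols_a), np.concatenate(cols_b)
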