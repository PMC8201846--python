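"""Paired-end fragments with planted nucleosome dyads on a tandem array.

ChIP fragments are centred on planted dyad offsets of the repeat monomer
(Gaussian jitter around the dyad), input fragments start uniformly over
the array with a uniform residue mod the monomer length, so input
midpoints are exactly uniform over monomer offsets.  Mates are read from
the two fragment ends toward each other, ready for overlap merging.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .. import dna
from ..reads import PairedReads, ReadSet


def _pairs_from_fragments(array_enc: np.ndarray, starts: np.ndarray,
                          fragment_len: int, read_len: int, prefix: str
                          ) -> PairedReads:
    n = starts.size
    frag = array_enc[starts[:, None] + np.arange(fragment_len)]
    r1 = frag[:, :read_len].copy()
    r2 = dna.complement_codes(frag[:, -read_len:])[:, ::-1].copy()
    lengths = np.full(n, read_len, dtype=np.int32)
    ids = [f"{prefix}:{i}" for i in range(n)]
    truth = pd.DataFrame({"start": starts,
                          "midpoint": starts + fragment_len // 2})
    return PairedReads(
        r1=ReadSet(r1, lengths.copy(), ids=[f"{i}/1" for i in ids]),
        r2=ReadSet(r2, lengths.copy(), ids=[f"{i}/2" for i in ids]),
        truth=truth,
    )


def simulate_midpoint_reads(monomer: str, array_copies: int,
                            dyad_positions: list[int], n_pairs: int,
                            fragment_len: int = 120, read_len: int = 75,
                            sigma: float = 5.0,
                            weights: list[float] | None = None,
                            seed: int = 0) -> tuple[PairedReads, PairedReads]:
    """Simulate (chip, input) mate pairs on a tandem array of ``monomer``.

    ``weights`` sets the relative occupancy of each dyad (e.g. 2:2:1:1:1
    for two major and three minor nucleosome positions).
    """
    L = len(monomer)
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if any(d >= L or d < 0 for d in dyad_positions):
        raise ValueError("dyad offsets must lie within the monomer")
    if fragment_len > L * (array_copies - 2):
        raise ValueError("array too short for the fragment length")
    if read_len > fragment_len:
        raise ValueError("read_len cannot exceed fragment_len")

    rng = np.random.default_rng(seed)
    array = monomer * array_copies
    array_enc = dna.encode(array)
    max_start = len(array) - fragment_len

    # chip: fragment midpoints on jittered dyads of random interior copies
    w = np.ones(len(dyad_positions)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    dyad_idx = rng.choice(len(dyad_positions), size=n_pairs, p=w)
    copies = rng.integers(1, array_copies - 1, n_pairs)
    jitter = np.round(rng.normal(0.0, sigma, n_pairs)).astype(np.int64)
    mids = copies * L + np.asarray(dyad_positions)[dyad_idx] + jitter
    chip_starts = np.clip(mids - fragment_len // 2, 0, max_start)
    chip = _pairs_from_fragments(array_enc, chip_starts, fragment_len, read_len, "chip")
    chip.truth["dyad"] = np.asarray(dyad_positions)[dyad_idx]

    # input: exactly uniform midpoint residues mod L
    n_res_copies = array_copies - max(1, (fragment_len + L - 1) // L)
    in_copies = rng.integers(0, n_res_copies, n_pairs)
    phase = rng.integers(0, L, n_pairs)
    input_starts = in_copies * L + phase
    inp = _pairs_from_fragments(array_enc, input_starts, fragment_len, read_len, "input")
    return chip, inp
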