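"""Read-level steps of deficiency mapping.

Three operations, applied per line in order: 3' trimming of ambiguous (N)
and artificial poly-G tails; subtraction of reads that map to a unique
location on the host (A-chromosome) complement with a small mismatch
budget; and placement of the survivors that map to a unique location on
the target scaffolds with zero mismatches.  Uniqueness is always a global
two-strand property.
"""
from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .. import dna
from ..mapping import ReferenceIndex, count_alignments
from ..reads import ReadSet

logger = logging.getLogger(__name__)

TRIM_MIN = 3
MIN_KEEP = 30


def preprocess_reads(reads: ReadSet, trim_min: int = TRIM_MIN,
                     min_keep: int = MIN_KEEP) -> ReadSet:
    """Trim maximal 3' runs of N and/or G (length >= trim_min); drop short reads."""
    if reads.n == 0:
        raise ValueError("reads must be nonempty")
    seqs, lengths = reads.seqs, reads.lengths
    col = np.arange(seqs.shape[1])
    in_read = col[None, :] < lengths[:, None]
    tailish = ((seqs == 2) | (seqs == dna.N_CODE)) & in_read   # G or N
    keepable = in_read & ~tailish
    last_keep = np.where(keepable.any(axis=1),
                         keepable.shape[1] - 1 - np.argmax(keepable[:, ::-1], axis=1),
                         -1)
    new_len = (last_keep + 1).astype(np.int32)
    run = lengths - new_len
    new_len = np.where(run >= trim_min, new_len, lengths).astype(np.int32)

    out = ReadSet(seqs.copy(), new_len, ids=reads.ids, truth=reads.truth)
    pad_mask = col[None, :] >= new_len[:, None]
    out.seqs[pad_mask] = dna.PAD_CODE
    survivors = new_len >= min_keep
    n_trim = int((run >= trim_min).sum())
    n_drop = int((~survivors).sum())
    if n_trim or n_drop:
        logger.info("preprocess: trimmed %d reads, dropped %d short reads",
                    n_trim, n_drop)
    if n_drop == 0:
        return out
    if survivors.sum() == 0:
        logger.warning("preprocess: no reads survive trimming")
    return out.subset(survivors)


def _as_index(reference, k: int) -> ReferenceIndex:
    if isinstance(reference, ReferenceIndex):
        return reference
    return ReferenceIndex(reference, k=k)


def subtract_host_reads(reads: ReadSet, a_genome, max_mismatches: int = 2,
                        max_hits: int = 10, k: int = 10) -> ReadSet:
    """Remove reads with exactly one host alignment within the mismatch budget.

    A read is removed iff it has exactly one alignment to the host
    complement with at most ``max_mismatches`` substitutions among at most
    ``max_hits`` reported placements (a read with more alignments than the
    reporting cap is by definition not uniquely placed and is retained).
    """
    index = _as_index(a_genome, k)
    res = count_alignments(reads, index, max_mismatches, count_cap=max_hits + 1)
    removed = res.counts == 1
    logger.info("subtract: removed %d / %d host-unique reads",
                int(removed.sum()), reads.n)
    return reads.subset(~removed)


def map_unique_to_scaffolds(reads: ReadSet, scaffolds, k: int = 10
                            ) -> pd.DataFrame:
    """Zero-mismatch unique placements: (read_index, scaffold, start, strand)."""
    index = _as_index(scaffolds, k)
    res = count_alignments(reads, index, max_mismatches=0, count_cap=2)
    unique = np.flatnonzero(res.counts == 1)
    seq_idx, local = index.locate(res.gpos[unique])
    return pd.DataFrame({
        "read_index": unique,
        "scaffold": [index.names[i] for i in seq_idx],
        "start": local,
        "strand": np.where(res.strand[unique] == 1, "+", "-"),
    })
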