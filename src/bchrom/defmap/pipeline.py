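"""End-to-end deficiency-mapping driver.

Runs, for every mapping line: 3' trimming, host-read subtraction against
the A complement, unique zero-mismatch placement on the B scaffolds and
1-kb window counting; then calls the presence matrix, orders scaffolds
into breakpoint bins, orients breakpoint-spanning scaffolds and emits the
pseudomolecule, and finally re-profiles every line against the
pseudomolecule to verify that each line covers one contiguous block.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .. import kmer
from ..mapping import ReferenceIndex
from ..reads import ReadSet
from .build import orient_and_build, verify_profile
from .coverage import PresenceMatrix, WindowCoverage, call_presence, coverage_windows
from .order import PseudomoleculeLayout, order_scaffolds
from .reads import map_unique_to_scaffolds, preprocess_reads, subtract_host_reads

logger = logging.getLogger(__name__)


@dataclass
class DeficiencyMapResult:
    matrix: PresenceMatrix
    layout: PseudomoleculeLayout
    pseudomolecule: str
    verification: pd.DataFrame
    cov_by_line: dict[str, dict[str, WindowCoverage]]
    repeat_mask: dict[str, np.ndarray] = field(repr=False, default=None)


def expand_position_mask(mask: np.ndarray, length: int, k: int) -> np.ndarray:
    """Expand a k-mer start-position mask to a per-base mask of ``length``."""
    idx = np.arange(length)
    reach = np.zeros(length, dtype=np.int64)
    sub = idx[: mask.size]
    reach[: mask.size][mask] = sub[mask] + k
    return idx < np.maximum.accumulate(reach)


def line_coverage(reads: ReadSet, a_index: ReferenceIndex,
                  scaffold_index: ReferenceIndex,
                  scaffold_lengths: Mapping[str, int],
                  base_masks: Mapping[str, np.ndarray] | None,
                  window: int = 1000, max_mismatches: int = 2,
                  max_hits: int = 10) -> dict[str, WindowCoverage]:
    """Trim, subtract, place and window-count one line's read set."""
    trimmed = preprocess_reads(reads)
    kept = subtract_host_reads(trimmed, a_index, max_mismatches=max_mismatches,
                               max_hits=max_hits)
    placements = map_unique_to_scaffolds(kept, scaffold_index)
    return coverage_windows(placements, scaffold_lengths, window=window,
                            repeat_mask=base_masks, drop_masked_starts=True)


def run_deficiency_mapping(scaffolds: Mapping[str, str],
                           a_genome: Mapping[str, str],
                           reads_by_line: Mapping[str, ReadSet],
                           terminal_lines: list[str],
                           control_line: str,
                           mini_lines: list[str] | None = None,
                           window: int = 1000,
                           max_mismatches: int = 2,
                           present_frac: float = 0.9,
                           absent_frac: float = 0.1,
                           min_count: int = 3,
                           gap_len: int = 100,
                           mask_k: int = 31,
                           mask_threshold: int = 2,
                           verify: bool = True,
                           force: bool = False) -> DeficiencyMapResult:
    a_index = ReferenceIndex(a_genome, k=10)
    scaffold_index = ReferenceIndex(scaffolds, k=10)
    scaffold_lengths = {n: len(s) for n, s in scaffolds.items()}

    # repetitive mask over the combined corpus: windows whose k-mers recur
    # (satellite arrays, young TE copies, knob shared with A) are excluded
    # from presence denominators
    pos_masks = kmer.repeat_mask(scaffolds, extra=a_genome, k=mask_k,
                                 threshold=mask_threshold)
    base_masks = {name: expand_position_mask(m, scaffold_lengths[name], mask_k)
                  for name, m in pos_masks.items()}

    cov_by_line = {}
    for line, reads in reads_by_line.items():
        logger.info("profiling line %s (%d reads)", line, reads.n)
        cov_by_line[line] = line_coverage(
            reads, a_index, scaffold_index, scaffold_lengths, base_masks,
            window=window, max_mismatches=max_mismatches)

    # min_count > 1 makes windows robust to "error echo" placements: a
    # sequencing error that lands exactly on the one site distinguishing
    # two young TE copies recreates the sister copy verbatim and yields a
    # stray unique placement; such windows collect one or two reads where
    # genuinely retained windows collect dozens
    matrix = call_presence(cov_by_line, present_frac=present_frac,
                           absent_frac=absent_frac, min_count=min_count)
    layout = order_scaffolds(matrix, terminal_lines, mini_lines=mini_lines,
                             control_line=control_line,
                             scaffold_lengths=scaffold_lengths, force=force)
    pseudo, layout = orient_and_build(layout, scaffolds, matrix, cov_by_line,
                                      gap_len=gap_len, min_count=min_count)

    verification = pd.DataFrame()
    if verify:
        pseudo_name = "chrB_pseudomolecule"
        pseudo_index = ReferenceIndex({pseudo_name: pseudo}, k=10)
        p_mask = kmer.repeat_mask({pseudo_name: pseudo}, extra=a_genome,
                                  k=mask_k, threshold=mask_threshold)
        p_base = {pseudo_name: expand_position_mask(
            p_mask[pseudo_name], len(pseudo), mask_k)}
        per_line = {}
        for line, reads in reads_by_line.items():
            cov = line_coverage(reads, a_index, pseudo_index,
                                {pseudo_name: len(pseudo)}, p_base,
                                window=window, max_mismatches=max_mismatches)
            per_line[line] = cov[pseudo_name]
        verification = verify_profile(per_line, min_count=min_count)

    return DeficiencyMapResult(matrix=matrix, layout=layout,
                               pseudomolecule=pseudo,
                               verification=verification,
                               cov_by_line=cov_by_line,
                               repeat_mask=base_masks)
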