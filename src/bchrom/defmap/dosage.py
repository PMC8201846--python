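"""Chromosome-arm dosage (copy-number) test from gene-region read counts.

Reads of each library are placed uniquely on the host genome; counts in
annotated gene regions are normalised per million placed reads, each
region's ratio is taken against a haploid control library, and regions
are summarised per chromosome segment by the median ratio.  A disomic
segment in a haploid background shows a ratio near 2, a monosomic segment
in a diploid background near 0.5; segments crossing the gain/loss
thresholds are flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ..mapping import ReferenceIndex, count_alignments
from ..reads import ReadSet

logger = logging.getLogger(__name__)

GAIN_THRESHOLD = 1.5
LOSS_THRESHOLD = 0.66


@dataclass
class DosageProfile:
    region_counts: pd.DataFrame    # region, library, count, cpm
    ratios: pd.DataFrame           # region, segment, library, ratio
    segment_ratios: pd.DataFrame   # library, segment, ratio, call


def _count_regions(reads: ReadSet, index: ReferenceIndex,
                   regions: pd.DataFrame, max_mismatches: int
                   ) -> tuple[np.ndarray, int]:
    res = count_alignments(reads, index, max_mismatches, count_cap=2)
    unique = res.counts == 1
    seq_idx, local = index.locate(res.gpos[unique])
    chrom = np.array(index.names, dtype=object)[seq_idx]
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {c: np.sort(local[chrom == c]) for c in index.names}
    for i, row in enumerate(regions.itertuples(index=False)):
        pos = by_chrom.get(row.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
    return counts, int(unique.sum())


def dosage_profile(gene_regions: pd.DataFrame,
                   libraries: Mapping[str, ReadSet],
                   control: str,
                   reference: Mapping[str, str] | ReferenceIndex,
                   max_mismatches: int = 0,
                   gain: float = GAIN_THRESHOLD,
                   loss: float = LOSS_THRESHOLD,
                   median_center: bool = True,
                   k: int = 10) -> DosageProfile:
    """Per-region and per-segment dosage ratios of each library vs control.

    ``gene_regions`` needs columns chrom, start, end, name and optionally
    ``segment`` (defaults to the chromosome).  With ``median_center`` the
    per-region ratios of each library are rescaled by that library's
    genome-wide median ratio, so a euploid background sits at 1.0 even
    when the aberrant segment shifts the library size itself.
    """
    if control not in libraries:
        raise ValueError(f"control library {control!r} missing")
    regions = gene_regions.reset_index(drop=True).copy()
    if "segment" not in regions.columns:
        regions["segment"] = regions["chrom"]
    index = reference if isinstance(reference, ReferenceIndex) else \
        ReferenceIndex(reference, k=k)

    count_rows = []
    cpm = {}
    for lib, reads in libraries.items():
        counts, total = _count_regions(reads, index, regions, max_mismatches)
        if total == 0:
            raise ValueError(f"library {lib!r} has no uniquely placed reads")
        cpm[lib] = counts / total * 1e6
        for i, c in enumerate(counts):
            count_rows.append((regions.at[i, "name"], lib, int(c), cpm[lib][i]))
    region_counts = pd.DataFrame(count_rows,
                                 columns=["region", "library", "count", "cpm"])

    ratio_rows = []
    ctrl = cpm[control]
    skipped = int((ctrl == 0).sum())
    if skipped:
        logger.info("dosage: skipping %d regions with zero control counts", skipped)
    for lib in libraries:
        if lib == control:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(ctrl > 0, cpm[lib] / np.where(ctrl > 0, ctrl, 1), np.nan)
        for i in range(len(regions)):
            if ctrl[i] == 0:
                continue
            ratio_rows.append((regions.at[i, "name"], regions.at[i, "segment"],
                               lib, float(r[i])))
    ratios = pd.DataFrame(ratio_rows,
                          columns=["region", "segment", "library", "ratio"])
    if median_center and len(ratios):
        med = ratios.groupby("library")["ratio"].transform("median")
        ratios["ratio"] = ratios["ratio"] / med

    seg_rows = []
    for (lib, segment), grp in ratios.groupby(["library", "segment"]):
        med = float(grp["ratio"].median())
        call = "gain" if med >= gain else ("loss" if med <= loss else "neutral")
        seg_rows.append((lib, segment, med, call, len(grp)))
    segment_ratios = pd.DataFrame(
        seg_rows, columns=["library", "segment", "ratio", "call", "n_regions"])
    return DosageProfile(region_counts, ratios, segment_ratios)
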