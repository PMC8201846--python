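"""Orientation, pseudomolecule assembly, AGP 2.1 IO and verification.

A scaffold spanning a breakpoint is oriented by which of its halves is
covered in the line defining that breakpoint: the covered half must face
the retained, centromere-proximal side.  Scaffolds not spanning any
breakpoint cannot be oriented from the panel and are emitted as '+' with
orientation recorded as unknown.  Scaffolds are joined with a fixed run
of N; the AGP file records the layout and survives a parse round trip.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .. import dna
from .coverage import WindowCoverage, PresenceMatrix
from .order import PseudomoleculeLayout, PlacedScaffold

logger = logging.getLogger(__name__)

DEFAULT_GAP = 100
TIE_MARGIN = 0.10
AGP_OBJECT = "chrB_pseudomolecule"


def _half_coverage(cov: WindowCoverage, min_count: int = 1
                   ) -> tuple[float, float]:
    half = cov.n_windows // 2
    out = []
    for sl in (slice(0, half), slice(half, None)):
        informative = cov.nonrepetitive[sl]
        counts = cov.counts[sl]
        if informative.sum() == 0:
            out.append(float("nan"))
        else:
            out.append(float((counts[informative] >= min_count).mean()))
    return out[0], out[1]


def orient_and_build(layout: PseudomoleculeLayout,
                     scaffolds: Mapping[str, str],
                     matrix: PresenceMatrix,
                     cov_by_line: Mapping[str, Mapping[str, WindowCoverage]],
                     gap_len: int = DEFAULT_GAP,
                     tie_margin: float = TIE_MARGIN,
                     min_count: int = 1) -> tuple[str, PseudomoleculeLayout]:
    """Fill orientations and offsets; return (pseudomolecule sequence, layout)."""
    terminal = layout.terminal_order
    for p in layout.placements:
        p.length = len(scaffolds[p.scaffold])
        partial_lines = [l for l in terminal
                         if matrix.calls.at[p.scaffold, l] == "partial"]
        best = None
        for line in partial_lines:
            h1, h2 = _half_coverage(cov_by_line[line][p.scaffold], min_count)
            if np.isnan(h1) or np.isnan(h2):
                continue
            diff = abs(h1 - h2)
            rel = diff / max(h1, h2) if max(h1, h2) > 0 else 0.0
            if best is None or diff > best[0]:
                best = (diff, rel, h1, h2, line)
        if best is None:
            p.orientation = "?"
            continue
        diff, rel, h1, h2, line = best
        if rel <= tie_margin:
            p.orientation = "?"
            logger.warning("orientation tie for %s in line %s (%.2f vs %.2f)",
                           p.scaffold, line, h1, h2)
        else:
            # the retained side of a terminal line is the proximal side
            p.orientation = "+" if h1 > h2 else "-"

    parts = []
    pos = 0
    for i, p in enumerate(layout.placements):
        if i > 0 and gap_len:
            parts.append("N" * gap_len)
            pos += gap_len
        seq = scaffolds[p.scaffold]
        if p.orientation == "-":
            seq = dna.revcomp(seq)
        p.start = pos
        p.end = pos + len(seq)
        parts.append(seq)
        pos = p.end
    return "".join(parts), layout


# --- AGP 2.1 ---------------------------------------------------------------

def write_agp(layout: PseudomoleculeLayout, path, object_name: str = AGP_OBJECT
              ) -> None:
    """Serialize the layout as AGP 2.1 (evidence tag "map" for gaps)."""
    lines = ["##agp-version\t2.1"]
    part = 0
    prev_end = 0
    for i, p in enumerate(layout.placements):
        if i > 0 and layout.gap_len:
            part += 1
            lines.append("\t".join(map(str, [
                object_name, prev_end + 1, prev_end + layout.gap_len, part,
                "N", layout.gap_len, "scaffold", "yes", "map"])))
        part += 1
        orient = p.orientation if p.orientation in "+-" else "?"
        lines.append("\t".join(map(str, [
            object_name, p.start + 1, p.end, part,
            "W", p.scaffold, 1, p.end - p.start, orient])))
        prev_end = p.end
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_agp(path) -> PseudomoleculeLayout:
    placements = []
    gap_len = 0
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if f[4] == "N":
                gap_len = int(f[5])
                continue
            start1, end = int(f[1]), int(f[2])
            placements.append(PlacedScaffold(
                scaffold=f[5], bin_index=-1, orientation=f[8],
                length=int(f[7]), start=start1 - 1, end=end))
    return PseudomoleculeLayout(placements=placements, gap_len=gap_len)


def verify_profile(cov_by_line: Mapping[str, WindowCoverage],
                   hole_tolerance: float = 0.1,
                   min_count: int = 1) -> pd.DataFrame:
    """Check each line's coverage of the pseudomolecule is one contiguous block.

    ``cov_by_line`` maps line name to the pseudomolecule's WindowCoverage
    after re-running the read pipeline against it.  A line passes when its
    covered informative windows form a single run (small holes tolerated).
    """
    rows = []
    for line, cov in cov_by_line.items():
        informative = np.flatnonzero(cov.nonrepetitive)
        covered = informative[cov.counts[informative] >= min_count]
        if covered.size == 0:
            rows.append((line, 0, 0.0, True))   # nothing covered: trivially one block
            continue
        span = np.flatnonzero((informative >= covered.min())
                              & (informative <= covered.max()))
        holes = span.size - covered.size
        contiguous = holes <= hole_tolerance * span.size
        rows.append((line, int(covered.size), holes / max(span.size, 1), bool(contiguous)))
    return pd.DataFrame(rows, columns=["line", "covered_windows",
                                       "hole_fraction", "contiguous"])
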