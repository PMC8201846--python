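"""Breakpoint ordering of scaffolds from the presence matrix.

The terminal-deletion lines retain nested prefixes of the chromosome, so a
scaffold's call vector over terminal lines ordered by retained length must
read absent ... absent, (partial at the breakpoint), present ... present —
the consecutive-ones property along a containment chain.  Scaffolds with
identical signatures share a bin (within-bin order unresolvable from the
panel); bins are ordered by how many terminal lines cover them, placing
the centromere-proximal bin first.  Any cell violating the chain pattern
is surfaced as a conflict rather than silently reordered.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coverage import PresenceMatrix

CALL_VALUE = {"absent": 0.0, "partial": 0.5, "present": 1.0}


class OrderingConflict(RuntimeError):
    def __init__(self, message: str, conflicts: pd.DataFrame):
        super().__init__(message)
        self.conflicts = conflicts


@dataclass
class PlacedScaffold:
    scaffold: str
    bin_index: int
    orientation: str = "?"       # '+', '-', '?' (unknown)
    length: int = 0
    start: int = -1              # offsets filled by orient_and_build
    end: int = -1


@dataclass
class PseudomoleculeLayout:
    placements: list[PlacedScaffold]
    gap_len: int = 100
    unresolved_bins: list[int] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)   # uninformative scaffolds
    terminal_order: list[str] = field(default_factory=list)

    @property
    def bins(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for p in self.placements:
            out.setdefault(p.bin_index, []).append(p.scaffold)
        return [out[i] for i in sorted(out)]

    def scaffold_order(self) -> list[str]:
        return [p.scaffold for p in self.placements]

    def orientation_of(self, scaffold: str) -> str:
        for p in self.placements:
            if p.scaffold == scaffold:
                return p.orientation
        raise KeyError(scaffold)


def _terminal_chain(matrix: PresenceMatrix, terminal_lines: list[str]
                    ) -> list[str]:
    """Order terminal lines by their coverage footprint (smallest first).

    Derived from the calls themselves: a line retaining less of the
    chromosome covers fewer scaffolds (weighting partial as half).
    """
    scores = {}
    for line in terminal_lines:
        vals = [CALL_VALUE.get(matrix.calls.at[s, line], 0.0)
                for s in matrix.scaffolds]
        scores[line] = sum(vals)
    return sorted(terminal_lines, key=lambda l: (scores[l], l))


def order_scaffolds(matrix: PresenceMatrix, terminal_lines: list[str],
                    mini_lines: list[str] | None = None,
                    control_line: str | None = None,
                    scaffold_lengths: dict[str, int] | None = None,
                    force: bool = False) -> PseudomoleculeLayout:
    """Group scaffolds into bins by signature and order bins along the chain."""
    if control_line is not None:
        ctrl = matrix.calls[control_line]
        informative = [s for s in matrix.scaffolds if ctrl[s] != "uninformative"]
        not_present = [s for s in informative if ctrl[s] != "present"]
        if not_present and not force:
            raise OrderingConflict(
                "control line does not show every informative scaffold as present",
                pd.DataFrame({"scaffold": not_present, "line": control_line,
                              "call": [ctrl[s] for s in not_present]}))
    chain = _terminal_chain(matrix, terminal_lines)

    conflicts = []
    signatures: dict[str, tuple] = {}
    excluded = []
    for s in matrix.scaffolds:
        calls = [matrix.calls.at[s, line] for line in chain]
        if any(c == "uninformative" for c in calls):
            excluded.append(s)
            continue
        vals = [CALL_VALUE[c] for c in calls]
        # chain consistency: non-decreasing along increasing retention,
        # with at most one strict partial plateau at the transition
        for i in range(1, len(vals)):
            if vals[i] < vals[i - 1]:
                conflicts.append((s, chain[i], calls[i], "drops along chain"))
        signatures[s] = tuple(vals)

    conflict_frame = pd.DataFrame(conflicts,
                                  columns=["scaffold", "line", "call", "problem"])
    if len(conflict_frame) and not force:
        raise OrderingConflict(
            f"{len(conflict_frame)} presence calls violate the containment chain",
            conflict_frame)

    # bins: identical signature; order by descending coverage score
    sig_to_scaffolds: dict[tuple, list[str]] = {}
    for s, sig in signatures.items():
        sig_to_scaffolds.setdefault(sig, []).append(s)
    ordered_sigs = sorted(sig_to_scaffolds, key=lambda sig: -sum(sig))

    lengths = scaffold_lengths or {}
    placements = []
    unresolved = []
    for bi, sig in enumerate(ordered_sigs):
        # within a bin the panel gives no order: sort by descending length
        # (then name) purely for determinism, and flag the bin
        members = sorted(sig_to_scaffolds[sig],
                         key=lambda s: (-lengths.get(s, 0), s))
        if len(members) > 1:
            unresolved.append(bi)
        for s in members:
            placements.append(PlacedScaffold(scaffold=s, bin_index=bi,
                                             length=lengths.get(s, 0)))
    return PseudomoleculeLayout(placements=placements,
                                unresolved_bins=unresolved,
                                excluded=excluded,
                                terminal_order=chain)
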