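"""Deletion / translocation line panels with known retained B intervals.

The panel emulates the genetic material that makes deficiency mapping
possible: a nested family of terminal-deletion lines retaining [0, bp_i)
of the B with pairwise-distinct breakpoints, mini-chromosome lines
retaining an interval around the centromere, a control line with the full
B, a line without any B, and dosage-variant lines (one A segment disomic
in a haploid background, one monosomic in a diploid background) for the
copy-number test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

LINE_KINDS = ("control", "zero_b", "terminal", "mini", "disomy", "monosomy")


@dataclass
class LineSpec:
    name: str
    kind: str
    retained: list[tuple[int, int]]          # sorted, non-overlapping B intervals
    b_copies: int = 1
    a_dosage: dict[str, int] = field(default_factory=dict)  # segment -> 0/1/2

    def dosage(self, segment: str, default: int = 1) -> int:
        return self.a_dosage.get(segment, self.a_dosage.get("*", default))

    def retained_length(self) -> int:
        return sum(e - s for s, e in self.retained) if self.b_copies else 0

    def covers(self, start: int, end: int) -> float:
        """Fraction of [start, end) retained by this line (0 if no B copy)."""
        if not self.b_copies:
            return 0.0
        cov = 0
        for s, e in self.retained:
            cov += max(0, min(e, end) - max(s, start))
        return cov / (end - start)


@dataclass
class LinePanel:
    lines: list[LineSpec]
    b_length: int

    def __post_init__(self):
        for line in self.lines:
            prev = 0
            for s, e in line.retained:
                if not (0 <= s < e <= self.b_length) or s < prev:
                    raise ValueError(f"bad retained intervals in line {line.name}")
                prev = e
        if not any(line.kind == "control" for line in self.lines):
            raise ValueError("panel must include a full-B control line")
        bps = self.breakpoints()
        if len(bps) != len(set(bps)):
            raise ValueError("panel breakpoints must be pairwise distinct")

    def breakpoints(self) -> list[int]:
        out = []
        for line in self.lines:
            for s, e in line.retained:
                if s > 0:
                    out.append(s)
                if e < self.b_length:
                    out.append(e)
        return out

    def get(self, name: str) -> LineSpec:
        for line in self.lines:
            if line.name == name:
                return line
        raise KeyError(name)

    def by_kind(self, kind: str) -> list[LineSpec]:
        return [line for line in self.lines if line.kind == kind]

    def mapping_lines(self) -> list[LineSpec]:
        """Lines used for presence/absence mapping (no dosage variants)."""
        return [l for l in self.lines if l.kind in ("control", "terminal", "mini")]

    # --- TSV round trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line in self.lines:
            intervals = ";".join(f"{s}-{e}" for s, e in line.retained)
            dosage = ";".join(f"{k}={v}" for k, v in sorted(line.a_dosage.items()))
            rows.append((line.name, line.kind, line.b_copies, intervals, dosage))
        return pd.DataFrame(
            rows, columns=["line", "kind", "b_copies", "retained", "a_dosage"])

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "b_length", self.b_length)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LinePanel":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        lines = []
        for _, row in frame.iterrows():
            retained = []
            if row["retained"]:
                for part in str(row["retained"]).split(";"):
                    s, e = part.split("-")
                    retained.append((int(s), int(e)))
            dosage = {}
            if row["a_dosage"]:
                for part in str(row["a_dosage"]).split(";"):
                    k, v = part.split("=")
                    dosage[k] = int(v)
            lines.append(LineSpec(row["line"], row["kind"], retained,
                                  int(row["b_copies"]), dosage))
        return cls(lines, int(frame["b_length"].iloc[0]))


def make_line_panel(genome: GenomeModel, n_terminal: int = 8, n_mini: int = 2,
                    seed: int = 0, breakpoint_jitter: float = 0.25) -> LinePanel:
    """Build the standard panel for a genome.

    Terminal breakpoints are spread between the end of the centromere (BC)
    and the distal end, jittered around even spacing; mini lines retain an
    interval containing BC entirely.
    """
    if n_terminal < 2:
        raise ValueError("n_terminal must be >= 2")
    rng = np.random.default_rng(seed)
    b_len = genome.b_len
    bc_start, bc_end = genome.segment_interval("BC")

    lo = bc_end + int(0.02 * b_len)
    hi = b_len - int(0.02 * b_len)
    spacing = (hi - lo) / n_terminal
    for _ in range(100):
        jitter = rng.uniform(-breakpoint_jitter, breakpoint_jitter, n_terminal) * spacing
        bps = np.sort((lo + (np.arange(n_terminal) + 0.5) * spacing + jitter).astype(int))
        if np.all(np.diff(bps) > 0):
            break
    else:  # pragma: no cover - jitter < spacing/2 makes collisions impossible
        raise RuntimeError("could not draw distinct breakpoints")

    segments = genome.a_segment_names()
    mid = segments[len(segments) // 4]      # target segment for dosage variants

    for _ in range(50):  # redraw mini intervals on breakpoint collisions
        lines = [LineSpec("B-full", "control", [(0, b_len)], b_copies=1)]
        lines.append(LineSpec("0B", "zero_b", [], b_copies=0))
        for i, bp in enumerate(bps):
            lines.append(LineSpec(f"tdel{i:02d}", "terminal", [(0, int(bp))],
                                  b_copies=1))
        for j in range(n_mini):
            start = int(rng.integers(0, max(bc_start, 1))) if bc_start > 0 else 0
            max_ext = max(int(0.10 * (b_len - bc_end)), 1)
            end = bc_end + int(rng.integers(1, max_ext + 1))
            lines.append(LineSpec(f"miniB{j:02d}", "mini", [(start, end)],
                                  b_copies=1))
        lines.append(LineSpec("disomy", "disomy", [], b_copies=0,
                              a_dosage={"*": 1, mid: 2}))
        lines.append(LineSpec("monosomy", "monosomy", [], b_copies=0,
                              a_dosage={"*": 2, mid: 1}))
        try:
            return LinePanel(lines, b_len)
        except ValueError:
            continue
    raise RuntimeError("could not build a panel with distinct breakpoints")
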