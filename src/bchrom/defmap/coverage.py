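"""Window coverage and presence/absence calling.

Unique-read placements are counted in fixed windows (1 kb by default)
along each scaffold; windows overlapping the repetitive mask by at least
half are flagged and excluded from the presence denominator, because
unique reads cannot inform them.  A scaffold's covered fraction in a line
is the fraction of informative windows holding at least ``min_count``
reads; thresholds turn it into present / partial / absent calls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 1000
PRESENT_FRAC = 0.9
ABSENT_FRAC = 0.1
CALLS = ("present", "partial", "absent", "uninformative")


@dataclass
class WindowCoverage:
    scaffold: str
    window: int
    counts: np.ndarray            # unique-read count per window
    nonrepetitive: np.ndarray     # per-window informative flag

    @property
    def n_windows(self) -> int:
        return self.counts.size

    def covered_fraction(self, min_count: int = 1) -> float:
        informative = self.nonrepetitive
        if informative.sum() == 0:
            return float("nan")
        return float((self.counts[informative] >= min_count).mean())


def _window_repetitive(length: int, window: int, mask) -> np.ndarray:
    """Per-window flag: >= 50% of window bases under the repetitive mask."""
    n_win = -(-length // window)
    if mask is None:
        return np.zeros(n_win, dtype=bool)
    base_mask = np.zeros(length, dtype=bool)
    if isinstance(mask, np.ndarray):
        if mask.dtype == bool:
            base_mask[: mask.size] = mask
        else:
            raise TypeError("ndarray mask must be boolean")
    else:  # BED-like frame with start/end
        for _, row in mask.iterrows():
            base_mask[int(row["start"]): int(row["end"])] = True
    flags = np.zeros(n_win, dtype=bool)
    for w in range(n_win):
        chunk = base_mask[w * window: (w + 1) * window]
        flags[w] = chunk.mean() >= 0.5
    return flags


def coverage_windows(placements: pd.DataFrame, scaffold_lengths: Mapping[str, int],
                     window: int = DEFAULT_WINDOW,
                     repeat_mask: Mapping | None = None,
                     drop_masked_starts: bool = False
                     ) -> dict[str, WindowCoverage]:
    """Count placements per window (a placement falls in the window of its start).

    With ``drop_masked_starts`` placements whose start position lies under
    the repetitive mask are ignored: a read that maps "uniquely" into a
    region it did not come from must lie entirely within a duplicated
    stretch, so its start is masked, while genuinely local reads also
    start on the unique sequence around it.
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    out: dict[str, WindowCoverage] = {}
    groups = dict(tuple(placements.groupby("scaffold"))) if len(placements) else {}
    for scaffold, length in scaffold_lengths.items():
        n_win = -(-length // window)
        counts = np.zeros(n_win, dtype=np.int64)
        if scaffold in groups:
            starts = groups[scaffold]["start"].to_numpy()
            if (starts < 0).any() or (starts >= length).any():
                raise ValueError(f"placement out of bounds on {scaffold}")
            if drop_masked_starts and repeat_mask is not None:
                mask = repeat_mask.get(scaffold)
                if isinstance(mask, np.ndarray) and mask.dtype == bool:
                    starts = starts[~mask[np.minimum(starts, mask.size - 1)]]
            counts = np.bincount(starts // window, minlength=n_win).astype(np.int64)
        mask = repeat_mask.get(scaffold) if repeat_mask is not None else None
        flags = _window_repetitive(length, window, mask)
        informative = ~flags
        # a short tail window holds too few potential read starts to inform
        if length % window and (length % window) < window // 2:
            informative[-1] = False
        out[scaffold] = WindowCoverage(scaffold, window, counts, informative)
    return out


def write_bedgraph(cov: Mapping[str, WindowCoverage], path) -> None:
    """Per-window unique-read counts as bedGraph (repetitive windows skipped)."""
    with open(path, "w") as fh:
        for scaffold, wc in cov.items():
            for w in range(wc.n_windows):
                if not wc.nonrepetitive[w]:
                    continue
                fh.write(f"{scaffold}\t{w * wc.window}"
                         f"\t{(w + 1) * wc.window}\t{int(wc.counts[w])}\n")


@dataclass
class PresenceMatrix:
    fractions: pd.DataFrame     # scaffolds x lines, covered fraction (NaN = no info)
    calls: pd.DataFrame         # scaffolds x lines, categorical call

    @property
    def scaffolds(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def lines(self) -> list[str]:
        return list(self.fractions.columns)

    def to_tsv(self, path) -> None:
        long = self.fractions.stack().rename("covered_fraction").reset_index()
        long.columns = ["scaffold", "line", "covered_fraction"]
        long["call"] = [
            self.calls.at[s, l] for s, l in zip(long["scaffold"], long["line"])
        ]
        long.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        long = pd.read_csv(path, sep="\t")
        scaffold_order = long["scaffold"].drop_duplicates().tolist()
        line_order = long["line"].drop_duplicates().tolist()
        fractions = long.pivot(index="scaffold", columns="line",
                               values="covered_fraction")
        calls = long.pivot(index="scaffold", columns="line", values="call")
        fractions = fractions.reindex(index=scaffold_order, columns=line_order)
        calls = calls.reindex(index=scaffold_order, columns=line_order)
        fractions.columns.name = None
        calls.columns.name = None
        return cls(fractions, calls)


def call_presence(cov_by_line: Mapping[str, Mapping[str, WindowCoverage]],
                  present_frac: float = PRESENT_FRAC,
                  absent_frac: float = ABSENT_FRAC,
                  min_count: int = 1) -> PresenceMatrix:
    """Presence matrix over all lines; scaffolds without informative windows
    are called "uninformative" everywhere and excluded from ordering."""
    if not cov_by_line:
        raise ValueError("need at least one line")
    lines = list(cov_by_line)
    scaffolds = list(next(iter(cov_by_line.values())))
    frac = pd.DataFrame(index=scaffolds, columns=lines, dtype=float)
    calls = pd.DataFrame(index=scaffolds, columns=lines, dtype=object)
    for line in lines:
        for scaffold in scaffolds:
            f = cov_by_line[line][scaffold].covered_fraction(min_count)
            frac.at[scaffold, line] = f
            if np.isnan(f):
                calls.at[scaffold, line] = "uninformative"
            elif f >= present_frac:
                calls.at[scaffold, line] = "present"
            elif f <= absent_frac:
                calls.at[scaffold, line] = "absent"
            else:
                calls.at[scaffold, line] = "partial"
    return PresenceMatrix(frac, calls)
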