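"""Synthetic A-complement + acrocentric B chromosome with truth annotation.

The B chromosome is assembled segment by segment in the fixed cytological
order BS (short arm), BC (centromere), PH (proximal heterochromatin),
PE (proximal euchromatin), DH1-4 (distal heterochromatin blocks), DE
(distal euchromatin).  The short arm and centromere are dominated by the
B-specific tandem repeat interleaved with centromeric satellite; the
heterochromatin blocks carry knob arrays that also occur on the A
chromosomes; transposable elements are drawn from a shared template pool
and placed on both A and B with insertion ages from a common exponential
distribution; B genes are mutated copies of randomly chosen A genes.

All coordinates are 0-based half-open.  Truth rows use types
{"segment", "repeat", "te", "gene"}.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import dna
from .coding import evolve_cds, random_cds
from .library import RepeatLibrary

SEGMENT_ORDER = ["BS", "BC", "PH", "PE", "DH1", "DH2", "DH3", "DH4", "DE"]

DEFAULT_TE_AGE_MEDIAN_MY = 0.46      # simulation default for insertion-age median
DEFAULT_LTR_RATE = 1.3e-8            # substitutions / site / year
DEFAULT_A_SEGMENT_LEN = 30_000


@dataclass
class SegmentSpec:
    name: str
    length: int
    repeat_weights: dict[str, float] = field(default_factory=dict)  # monomer -> bp fraction
    te_fraction: float = 0.60
    genes_per_mb: float = 0.0
    repeat_divergence: float = 0.03   # per-site divergence of array copies from consensus


@dataclass
class BBlueprint:
    segments: list[SegmentSpec]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if names != [n for n in SEGMENT_ORDER if n in names]:
            raise ValueError(f"segment order must follow {SEGMENT_ORDER}")
        for s in self.segments:
            if s.length <= 0:
                raise ValueError(f"segment {s.name} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


_DEFAULT_SEGMENTS = [
    # name, frac of total, repeat weights, te_fraction, genes_per_mb, repeat_div
    ("BS", 0.03, {"b_specific": 0.45, "telomeric": 0.05}, 0.30, 0.0, 0.01),
    ("BC", 0.05, {"b_specific": 0.40, "centromeric_satellite": 0.20}, 0.15, 10.0, 0.01),
    ("PH", 0.12, {"knob": 0.25, "b_specific": 0.05}, 0.55, 5.0, 0.03),
    ("PE", 0.20, {"knob": 0.02}, 0.68, 30.0, 0.03),
    ("DH1", 0.075, {"knob": 0.30}, 0.60, 5.0, 0.03),
    ("DH2", 0.075, {"knob": 0.30}, 0.60, 5.0, 0.03),
    ("DH3", 0.075, {"knob": 0.30}, 0.60, 5.0, 0.03),
    ("DH4", 0.075, {"knob": 0.30}, 0.60, 5.0, 0.03),
    ("DE", 0.30, {"b_specific": 0.02, "centromeric_satellite": 0.02}, 0.65, 25.0, 0.08),
]


def default_blueprint(total_length: int = 2_000_000) -> BBlueprint:
    segs = [
        SegmentSpec(name, max(int(round(frac * total_length)), 1), dict(weights),
                    te_fraction=te, genes_per_mb=gpm, repeat_divergence=div)
        for name, frac, weights, te, gpm, div in _DEFAULT_SEGMENTS
    ]
    # absorb rounding drift into the largest segment
    drift = total_length - sum(s.length for s in segs)
    segs[-1].length += drift
    return BBlueprint(segs)


@dataclass
class LTRInsertionEvent:
    element_id: str
    family_id: str
    age_my: float
    rate: float
    ltr5: str
    ltr3: str
    internal_len: int
    chrom: str
    position: int
    chrom_class: str   # "A" or "B"


@dataclass
class GenomeModel:
    a_chromosomes: list[tuple[str, str]]
    b_chromosome: str
    truth: pd.DataFrame            # chrom, type, start, end, strand, source_id
    library: RepeatLibrary
    ltr_events: list[LTRInsertionEvent] = field(default_factory=list)
    a_segment_length: int = DEFAULT_A_SEGMENT_LEN

    def __post_init__(self):
        lengths = {name: len(seq) for name, seq in self.a_chromosomes}
        lengths["chrB"] = len(self.b_chromosome)
        t = self.truth
        bad = (t["start"] < 0) | (t["end"] > t["chrom"].map(lengths)) | (t["start"] >= t["end"])
        if bad.any():
            raise ValueError("truth intervals out of sequence bounds")
        genes = t[(t["type"] == "gene") & (t["chrom"] == "chrB")].sort_values("start")
        if (genes["start"].values[1:] < genes["end"].values[:-1]).any():
            raise ValueError("B gene truth intervals overlap")

    @property
    def b_len(self) -> int:
        return len(self.b_chromosome)

    @property
    def b_truth(self) -> pd.DataFrame:
        return self.truth[self.truth["chrom"] == "chrB"]

    def a_sequences(self) -> dict[str, str]:
        return dict(self.a_chromosomes)

    def segment_interval(self, name: str) -> tuple[int, int]:
        row = self.truth[(self.truth["type"] == "segment")
                         & (self.truth["source_id"] == name)].iloc[0]
        return int(row["start"]), int(row["end"])

    def a_segments(self) -> pd.DataFrame:
        rows = []
        for chrom, seq in self.a_chromosomes:
            for i, s in enumerate(range(0, len(seq), self.a_segment_length)):
                e = min(s + self.a_segment_length, len(seq))
                rows.append((chrom, s, e, f"{chrom}:{i:02d}"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def a_segment_names(self) -> list[str]:
        return list(self.a_segments()["name"])

    def gene_regions(self, chroms: list[str] | None = None) -> pd.DataFrame:
        t = self.truth
        sel = t["type"] == "gene"
        if chroms is not None:
            sel &= t["chrom"].isin(chroms)
        out = t.loc[sel, ["chrom", "start", "end", "source_id"]].copy()
        return out.rename(columns={"source_id": "name"}).reset_index(drop=True)

    def te_fraction_b(self) -> float:
        te = self.b_truth[self.b_truth["type"] == "te"]
        return float((te["end"] - te["start"]).sum()) / self.b_len


def _draw_te_element(rng, template, age_my: float, rate: float):
    """Element sequence + its 5'/3' LTR pair for a given insertion age.

    The source lineage drifts before insertion (shared by both LTRs); after
    insertion each LTR accumulates age * rate substitutions/site
    independently, so the expected pairwise LTR divergence is 2 * age * rate.
    """
    d = age_my * 1e6 * rate
    base_ltr = dna.jc_mutate(template.ltr, d, rng)
    internal = dna.jc_mutate(template.internal, d, rng)
    ltr5 = dna.jc_mutate(base_ltr, d, rng)
    ltr3 = dna.jc_mutate(base_ltr, d, rng)
    return ltr5 + internal + ltr3, ltr5, ltr3


def _build_region(rng, library: RepeatLibrary, length: int, *,
                  repeat_weights: dict[str, float], te_fraction: float,
                  genes: list[tuple[str, str]], repeat_divergence: float,
                  te_age_median_my: float, rate: float, chrom: str,
                  chrom_class: str, id_counter: list[int],
                  events: list[LTRInsertionEvent]):
    """Assemble one region as shuffled blocks + random filler of exact length."""
    blocks = []  # (kind, source_id, seq)
    gene_bp = sum(len(cds) for _, cds in genes)
    budget = length - gene_bp  # bp available for repeats + TEs + filler
    if budget < 0:
        raise ValueError(f"genes alone exceed region length {length}")

    for mono_name, frac in repeat_weights.items():
        target = min(int(frac * length), budget)
        monomer = library.monomers[mono_name]
        got = 0
        while got < target:
            copies = int(rng.integers(5, 31))
            arr = "".join(
                dna.point_mutate(monomer, repeat_divergence, rng) for _ in range(copies)
            )
            if got + len(arr) > target:
                arr = arr[: target - got]
                if len(arr) < len(monomer):
                    break
            blocks.append(("repeat", mono_name, arr))
            got += len(arr)
        budget -= got

    te_target = min(int(te_fraction * length), budget)
    got = 0
    while got < te_target:
        template = library.te_templates[int(rng.integers(len(library.te_templates)))]
        age = float(rng.exponential(te_age_median_my / math.log(2)))
        seq, ltr5, ltr3 = _draw_te_element(rng, template, age, rate)
        if got + len(seq) > te_target:
            # fragmented element at the edge of the TE budget: keep the
            # truncated copy in the truth but do not emit an LTR-pair event
            seq = seq[: te_target - got]
            if len(seq) < 50:
                break
            blocks.append(("te", f"tefrag{id_counter[0]:05d}", seq))
            id_counter[0] += 1
            got += len(seq)
            break
        eid = f"te{id_counter[0]:05d}"
        id_counter[0] += 1
        events.append(LTRInsertionEvent(
            element_id=eid, family_id=template.name, age_my=age, rate=rate,
            ltr5=ltr5, ltr3=ltr3, internal_len=len(template.internal),
            chrom=chrom, position=-1, chrom_class=chrom_class))
        blocks.append(("te", eid, seq))
        got += len(seq)

    for gene_id, cds in genes:
        blocks.append(("gene", gene_id, cds))

    used = sum(len(b[2]) for b in blocks)
    assert used <= length

    order = rng.permutation(len(blocks))
    filler_total = length - used
    cuts = np.sort(rng.integers(0, filler_total + 1, size=len(blocks)))
    filler_parts = np.diff(np.concatenate([[0], cuts, [filler_total]]))

    parts = []
    rows = []  # type, start, end, strand, source_id
    pos = 0
    for slot, bi in enumerate(order):
        fill = int(filler_parts[slot])
        if fill:
            parts.append(dna.random_dna(rng, fill))
            pos += fill
        kind, source_id, seq = blocks[bi]
        rows.append((kind, pos, pos + len(seq), "+", source_id))
        if kind == "te":
            for ev in events:
                if ev.element_id == source_id:
                    ev.position = pos
                    break
        parts.append(seq)
        pos += len(seq)
    tail = int(filler_parts[-1])
    if tail:
        parts.append(dna.random_dna(rng, tail))
        pos += tail
    assert pos == length
    return "".join(parts), rows


def make_genome(blueprint: BBlueprint | None = None,
                library: RepeatLibrary | None = None,
                n_a_chromosomes: int = 2,
                a_length: int = 300_000,
                n_transposed_genes: int = 30,
                seed: int = 0, *,
                te_age_median_my: float = DEFAULT_TE_AGE_MEDIAN_MY,
                rate: float = DEFAULT_LTR_RATE,
                a_te_fraction: float = 0.35,
                a_knob_fraction: float = 0.05,
                a_genes_per_mb: float = 300.0,
                gene_codons: tuple[int, int] = (100, 200),
                a_segment_length: int = DEFAULT_A_SEGMENT_LEN,
                gene_branch_length: float = 0.12,
                gene_nonsyn_accept: float = 0.6) -> GenomeModel:
    """Generate the A complement plus the B chromosome with full truth."""
    from .library import make_repeat_library

    rng = np.random.default_rng(seed)
    if library is None:
        library = make_repeat_library(seed)
    if blueprint is None:
        blueprint = default_blueprint()

    id_counter = [0]
    events: list[LTRInsertionEvent] = []
    truth_rows = []

    # --- A complement, with genes available as transposition donors
    a_chromosomes = []
    a_genes: list[tuple[str, str]] = []
    for ci in range(n_a_chromosomes):
        chrom = f"A{ci + 1}"
        n_genes = int(round(a_genes_per_mb * a_length / 1e6))
        genes = []
        for gi in range(n_genes):
            n_codons = int(rng.integers(gene_codons[0], gene_codons[1]))
            gene_id = f"{chrom}g{gi:04d}"
            cds = random_cds(rng, n_codons)
            genes.append((gene_id, cds))
        a_genes.extend(genes)
        seq, rows = _build_region(
            rng, library, a_length,
            repeat_weights={"knob": a_knob_fraction},
            te_fraction=a_te_fraction, genes=genes,
            repeat_divergence=0.03, te_age_median_my=te_age_median_my,
            rate=rate, chrom=chrom, chrom_class="A",
            id_counter=id_counter, events=events)
        a_chromosomes.append((chrom, seq))
        truth_rows.extend((chrom, t, s, e, st, sid) for t, s, e, st, sid in rows)

    if n_transposed_genes > len(a_genes):
        raise ValueError("n_transposed_genes exceeds genes available on A")

    # --- distribute transposed genes over segments by gene-density weights
    # (largest-remainder apportionment)
    gene_weights = np.array([s.genes_per_mb * s.length for s in blueprint.segments])
    per_seg = np.zeros(len(blueprint.segments), dtype=int)
    if gene_weights.sum() > 0 and n_transposed_genes > 0:
        exact = gene_weights / gene_weights.sum() * n_transposed_genes
        per_seg = np.floor(exact).astype(int)
        remainder_order = np.argsort(-(exact - per_seg))
        for j in remainder_order[: n_transposed_genes - per_seg.sum()]:
            per_seg[j] += 1

    donor_idx = rng.choice(len(a_genes), size=n_transposed_genes,
                           replace=n_transposed_genes > len(a_genes))
    donors = [a_genes[i] for i in donor_idx]

    # --- B chromosome, segment by segment
    b_parts = []
    pos = 0
    di = 0
    bi = 0
    for si, spec in enumerate(blueprint.segments):
        seg_genes = []
        for _ in range(int(per_seg[si])):
            donor_id, donor_cds = donors[di]
            di += 1
            b_copy = evolve_cds(donor_cds, gene_branch_length, gene_nonsyn_accept, rng)
            seg_genes.append((f"Bg{bi:03d}|{donor_id}", b_copy))
            bi += 1
        seq, rows = _build_region(
            rng, library, spec.length,
            repeat_weights=spec.repeat_weights, te_fraction=spec.te_fraction,
            genes=seg_genes, repeat_divergence=spec.repeat_divergence,
            te_age_median_my=te_age_median_my, rate=rate, chrom="chrB",
            chrom_class="B", id_counter=id_counter, events=events)
        truth_rows.append(("chrB", "segment", pos, pos + spec.length, "+", spec.name))
        seg_te_ids = {sid for t, s, e, st, sid in rows if t == "te"}
        truth_rows.extend(("chrB", t, pos + s, pos + e, st, sid)
                          for t, s, e, st, sid in rows)
        # lift region-local TE event positions to B coordinates
        for ev in events:
            if ev.element_id in seg_te_ids:
                ev.position += pos
        b_parts.append(seq)
        pos += spec.length

    b_chromosome = "".join(b_parts)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "type", "start", "end", "strand", "source_id"])

    return GenomeModel(a_chromosomes=a_chromosomes, b_chromosome=b_chromosome,
                       truth=truth, library=library, ltr_events=events,
                       a_segment_length=a_segment_length)


@dataclass
class ScaffoldSet:
    """Scaffolds partitioning the B chromosome, with hidden truth coordinates."""
    sequences: dict[str, str]
    truth: pd.DataFrame          # scaffold, start, end, strand (B coordinates)
    gaps: list[int]              # inter-scaffold gap lengths (len = n_scaffolds - 1)

    def reconstruct(self) -> str:
        """Invert the fragmentation: true order/orientation + recorded gaps."""
        rows = self.truth.sort_values("start")
        parts = []
        for i, (_, row) in enumerate(rows.iterrows()):
            seq = self.sequences[row["scaffold"]]
            parts.append(seq if row["strand"] == "+" else dna.revcomp(seq))
        return "".join(parts)


def fragment_scaffolds(genome: GenomeModel, n_scaffolds: int,
                       min_len: int = 10_000, seed: int = 0) -> ScaffoldSet:
    """Partition the B chromosome into scaffolds with random strand flips.

    Emulates the scaffold stage of an assembly: downstream inference sees
    only the scaffold sequences; the true (start, end, strand) per scaffold
    stays in the hidden truth table.
    """
    if n_scaffolds < 2 and n_scaffolds != 1:
        raise ValueError("n_scaffolds must be >= 1")
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000")
    b_len = genome.b_len
    if n_scaffolds * min_len > b_len:
        raise ValueError("infeasible partition: n_scaffolds * min_len exceeds B length")
    rng = np.random.default_rng(seed)
    extra = rng.multinomial(b_len - n_scaffolds * min_len,
                            np.full(n_scaffolds, 1.0 / n_scaffolds))
    lengths = min_len + extra
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    seqs = {}
    rows = []
    for i, (s, L) in enumerate(zip(starts, lengths)):
        name = f"scaffold{i:03d}"
        seg = genome.b_chromosome[int(s): int(s + L)]
        flip = bool(rng.random() < 0.5)
        seqs[name] = dna.revcomp(seg) if flip else seg
        rows.append((name, int(s), int(s + L), "-" if flip else "+"))
    truth = pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand"])
    return ScaffoldSet(sequences=seqs, truth=truth, gaps=[0] * (n_scaffolds - 1))
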