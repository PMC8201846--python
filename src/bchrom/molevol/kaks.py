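"""Protein-guided codon alignment and Nei–Gojobori (NG86) Ka/Ks.

Sites: for each codon, every position contributes fractions of synonymous
and nonsynonymous sites according to which of its three single-base
changes preserve the encoded amino acid; changes creating stop codons
count as nonsynonymous, so N + S = 3 x codons exactly.  Substitutions
between two codons are classified by averaging over all shortest
mutational paths (equal weights; paths through stop codons are excluded
unless all paths are blocked).  The proportions pN = Nd/N and pS = Sd/S
receive the Jukes–Cantor multiple-hit correction; Ka/Ks is undefined when
Ks = 0 and flagged saturated when a proportion reaches the JC limit.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ..simulate.coding import codon_table

JC_SATURATION = 0.7499
BASES = "ACGT"


# --- protein-guided codon alignment ---------------------------------------

def _translate(cds: str, label: str) -> str:
    table = codon_table()
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i: i + 3]
        if codon not in table:
            raise ValueError(f"unrecognised codon {codon!r} in {label}")
        aa.append(table[codon])
    prot = "".join(aa)
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"internal stop codon in {label}")
    return prot


def align_codon_pair(cds_a: str, cds_b: str,
                     labels: tuple[str, str] = ("cds_a", "cds_b")
                     ) -> tuple[str, str]:
    """Globally align two CDS via their proteins; gaps come in codon triplets.

    Trailing incomplete codons and trailing stops are trimmed; internal
    stops raise an error naming the offending sequence.
    """
    prot_a = _translate(cds_a, labels[0])
    prot_b = _translate(cds_b, labels[1])

    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(prot_a, prot_b)[0]

    out_a, out_b = [], []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        while ia < sa:                       # gap in b
            out_a.append(cds_a[3 * ia: 3 * ia + 3])
            out_b.append("---")
            ia += 1
        while ib < sb:                       # gap in a
            out_a.append("---")
            out_b.append(cds_b[3 * ib: 3 * ib + 3])
            ib += 1
        for _ in range(ea - sa):
            out_a.append(cds_a[3 * ia: 3 * ia + 3])
            out_b.append(cds_b[3 * ib: 3 * ib + 3])
            ia += 1
            ib += 1
    while ia < len(prot_a):
        out_a.append(cds_a[3 * ia: 3 * ia + 3])
        out_b.append("---")
        ia += 1
    while ib < len(prot_b):
        out_a.append("---")
        out_b.append(cds_b[3 * ib: 3 * ib + 3])
        ib += 1
    return "".join(out_a), "".join(out_b)


# --- NG86 ------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (sums to 3)."""
    table = codon_table()
    aa = table[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            # stop-creating changes count as nonsynonymous
            if table[alt] != "*" and table[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_path_substitutions(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) substitutions between two codons, averaged over all
    shortest mutational paths; stop-codon intermediates are excluded
    unless every path passes through one."""
    table = codon_table()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                return None
            if table[nxt] == table[cur]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all paths blocked by stops: fall back to counting through them
        def walk_any(order):
            syn = nonsyn = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                syn += table[nxt] == table[cur]
                nonsyn += table[nxt] != table[cur]
                cur = nxt
            return syn, nonsyn
        valid = [walk_any(order) for order in itertools.permutations(diff_pos)]
    s = sum(v[0] for v in valid) / len(valid)
    n = sum(v[1] for v in valid) / len(valid)
    return s, n


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None            # None when Ks == 0
    n_sites: float                 # nonsynonymous sites N
    s_sites: float                 # synonymous sites S
    nd: float                      # nonsynonymous substitutions
    sd: float                      # synonymous substitutions
    n_codons: int
    saturated: bool = False

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def compute_kaks(aligned_a: str, aligned_b: str) -> KaKsResult:
    """NG86 Ka/Ks from a codon-aware alignment (gap codons skipped)."""
    if len(aligned_a) != len(aligned_b) or len(aligned_a) % 3:
        raise ValueError("inputs must be equal-length codon alignments")
    table = codon_table()
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(aligned_a), 3):
        ca, cb = aligned_a[i: i + 3], aligned_b[i: i + 3]
        if "-" in ca or "-" in cb:
            continue
        if table.get(ca) == "*" or table.get(cb) == "*":
            continue
        n_codons += 1
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        s_obs, n_obs = _codon_path_substitutions(ca, cb)
        sd += s_obs
        nd += n_obs
    if n_codons < 10:
        raise ValueError("need at least 10 aligned codons")

    p_n = nd / n_sites if n_sites else 0.0
    p_s = sd / s_sites if s_sites else 0.0
    saturated = p_n >= JC_SATURATION or p_s >= JC_SATURATION
    if saturated:
        ka, ks = p_n, p_s          # uncorrected values still reported
    else:
        ka = -0.75 * math.log(1.0 - 4.0 * p_n / 3.0)
        ks = -0.75 * math.log(1.0 - 4.0 * p_s / 3.0)
    ratio = None if ks == 0 else ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, n_sites=n_sites,
                      s_sites=s_sites, nd=nd, sd=sd, n_codons=n_codons,
                      saturated=saturated)


def kaks_for_pair(cds_a: str, cds_b: str,
                  labels: tuple[str, str] = ("cds_a", "cds_b")) -> KaKsResult:
    return compute_kaks(*align_codon_pair(cds_a, cds_b, labels))


# --- three-way selection comparison ---------------------------------------

def selection_comparison(triples: list[dict[str, str]]) -> tuple[pd.DataFrame,
                                                                 pd.DataFrame,
                                                                 float]:
    """Ka/Ks for B–A, B–outgroup and A–outgroup per triple, plus the paired
    one-sided Wilcoxon test of Ka/Ks(B,A) > Ka/Ks(A,outgroup).

    Triples with an undefined ratio in the compared pair are dropped
    pairwise and counted in the summary.
    """
    rows = []
    for i, t in enumerate(triples):
        res = {
            "b_vs_a": kaks_for_pair(t["b"], t["a"], ("b", "a")),
            "b_vs_out": kaks_for_pair(t["b"], t["outgroup"], ("b", "outgroup")),
            "a_vs_out": kaks_for_pair(t["a"], t["outgroup"], ("a", "outgroup")),
        }
        row = {"triple": i}
        for name, r in res.items():
            row[f"ka_{name}"] = r.ka
            row[f"ks_{name}"] = r.ks
            row[f"ratio_{name}"] = np.nan if r.ratio is None else r.ratio
        rows.append(row)
    table = pd.DataFrame(rows)

    paired = table.dropna(subset=["ratio_b_vs_a", "ratio_a_vs_out"])
    n_dropped = len(table) - len(paired)
    if len(paired) < 5:
        raise ValueError("too few triples with defined ratios")
    stat, p = sstats.wilcoxon(paired["ratio_b_vs_a"], paired["ratio_a_vs_out"],
                              alternative="greater")
    summary = pd.DataFrame([{
        "n_triples": len(table),
        "n_compared": len(paired),
        "n_dropped": n_dropped,
        "median_b_vs_a": float(paired["ratio_b_vs_a"].median()),
        "median_b_vs_out": float(table["ratio_b_vs_out"].median()),
        "median_a_vs_out": float(paired["ratio_a_vs_out"].median()),
        "wilcoxon_stat": float(stat),
        "wilcoxon_p": float(p),
    }])
    return table, summary, float(p)
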