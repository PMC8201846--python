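"""LTR retrotransposon family clustering and insertion-age dating.

An element's insertion age follows from the divergence of its two long
terminal repeats, which are identical at insertion: with pairwise
distance d (substitutions/site, corrected for multiple hits) and clock
rate r (substitutions/site/year), T = d / (2 r).  Families are single-
linkage clusters on 5' LTR global identity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .. import dna
from ..simulate.ltr import LTRPair

DEFAULT_RATE = 1.3e-8           # substitutions/site/year (grass LTR clock)
FAMILY_IDENTITY = 80.0
MIN_FAMILY_MEMBERS = 10
JC_SATURATION = 0.7499


def pairwise_ltr_identity(a: str, b: str) -> float:
    """Percent global-alignment identity between two LTR sequences."""
    return dna.global_identity(a, b)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_ltr_families(elements: Sequence[LTRPair],
                         identity_threshold: float = FAMILY_IDENTITY,
                         min_members: int = MIN_FAMILY_MEMBERS
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage clustering on 5' LTR identity.

    Returns (membership, families): membership assigns every element a
    cluster id; families summarises per-cluster size and A/B member counts
    with an ``included`` flag for clusters reaching ``min_members``.
    """
    if not elements:
        raise ValueError("need at least one element")
    n = len(elements)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if pairwise_ltr_identity(elements[i].ltr5, elements[j].ltr5) \
                    >= identity_threshold:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    ids = {}
    cluster = []
    for r in roots:
        if r not in ids:
            ids[r] = f"cluster{len(ids):03d}"
        cluster.append(ids[r])
    membership = pd.DataFrame({
        "element_id": [e.element_id for e in elements],
        "cluster": cluster,
        "chrom_class": [e.chrom_class for e in elements],
    })
    families = (membership.groupby("cluster")
                .agg(n_members=("element_id", "size"),
                     n_a=("chrom_class", lambda c: int((c == "A").sum())),
                     n_b=("chrom_class", lambda c: int((c == "B").sum())))
                .reset_index())
    families["included"] = families["n_members"] >= min_members
    return membership, families


@dataclass
class AgeEstimate:
    element_id: str
    p_distance: float
    distance: float               # corrected substitutions/site
    rate: float
    age_my: float
    model: str
    n_sites: int


def _pairwise_counts(a: str, b: str) -> tuple[int, int, int]:
    """(differences, transitions, ungapped columns) between two LTRs.

    Equal-length LTRs are compared position by position: a minimum-edit
    alignment would occasionally trade clustered substitutions for gap
    pairs and deflate the p-distance.  Unequal lengths go through a
    global affine-gap alignment and only its ungapped columns count.
    """
    if len(a) == len(b):
        ca, cb = dna.encode(a), dna.encode(b)
    else:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -8.0
        aligner.extend_gap_score = -2.0
        aln = aligner.align(a, b)[0]
        cols_a, cols_b = [], []
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            cols_a.append(dna.encode(a[sa:ea]))
            cols_b.append(dna.encode(b[sb:eb]))
        ca = np.concatenate(cols_a) if cols_a else np.empty(0, np.uint8)
        cb = np.concatenate(cols_b) if cols_b else np.empty(0, np.uint8)
    diff = ca != cb
    # transitions: A<->G (codes 0,2) and C<->T (codes 1,3): same parity
    ts = diff & ((ca % 2) == (cb % 2))
    return int(diff.sum()), int(ts.sum()), int(ca.size)


def jc69_distance(p: float) -> float:
    if p >= JC_SATURATION:
        raise ValueError(f"p-distance {p:.3f} saturated under JC69")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def k2p_distance(p_ts: float, p_tv: float) -> float:
    w1 = 1.0 - 2.0 * p_ts - p_tv
    w2 = 1.0 - 2.0 * p_tv
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distances saturated under K2P")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def estimate_insertion_age(pair: LTRPair, rate: float = DEFAULT_RATE,
                           model: str = "JC69") -> AgeEstimate:
    """Date one element from its 5'/3' LTR divergence: T = d / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    diff, ts, n_sites = _pairwise_counts(pair.ltr5, pair.ltr3)
    if n_sites == 0:
        raise ValueError("LTRs do not align")
    p = diff / n_sites
    if model == "JC69":
        d = jc69_distance(p)
    elif model == "K2P":
        d = k2p_distance(ts / n_sites, (diff - ts) / n_sites)
    else:
        raise ValueError(f"unknown model {model!r}")
    age_years = d / (2.0 * rate)
    return AgeEstimate(pair.element_id, p, d, rate, age_years / 1e6,
                       model, n_sites)


def date_cohort(elements: Iterable[LTRPair], rate: float = DEFAULT_RATE,
                model: str = "JC69") -> pd.DataFrame:
    rows = []
    for e in elements:
        est = estimate_insertion_age(e, rate=rate, model=model)
        rows.append({"element_id": e.element_id, "family_id": e.family_id,
                     "chrom_class": e.chrom_class, "p_distance": est.p_distance,
                     "distance": est.distance, "age_my": est.age_my,
                     "true_age_my": e.true_age_my})
    return pd.DataFrame(rows)


def summarize_ages(ages: pd.DataFrame, percentile_cut: float = 99.0
                   ) -> pd.DataFrame:
    """Per-family age summaries with A-vs-B medians side by side.

    Elements above the ``percentile_cut`` age percentile (cohort-wide) are
    excluded from the summaries.
    """
    if ages.empty:
        raise ValueError("no age estimates")
    cut = np.percentile(ages["age_my"], percentile_cut)
    kept = ages[ages["age_my"] <= cut]
    rows = []
    for fam, grp in ages.groupby("family_id"):
        g = kept[kept["family_id"] == fam]
        if g.empty:
            rows.append({"family_id": fam, "n": 0, "median_age_my": np.nan,
                         "q25": np.nan, "q75": np.nan,
                         "median_a": np.nan, "median_b": np.nan})
            continue
        a = g.loc[g["chrom_class"] == "A", "age_my"]
        b = g.loc[g["chrom_class"] == "B", "age_my"]
        rows.append({
            "family_id": fam, "n": len(g),
            "median_age_my": float(g["age_my"].median()),
            "q25": float(g["age_my"].quantile(0.25)),
            "q75": float(g["age_my"].quantile(0.75)),
            "median_a": float(a.median()) if len(a) else np.nan,
            "median_b": float(b.median()) if len(b) else np.nan,
        })
    return pd.DataFrame(rows)
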