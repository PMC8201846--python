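"""Coding-sequence generation and codon-aware evolution.

The mutation process proposes substitutions site by site; synonymous
proposals are always accepted, nonsynonymous proposals are accepted with a
configurable probability (1.0 = neutral evolution, <1 = purifying
selection), and proposals creating internal stop codons are always
rejected.  Relaxed selection on supernumerary-chromosome gene copies is
modelled by multiplying the nonsynonymous acceptance probability.
"""
from __future__ import annotations

import numpy as np

from .. import dna

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}


def codon_table() -> dict[str, str]:
    """Standard genetic code, codon -> amino acid ('*' for stop)."""
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


SENSE_CODONS: list[str] = []


def sense_codons() -> list[str]:
    if not SENSE_CODONS:
        SENSE_CODONS.extend(sorted(c for c in codon_table() if codon_table()[c] != "*"))
    return SENSE_CODONS


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = sense_codons()
    idx = rng.integers(0, len(codons), n_codons)
    return "".join(codons[i] for i in idx)


def evolve_cds(cds: str, branch_length: float, nonsyn_accept: float,
               rng: np.random.Generator) -> str:
    """Evolve a CDS along a branch of ``branch_length`` proposed subs/site.

    ``nonsyn_accept`` is the probability that a proposed nonsynonymous
    substitution fixes; synonymous proposals always fix; proposals creating
    a stop codon never fix.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    table = codon_table()
    seq = list(cds)
    hits = np.flatnonzero(rng.random(len(seq)) < branch_length)
    shifts = rng.integers(1, 4, hits.size)
    accept_draw = rng.random(hits.size)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"
    for pos, shift, u in zip(hits, shifts, accept_draw):
        ci = pos // 3
        codon = "".join(seq[3 * ci: 3 * ci + 3])
        new_base = bases[(order[seq[pos]] + shift) % 4]
        new_codon = codon[: pos % 3] + new_base + codon[pos % 3 + 1:]
        if table[new_codon] == "*":
            continue
        if table[new_codon] != table[codon] and u >= nonsyn_accept:
            continue
        seq[pos] = new_base
    return "".join(seq)


def make_neutral_pairs(n: int = 100, n_codons: int = 300,
                       branch_length: float = 0.075, seed: int = 0
                       ) -> list[tuple[str, str]]:
    """Pairs of CDS evolved neutrally from a common ancestor (one per pair).

    The default divergence (0.075 proposals/site per branch) keeps enough
    synonymous substitutions per pair that the ratio estimate is not
    dominated by small-count noise in its denominator, while staying far
    from saturation.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        anc = random_cds(rng, n_codons)
        a = evolve_cds(anc, branch_length, 1.0, rng)
        b = evolve_cds(anc, branch_length, 1.0, rng)
        pairs.append((a, b))
    return pairs


def make_relaxed_triples(n: int = 100, n_codons: int = 300,
                         branch_length: float = 0.05, outgroup_branch: float = 0.15,
                         nonsyn_accept: float = 0.2, relaxed_multiplier: float = 2.0,
                         seed: int = 0) -> list[dict[str, str]]:
    """(B, A, outgroup) CDS triples with relaxed purifying selection on B.

    The A copy and the outgroup evolve under the same purifying acceptance;
    the B copy evolves with ``relaxed_multiplier`` times that acceptance,
    planting the relaxed-selection contrast the comparison must recover.
    """
    rng = np.random.default_rng(seed)
    relaxed = min(nonsyn_accept * relaxed_multiplier, 1.0)
    triples = []
    for _ in range(n):
        anc = random_cds(rng, n_codons)
        triples.append({
            "outgroup": evolve_cds(anc, outgroup_branch, nonsyn_accept, rng),
            "a": evolve_cds(anc, branch_length, nonsyn_accept, rng),
            "b": evolve_cds(anc, branch_length, relaxed, rng),
        })
    return triples
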