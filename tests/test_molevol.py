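"""LTR dating, family clustering, codon alignment and NG86 Ka/Ks."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bchrom import dna
from bchrom.molevol import (
    align_codon_pair,
    cluster_ltr_families,
    compute_kaks,
    estimate_insertion_age,
    selection_comparison,
)
from bchrom.molevol.kaks import (
    _codon_path_substitutions,
    _codon_site_fractions,
    kaks_for_pair,
)
from bchrom.molevol.ltr import jc69_distance, k2p_distance, date_cohort
from bchrom.simulate import make_ltr_cohort, make_relaxed_triples
from bchrom.simulate.coding import codon_table, random_cds, sense_codons
from bchrom.simulate.ltr import LTRPair


class TestInsertionAge:
    def test_identical_ltrs_age_zero(self):
        pair = LTRPair("e", "f", "ACGT" * 100, "ACGT" * 100)
        est = estimate_insertion_age(pair)
        assert est.age_my == 0.0

    def test_jc69_closed_form(self):
        # p = 0.10 gives d = -(3/4) ln(1 - 4*0.10/3) ~ 0.10733;
        # at r = 1.3e-8/site/year the age is ~4.13 My
        assert jc69_distance(0.10) == pytest.approx(0.1073256, abs=1e-6)
        n = 1000
        ltr5 = "A" * n
        ltr3 = "C" * 100 + "A" * 900          # p = 0.10 exactly
        est = estimate_insertion_age(LTRPair("e", "f", ltr5, ltr3),
                                     rate=1.3e-8)
        assert est.age_my == pytest.approx(4.128, abs=0.01)

    def test_saturation_raises(self):
        pair = LTRPair("e", "f", "A" * 100, "C" * 100)
        with pytest.raises(ValueError):
            estimate_insertion_age(pair)

    def test_jc69_inversion_consistency(self):
        for p in (0.01, 0.05, 0.2, 0.5):
            d = jc69_distance(p)
            p_back = 0.75 * (1 - math.exp(-4 * d / 3))
            assert abs(p_back - p) < 1e-9

    def test_k2p_reduces_to_jc_under_even_rates(self):
        # with transitions at a third of differences, K2P ~ JC69
        p = 0.09
        d_k2p = k2p_distance(p / 3, 2 * p / 3)
        assert d_k2p == pytest.approx(jc69_distance(p), rel=0.02)

    def test_estimator_unbiased_in_simulation(self):
        cohort = make_ltr_cohort(n=300, fixed_divergence=0.05, seed=44)
        ages = date_cohort(cohort)
        rel = ((ages["age_my"] - ages["true_age_my"])
               / ages["true_age_my"]).mean()
        assert abs(rel) < 0.05


def brute_force_components(elements, threshold):
    """Independent clustering oracle via networkx connected components."""
    import networkx as nx

    from bchrom.molevol.ltr import pairwise_ltr_identity

    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            if pairwise_ltr_identity(elements[i].ltr5, elements[j].ltr5) \
                    >= threshold:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestClustering:
    def test_single_family_low_divergence(self):
        cohort = make_ltr_cohort(n=15, n_families=1, ltr_len=300, seed=45)
        mem, fam = cluster_ltr_families(cohort)
        assert fam.shape[0] == 1
        assert bool(fam["included"].iloc[0])

    def test_two_templates_two_families(self):
        cohort = make_ltr_cohort(n=24, n_families=2, ltr_len=300, seed=46)
        mem, fam = cluster_ltr_families(cohort, min_members=10)
        assert fam.shape[0] == 2

    def test_matches_connected_components_oracle(self, rng):
        for trial in range(5):
            cohort = make_ltr_cohort(n=12, n_families=3, ltr_len=200,
                                     seed=100 + trial)
            mem, _ = cluster_ltr_families(cohort)
            got = {frozenset(np.flatnonzero(mem["cluster"] == c))
                   for c in mem["cluster"].unique()}
            assert got == brute_force_components(cohort, 80.0)


class TestCodonAlignment:
    def test_identical_cds_gapless(self, rng):
        cds = random_cds(rng, 40)
        a, b = align_codon_pair(cds, cds)
        assert a == b == cds

    def test_inserted_codon_single_triplet_gap(self, rng):
        cds = random_cds(rng, 40)
        longer = cds[:60] + "GCT" + cds[60:]
        a, b = align_codon_pair(longer, cds)
        assert a.replace("-", "") == longer
        assert b.count("-") == 3
        i = b.index("-")
        assert b[i: i + 3] == "---" and i % 3 == 0

    def test_internal_stop_rejected(self, rng):
        cds = random_cds(rng, 30)
        broken = cds[:30] + "TAA" + cds[33:]
        with pytest.raises(ValueError, match="cds_a"):
            align_codon_pair(broken, cds)

    def test_matches_independent_codon_dp_score(self, rng):
        # Gotoh affine DP over codons, written independently, must agree
        # with the back-threaded protein alignment's score on small inputs
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        table = codon_table()

        def oracle_score(p1, p2, open_=-11.0, ext=-1.0):
            n, m = len(p1), len(p2)
            NEG = -1e9
            M = np.full((n + 1, m + 1), NEG)
            X = np.full((n + 1, m + 1), NEG)   # gap in p2
            Y = np.full((n + 1, m + 1), NEG)
            M[0, 0] = 0.0
            for i in range(1, n + 1):
                X[i, 0] = open_ + (i - 1) * ext
            for j in range(1, m + 1):
                Y[0, j] = open_ + (j - 1) * ext
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[p1[i - 1], p2[j - 1]]
                    M[i, j] = max(M[i-1, j-1], X[i-1, j-1], Y[i-1, j-1]) + s
                    X[i, j] = max(M[i-1, j] + open_, X[i-1, j] + ext,
                                  Y[i-1, j] + open_)
                    Y[i, j] = max(M[i, j-1] + open_, Y[i, j-1] + ext,
                                  X[i, j-1] + open_)
            return max(M[n, m], X[n, m], Y[n, m])

        def alignment_score(a, b):
            score = 0.0
            in_gap = None
            for i in range(0, len(a), 3):
                ca, cb = a[i:i+3], b[i:i+3]
                if ca == "---" or cb == "---":
                    gap_side = "a" if ca == "---" else "b"
                    score += -1.0 if in_gap == gap_side else -11.0
                    in_gap = gap_side
                else:
                    score += blosum[table[ca], table[cb]]
                    in_gap = None
            return score

        for trial in range(10):
            cds1 = random_cds(rng, 20)
            cds2 = random_cds(rng, 18)
            a, b = align_codon_pair(cds1, cds2)
            p1 = "".join(table[cds1[i:i+3]] for i in range(0, 60, 3))
            p2 = "".join(table[cds2[i:i+3]] for i in range(0, 54, 3))
            assert alignment_score(a, b) == pytest.approx(oracle_score(p1, p2))


def oracle_path_counts(c1, c2):
    """Independent recursive path enumeration for NG86 substitutions."""
    table = codon_table()

    def recurse(cur, remaining):
        if not remaining:
            return [(0.0, 0.0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                continue
            step = (1.0, 0.0) if table[nxt] == table[cur] else (0.0, 1.0)
            for s, n in recurse(nxt, [p for p in remaining if p != pos]):
                out.append((step[0] + s, step[1] + n))
        return out

    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = recurse(c1, diff)
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestNG86:
    def test_identical_sequences(self, rng):
        cds = random_cds(rng, 50)
        r = compute_kaks(cds, cds)
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_single_synonymous_change(self):
        c1 = "TTT" * 100
        c2 = "TTC" + "TTT" * 99
        r = compute_kaks(c1, c2)
        assert r.nd == 0.0 and r.ka == 0.0
        assert r.ks > 0 and r.ratio == 0.0

    def test_sites_sum_invariant(self, rng):
        for _ in range(20):
            cds = random_cds(rng, 30)
            r = compute_kaks(cds, cds)
            assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons)

    def test_site_fractions_serine_vs_methionine(self):
        # ATG (Met) has no synonymous changes; CTT (Leu) has all third-
        # position changes synonymous
        assert _codon_site_fractions("ATG")[0] == pytest.approx(0.0)
        assert _codon_site_fractions("CTT")[0] >= 1.0

    def test_path_counts_match_enumeration_oracle(self):
        codons = sense_codons()
        rng = np.random.default_rng(47)
        checked = 0
        for _ in range(400):
            c1 = codons[int(rng.integers(len(codons)))]
            c2 = codons[int(rng.integers(len(codons)))]
            expected = oracle_path_counts(c1, c2)
            got = _codon_path_substitutions(c1, c2)
            if expected is not None:
                assert got == pytest.approx(expected)
                checked += 1
        assert checked > 300

    def test_two_substitution_pairs_exhaustive(self):
        codons = sense_codons()
        for c1, c2 in itertools.product(codons, repeat=2):
            if sum(a != b for a, b in zip(c1, c2)) != 2:
                continue
            expected = oracle_path_counts(c1, c2)
            if expected is None:
                continue
            s, n = _codon_path_substitutions(c1, c2)
            assert (s, n) == pytest.approx(expected)
            assert s + n == pytest.approx(2.0)


class TestSelectionComparison:
    def test_null_same_constraint(self):
        triples = make_relaxed_triples(n=50, relaxed_multiplier=1.0, seed=48)
        _, summary, p = selection_comparison(triples)
        assert p > 0.05

    def test_relaxed_contrast_direction(self):
        triples = make_relaxed_triples(n=60, seed=49)
        _, summary, p = selection_comparison(triples)
        assert summary["median_b_vs_a"].iloc[0] > summary["median_a_vs_out"].iloc[0]
        assert p < 0.01


class TestSummarizeAges:
    def test_single_element_median(self):
        from bchrom.molevol import summarize_ages
        import pandas as pd
        ages = pd.DataFrame({"element_id": ["e"], "family_id": ["f"],
                             "chrom_class": ["B"], "age_my": [1.5],
                             "true_age_my": [1.4]})
        s = summarize_ages(ages)
        assert s["median_age_my"].iloc[0] == 1.5

    def test_percentile_cut_excludes_oldest(self):
        from bchrom.molevol import summarize_ages
        import pandas as pd
        ages = pd.DataFrame({
            "element_id": [f"e{i}" for i in range(100)],
            "family_id": "f", "chrom_class": "B",
            "age_my": list(range(99)) + [10_000.0],
        })
        s = summarize_ages(ages, percentile_cut=99.0)
        assert s["n"].iloc[0] == 99          # the outlier is cut
        assert s["median_age_my"].iloc[0] == 49.0

    def test_shared_history_pattern(self):
        # A and B members drawn from one age distribution: per-family
        # medians agree within the family IQR
        from bchrom.molevol import summarize_ages
        from bchrom.molevol.ltr import date_cohort
        from bchrom.simulate import make_ltr_cohort
        cohort = make_ltr_cohort(n=240, n_families=4, seed=55)
        s = summarize_ages(date_cohort(cohort))
        gap = (s["median_a"] - s["median_b"]).abs()
        iqr = (s["q75"] - s["q25"]).clip(lower=1e-9)
        assert (gap <= iqr).all()
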