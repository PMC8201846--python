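"""Monomer scanning, pair merging, midpoint profiles and identity stats."""
import numpy as np
import pandas as pd
import pytest

from bchrom import dna
from bchrom.reads import PairedReads, ReadSet
from bchrom.repeatscan import (
    MidpointProfile,
    call_peaks,
    flatness_test,
    identity_stats,
    merge_read_pairs,
    midpoint_counts,
    midpoint_profile,
    scan_monomers,
)
from bchrom.simulate import simulate_midpoint_reads


@pytest.fixture(scope="module")
def monomer():
    return dna.random_dna(np.random.default_rng(41), 150)


class TestScanMonomers:
    def test_exact_tandem_copies(self, monomer):
        hits = scan_monomers(monomer * 5, monomer)
        assert len(hits) == 5
        assert all(h.identity == 100.0 for h in hits)
        spans = sorted((h.start, h.end) for h in hits)
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))  # abutting

    def test_three_substitutions_identity(self, monomer):
        mutated = list(monomer)
        for pos in (10, 70, 140):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        hits = scan_monomers("".join(mutated), monomer)
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(100 * 147 / 150, abs=0.2)

    def test_reverse_complement_array_on_minus_strand(self, monomer):
        hits = scan_monomers(dna.revcomp(monomer * 4), monomer)
        assert len(hits) == 4
        assert all(h.strand == "-" for h in hits)

    def test_mutated_array_copy_count(self, monomer, rng):
        arr = "".join(dna.point_mutate(monomer, 0.05, rng) for _ in range(8))
        hits = scan_monomers(arr, monomer)
        assert len(hits) == 8
        assert all(h.identity >= 80 for h in hits)


class TestMergePairs:
    def _pair(self, fragment, read_len):
        r1 = ReadSet.from_strings([fragment[:read_len]])
        r2 = ReadSet.from_strings([dna.revcomp(fragment[-read_len:])])
        return PairedReads(r1, r2)

    def test_exact_overlap_merge(self, rng):
        frag = dna.random_dna(rng, 100)      # 75 + 75 - 50 overlap
        merged = merge_read_pairs(self._pair(frag, 75))
        assert merged.n == 1
        assert merged.sequence(0) == frag

    def test_disjoint_mates_dropped(self, rng):
        r1 = ReadSet.from_strings([dna.random_dna(rng, 75)])
        r2 = ReadSet.from_strings([dna.random_dna(rng, 75)])
        merged = merge_read_pairs(PairedReads(r1, r2))
        assert merged.n == 0

    def test_min_overlap_boundary(self, rng):
        frag = dna.random_dna(rng, 2 * 75 - 10)   # exactly 10 bp overlap
        merged = merge_read_pairs(self._pair(frag, 75), min_overlap=10)
        assert merged.n == 1
        assert merged.sequence(0) == frag


class TestMidpoints:
    def test_offset_arithmetic(self, monomer):
        # a fragment at [10, 60) on the trimer has midpoint 35
        frag = (monomer * 3)[10:60]
        counts = midpoint_counts(ReadSet.from_strings([frag]), monomer)
        assert counts[35] == 1 and counts.sum() == 1

    def test_placement_invariance_across_copies(self, monomer):
        # the same fragment cut from different tandem copies folds to the
        # same offset
        offs = []
        for copy in range(3):
            frag = (monomer * 5)[copy * 150 + 20: copy * 150 + 140]
            counts = midpoint_counts(ReadSet.from_strings([frag]), monomer)
            offs.append(int(np.flatnonzero(counts)[0]))
        assert len(set(offs)) == 1

    def test_mass_conservation(self, monomer, rng):
        frags = [(monomer * 4)[s: s + 100]
                 for s in rng.integers(0, 300, size=50)]
        counts = midpoint_counts(ReadSet.from_strings(frags), monomer)
        assert counts.sum() == 50

    def test_overlong_fragment_skipped(self, monomer):
        counts = midpoint_counts(ReadSet.from_strings([monomer * 4]), monomer,
                                 copies=3)
        assert counts.sum() == 0


class TestPeaks:
    def test_flat_profile_no_peaks(self, monomer):
        prof = MidpointProfile(150, np.full(150, 100), np.full(150, 100),
                               15000, 15000)
        peaks = call_peaks(prof)
        assert len(peaks) == 0

    def test_single_planted_dyad(self, monomer):
        chip, inp = simulate_midpoint_reads(monomer, 40, [70], n_pairs=3000,
                                            sigma=5.0, seed=42)
        prof = midpoint_profile(merge_read_pairs(chip), merge_read_pairs(inp),
                                monomer)
        peaks = call_peaks(prof)
        assert len(peaks) >= 1
        assert abs(int(peaks["offset"].iloc[0]) - 70) <= 3

    def test_uniform_input_flat(self, monomer):
        _, inp = simulate_midpoint_reads(monomer, 40, [70], n_pairs=10_000,
                                         seed=43)
        prof_counts = midpoint_counts(merge_read_pairs(inp), monomer)
        assert flatness_test(prof_counts) > 0.01


class TestIdentityStats:
    def test_identical_groups(self):
        a = np.array([95.0, 95.0, 96.0, 94.0])
        summary, tests = identity_stats({"x": a, "y": a.copy()})
        assert tests["t"].iloc[0] == pytest.approx(0.0)
        assert tests["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        a = rng.normal(95, 1, 200)
        b = rng.normal(85, 1, 200)
        _, tests = identity_stats({"hi": a, "lo": b})
        assert tests["p"].iloc[0] < 1e-3

    def test_identity_definition(self):
        # m mismatches over length L gives 100 * (L - m) / L
        read = "A" * 50
        ref = "A" * 48 + "CC"
        from bchrom.repeatscan import read_identity
        assert read_identity(read, ref) == pytest.approx(100 * 48 / 50)

    def test_zero_variance_flagged(self):
        summary, tests = identity_stats({"x": [90.0, 90.0], "y": [80.0, 80.0]})
        assert bool(tests["zero_variance"].iloc[0])
        assert tests["p"].iloc[0] == 0.0
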