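"""Deficiency-mapping operations: trimming, subtraction, windows, calls,
ordering, building and dosage."""
import numpy as np
import pandas as pd
import pytest

from bchrom import dna
from bchrom.defmap import (
    PresenceMatrix,
    call_presence,
    coverage_windows,
    dosage_profile,
    map_unique_to_scaffolds,
    order_scaffolds,
    orient_and_build,
    preprocess_reads,
    read_agp,
    subtract_host_reads,
    verify_profile,
    write_agp,
)
from bchrom.defmap.coverage import WindowCoverage
from bchrom.defmap.order import OrderingConflict
from bchrom.mapping import ReferenceIndex
from bchrom.reads import ReadSet


class TestPreprocess:
    @pytest.mark.parametrize("raw,expected", [
        ("ACGTACGT" + "G" * 30, "ACGTACGT"),                  # poly-G tail
        ("ACGTACGTACGTACGTACGTACGTACGTAC" + "NNN", "ACGTACGTACGTACGTACGTACGTACGTAC"),
        ("ACGTACGTGGGACGTACGTACGTACGTACGTA", "ACGTACGTGGGACGTACGTACGTACGTACGTA"),
        ("ACGTACGTACGTACGTACGTACGTACGTACTNGNGGNN",
         "ACGTACGTACGTACGTACGTACGTACGTACT"),                  # mixed N/G run
    ])
    def test_three_prime_trimming(self, raw, expected):
        out = preprocess_reads(ReadSet.from_strings([raw + "A" * 0]),
                               min_keep=4)
        assert out.sequence(0) == expected

    def test_short_tail_untouched(self):
        # a 2-base tail is below trim_min and stays
        raw = "ACGTACGTACGTACGTACGTACGTACGTGG"
        out = preprocess_reads(ReadSet.from_strings([raw]), min_keep=4)
        assert out.sequence(0) == raw

    def test_short_reads_dropped(self):
        out = preprocess_reads(ReadSet.from_strings(
            ["ACGT" + "G" * 40, "ACGTACGTACGTACGTACGTACGTACGTACGT"]))
        assert out.n == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_reads(ReadSet.from_strings([]))


@pytest.fixture(scope="module")
def host():
    rng = np.random.default_rng(31)
    a = {"A1": dna.random_dna(rng, 4000), "A2": dna.random_dna(rng, 3000)}
    return a, rng


class TestSubtract:
    def test_unique_host_read_removed(self, host):
        a, _ = host
        read = a["A1"][100:175]
        out = subtract_host_reads(ReadSet.from_strings([read]), a)
        assert out.n == 0

    def test_foreign_read_retained(self, host, library):
        a, _ = host
        read = (library.monomers["b_specific"] * 2)[:75]
        out = subtract_host_reads(ReadSet.from_strings([read]), a)
        assert out.n == 1

    def test_two_exact_loci_retained(self, host):
        rng = np.random.default_rng(32)
        core = dna.random_dna(rng, 200)
        dup = {"c": core + dna.random_dna(rng, 500) + core}
        read = core[50:125]
        out = subtract_host_reads(ReadSet.from_strings([read]), dup)
        assert out.n == 1   # two placements: not unique, kept

    def test_two_mismatch_read_removed(self, host):
        a, _ = host
        rng = np.random.default_rng(33)
        read = list(a["A2"][500:575])
        read[10] = "A" if read[10] != "A" else "C"
        read[60] = "G" if read[60] != "G" else "T"
        out = subtract_host_reads(ReadSet.from_strings(["".join(read)]), a)
        assert out.n == 0


class TestMapUnique:
    def test_matches_brute_force_on_fixture(self, host):
        from bchrom.mapping import brute_force_alignments

        a, _ = host
        rng = np.random.default_rng(34)
        scaffolds = {"s1": dna.random_dna(rng, 2000),
                     "s2": dna.random_dna(rng, 1500)}
        reads = []
        for _ in range(50):
            src = scaffolds["s1" if rng.random() < 0.5 else "s2"]
            s = int(rng.integers(0, len(src) - 75))
            q = src[s: s + 75]
            if rng.random() < 0.3:
                q = dna.revcomp(q)
            reads.append(q)
        placements = map_unique_to_scaffolds(ReadSet.from_strings(reads),
                                             scaffolds)
        by_read = placements.set_index("read_index")
        for i, q in enumerate(reads):
            bf = [p for p in brute_force_alignments(q, scaffolds, 0)]
            if len(bf) == 1:
                row = by_read.loc[i]
                assert (row["scaffold"], row["start"], row["strand"]) == bf[0]
            else:
                assert i not in by_read.index


class TestCoverageWindows:
    def test_no_placements_all_zero(self):
        empty = pd.DataFrame(columns=["read_index", "scaffold", "start", "strand"])
        cov = coverage_windows(empty, {"s": 5000})
        assert cov["s"].counts.sum() == 0

    def test_out_of_bounds_placement_rejected(self):
        bad = pd.DataFrame({"read_index": [0], "scaffold": ["s"],
                            "start": [6000], "strand": ["+"]})
        with pytest.raises(ValueError):
            coverage_windows(bad, {"s": 5000})

    def test_window_counts(self):
        pl = pd.DataFrame({"read_index": range(5), "scaffold": "s",
                           "start": [0, 500, 999, 1000, 2500], "strand": "+"})
        cov = coverage_windows(pl, {"s": 3000})
        assert list(cov["s"].counts) == [3, 1, 1]

    def test_repetitive_window_flagged(self):
        mask = np.zeros(3000, dtype=bool)
        mask[1000:1600] = True    # 60% of window 1
        empty = pd.DataFrame(columns=["read_index", "scaffold", "start", "strand"])
        cov = coverage_windows(empty, {"s": 3000}, repeat_mask={"s": mask})
        assert list(cov["s"].nonrepetitive) == [True, False, True]


def _cov(counts, informative=None):
    counts = np.asarray(counts)
    if informative is None:
        informative = np.ones(counts.size, dtype=bool)
    return WindowCoverage("s", 1000, counts, np.asarray(informative))


class TestCallPresence:
    def test_full_and_absent(self):
        cov = {"L1": {"s": _cov([5, 6, 7, 8])}, "L2": {"s": _cov([0, 0, 0, 0])}}
        m = call_presence(cov)
        assert m.calls.at["s", "L1"] == "present"
        assert m.calls.at["s", "L2"] == "absent"

    def test_partial_at_half_coverage(self):
        m = call_presence({"L": {"s": _cov([8, 7, 0, 0])}})
        assert m.calls.at["s", "L"] == "partial"

    def test_uninformative_scaffold(self):
        m = call_presence({"L": {"s": _cov([0, 0], [False, False])}})
        assert m.calls.at["s", "L"] == "uninformative"


def _matrix(calls_by_scaffold, lines):
    calls = pd.DataFrame(calls_by_scaffold, index=lines).T
    frac = calls.map({"present": 1.0, "absent": 0.0, "partial": 0.5}.get)
    return PresenceMatrix(frac.astype(float), calls)


class TestOrdering:
    def test_unique_chain_consistent_order(self):
        # lines retain [0,30k) and [0,60k); scaffolds at [5k,15k), [35k,45k),
        # [65k,75k) give signatures (P,P), (A,P), (A,A): s1 < s2 < s3.
        m = _matrix({"s1": ["present", "present", "present"],
                     "s2": ["absent", "present", "present"],
                     "s3": ["absent", "absent", "present"]},
                    ["t30", "t60", "ctrl"])
        layout = order_scaffolds(m, ["t30", "t60"], control_line="ctrl")
        assert layout.scaffold_order() == ["s1", "s2", "s3"]
        # brute force: this is the unique chain-consistent order
        import itertools
        valid = []
        sig = {"s1": (1, 1), "s2": (0, 1), "s3": (0, 0)}
        for perm in itertools.permutations(sig):
            ok = all(tuple(sig[a][i] for a in perm)
                     == tuple(sorted((sig[a][i] for a in perm), reverse=True))
                     for i in range(2))
            if ok:
                valid.append(list(perm))
        assert valid == [["s1", "s2", "s3"]]

    def test_identical_signatures_share_bin(self):
        m = _matrix({"s1": ["present", "present"],
                     "s2": ["present", "present"]}, ["t", "ctrl"])
        layout = order_scaffolds(m, ["t"], control_line="ctrl")
        assert layout.bins == [["s1", "s2"]]
        assert layout.unresolved_bins == [0]

    def test_chain_violation_raises(self):
        # the chain (t30 before t60) is fixed by the other scaffolds'
        # footprints; s1 present in the smaller retention but absent in the
        # larger violates consecutive-ones and must be surfaced
        m = _matrix({"s0": ["present", "present", "present"],
                     "s2": ["absent", "present", "present"],
                     "s3": ["absent", "present", "present"],
                     "s1": ["present", "absent", "present"]},
                    ["t30", "t60", "ctrl"])
        with pytest.raises(OrderingConflict) as err:
            order_scaffolds(m, ["t30", "t60"], control_line="ctrl")
        assert len(err.value.conflicts) == 1
        # --force degrades the failure to a report
        layout = order_scaffolds(m, ["t30", "t60"], control_line="ctrl",
                                 force=True)
        assert "s0" in layout.scaffold_order()

    def test_partial_anchors_between_bins(self):
        m = _matrix({"s1": ["present", "present"],
                     "sp": ["partial", "present"],
                     "s3": ["absent", "present"]}, ["t", "ctrl"])
        layout = order_scaffolds(m, ["t"], control_line="ctrl")
        assert layout.scaffold_order() == ["s1", "sp", "s3"]


class TestBuildAndAgp:
    def test_gap_arithmetic(self, rng):
        scaffolds = {"a": dna.random_dna(rng, 1000), "b": dna.random_dna(rng, 1000)}
        m = _matrix({"a": ["present", "present"], "b": ["absent", "present"]},
                    ["t", "ctrl"])
        layout = order_scaffolds(m, ["t"], control_line="ctrl",
                                 scaffold_lengths={k: 1000 for k in scaffolds})
        cov = {"t": {"a": _cov([9, 9]), "b": _cov([0, 0])},
               "ctrl": {"a": _cov([9, 9]), "b": _cov([9, 9])}}
        pseudo, layout = orient_and_build(layout, scaffolds, m, cov, gap_len=100)
        assert len(pseudo) == 2100
        assert pseudo[1000:1100] == "N" * 100

    def test_agp_roundtrip(self, rng, tmp_path):
        scaffolds = {"a": dna.random_dna(rng, 1200), "b": dna.random_dna(rng, 800)}
        m = _matrix({"a": ["present", "present"], "b": ["absent", "present"]},
                    ["t", "ctrl"])
        layout = order_scaffolds(m, ["t"], control_line="ctrl")
        cov = {"t": {"a": _cov([9, 9]), "b": _cov([0])},
               "ctrl": {"a": _cov([9, 9]), "b": _cov([9])}}
        _, layout = orient_and_build(layout, scaffolds, m, cov)
        p = tmp_path / "layout.agp"
        write_agp(layout, p)
        back = read_agp(p)
        assert [(q.scaffold, q.orientation, q.start, q.end) for q in back.placements] \
            == [(q.scaffold, q.orientation, q.start, q.end) for q in layout.placements]
        assert back.gap_len == layout.gap_len
        # writing the parsed layout again is byte-identical
        p2 = tmp_path / "layout2.agp"
        write_agp(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_orientation_recovered_from_half_coverage(self, rng):
        scaffolds = {"a": dna.random_dna(rng, 4000)}
        m = _matrix({"a": ["partial", "present"]}, ["t", "ctrl"])
        layout = order_scaffolds(m, ["t"], control_line="ctrl")
        # covered half is the second half: stored scaffold is flipped
        cov = {"t": {"a": _cov([0, 0, 8, 9])},
               "ctrl": {"a": _cov([9, 9, 9, 9])}}
        _, layout = orient_and_build(layout, scaffolds, m, cov)
        assert layout.orientation_of("a") == "-"


class TestVerifyProfile:
    def test_contiguous_prefix_passes(self):
        cov = {"t": _cov([5, 6, 7, 0, 0, 0]), "ctrl": _cov([5] * 6)}
        rep = verify_profile(cov)
        assert rep["contiguous"].all()

    def test_shuffled_coverage_fails(self):
        rep = verify_profile({"t": _cov([5, 0, 0, 0, 6, 7, 0, 5, 0, 6, 0, 5])})
        assert not rep["contiguous"].iloc[0]


class TestDosage:
    def test_identity_ratio_one(self, rng):
        ref = {"A1": dna.random_dna(rng, 20_000)}
        reads = []
        for _ in range(2000):
            s = int(rng.integers(0, len(ref["A1"]) - 75))
            reads.append(ref["A1"][s: s + 75])
        lib = ReadSet.from_strings(reads)
        regions = pd.DataFrame({
            "chrom": "A1", "start": range(0, 18_000, 2000),
            "end": range(1000, 19_000, 2000),
            "name": [f"g{i}" for i in range(9)]})
        prof = dosage_profile(regions, {"ctl": lib, "test": lib}, "ctl", ref)
        assert np.allclose(prof.ratios["ratio"], 1.0)
        assert (prof.segment_ratios["call"] == "neutral").all()


def test_bedgraph_writer(tmp_path):
    from bchrom.defmap.coverage import write_bedgraph
    cov = {"s": _cov([3, 0, 7], [True, False, True])}
    p = tmp_path / "x.bedgraph"
    write_bedgraph(cov, p)
    lines = p.read_text().strip().split("\n")
    assert lines == ["s\t0\t1000\t3", "s\t2000\t3000\t7"]
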