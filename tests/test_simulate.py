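"""Generator properties: determinism, truth-table consistency, planted signals."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from bchrom import dna
from bchrom.reads import write_fastq
from bchrom.simulate import (
    default_blueprint,
    fragment_scaffolds,
    make_genome,
    make_line_panel,
    make_repeat_library,
    simulate_midpoint_reads,
    simulate_reads,
)


class TestRepeatLibrary:
    def test_deterministic_for_seed(self):
        a = make_repeat_library(seed=1)
        b = make_repeat_library(seed=1)
        assert a.monomers == b.monomers
        assert [(t.internal, t.ltr) for t in a.te_templates] == \
               [(t.internal, t.ltr) for t in b.te_templates]

    def test_b_specific_knob_identity_band(self, library):
        ident = dna.global_identity(library.monomers["b_specific"],
                                    library.monomers["knob"])
        assert 50.0 <= ident < 80.0

    def test_knob_monomer_length_override(self):
        lib = make_repeat_library(seed=2, monomer_lengths={"knob": 180})
        assert len(lib.monomers["knob"]) == 180

    def test_short_monomer_rejected(self):
        with pytest.raises(ValueError):
            make_repeat_library(seed=1, monomer_lengths={"knob": 10})


class TestGenome:
    def test_no_transposed_genes(self, library):
        g = make_genome(default_blueprint(200_000), library, seed=3,
                        a_length=40_000, n_transposed_genes=0)
        assert (g.b_truth["type"] == "gene").sum() == 0

    def test_b_specific_only_on_b_knob_on_both(self, small_genome):
        t = small_genome.truth
        rep = t[t["type"] == "repeat"]
        b_spec = rep[rep["source_id"] == "b_specific"]
        assert set(b_spec["chrom"]) == {"chrB"}
        knob = rep[rep["source_id"] == "knob"]
        assert "chrB" in set(knob["chrom"])
        assert any(c.startswith("A") for c in knob["chrom"])

    def test_te_fraction_near_default(self):
        g = make_genome(seed=5, a_length=60_000)
        assert abs(g.te_fraction_b() - 0.60) <= 0.05

    def test_truth_intervals_in_bounds(self, small_genome):
        t = small_genome.b_truth
        assert (t["start"] >= 0).all()
        assert (t["end"] <= small_genome.b_len).all()

    def test_interval_conservation(self, small_genome):
        t = small_genome.b_truth
        for kind in ("te", "repeat", "gene"):
            sub = t[t["type"] == kind]
            assert (sub["end"] - sub["start"]).sum() <= small_genome.b_len


class TestFragmentScaffolds:
    def test_single_scaffold_is_b_up_to_strand(self, small_genome):
        sc = fragment_scaffolds(small_genome, 1, seed=4)
        seq = next(iter(sc.sequences.values()))
        b = small_genome.b_chromosome
        assert seq in (b, dna.revcomp(b))

    def test_roundtrip_reconstruction(self, small_genome):
        for seed in (1, 2, 3):
            sc = fragment_scaffolds(small_genome, 7, seed=seed)
            assert sc.reconstruct() == small_genome.b_chromosome

    def test_min_len_respected(self, small_scaffolds):
        assert all(len(s) >= 10_000 for s in small_scaffolds.sequences.values())

    def test_infeasible_partition(self, small_genome):
        with pytest.raises(ValueError):
            fragment_scaffolds(small_genome, 1000, min_len=10_000, seed=1)


class TestLinePanel:
    def test_control_retains_everything(self, small_panel, small_genome):
        ctrl = small_panel.get("B-full")
        assert ctrl.retained == [(0, small_genome.b_len)]

    def test_mini_contains_centromere(self, small_panel, small_genome):
        bc = small_genome.segment_interval("BC")
        for mini in small_panel.by_kind("mini"):
            (s, e), = mini.retained
            assert s <= bc[0] and e >= bc[1]

    def test_terminal_chain_strictly_increasing(self, small_panel):
        ends = [line.retained[0][1] for line in small_panel.by_kind("terminal")]
        assert all(b < a for b, a in zip(ends, ends[1:])) or \
               all(a < b for a, b in zip(ends, ends[1:]))

    def test_breakpoints_distinct(self, small_panel):
        bps = small_panel.breakpoints()
        assert len(bps) == len(set(bps))

    def test_tsv_roundtrip(self, small_panel, tmp_path):
        p = tmp_path / "panel.tsv"
        small_panel.to_tsv(p)
        back = type(small_panel).from_tsv(p)
        assert back.b_length == small_panel.b_length
        for a, b in zip(small_panel.lines, back.lines):
            assert (a.name, a.kind, a.retained, a.b_copies, a.a_dosage) == \
                   (b.name, b.kind, b.retained, b.b_copies, b.a_dosage)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, small_genome, small_panel):
        line = small_panel.get("B-full")
        rs = simulate_reads(small_genome, line, coverage=0.2, seed=6,
                            tail_fraction=0.0)
        hay = {c: s for c, s in small_genome.a_chromosomes}
        hay["chrB"] = small_genome.b_chromosome
        for i in range(0, rs.n, 37):
            seq = rs.sequence(i)
            row = rs.truth.iloc[i]
            src = hay[row["chrom"]][row["start"]: row["start"] + len(seq)]
            expected = src if row["strand"] == "+" else dna.revcomp(src)
            assert seq == expected

    def test_coverage_law(self, small_genome, small_panel):
        line = small_panel.get("B-full")
        rs = simulate_reads(small_genome, line, coverage=6.0, seed=7)
        total = sum(len(s) for _, s in small_genome.a_chromosomes) \
            + small_genome.b_len
        depth = rs.lengths.sum() / total
        assert abs(depth - 6.0) / 6.0 < 0.05

    def test_reads_per_kb_poisson(self, small_genome, small_panel):
        # expectation 1000 * coverage / read_len = 80 reads per kb at defaults
        line = small_panel.get("B-full")
        rs = simulate_reads(small_genome, line, coverage=6.0, read_len=75,
                            seed=8, tail_fraction=0.0)
        b_reads = rs.truth[rs.truth["chrom"] == "chrB"]
        sub = b_reads[(b_reads["start"] >= 50_000) & (b_reads["start"] < 51_000)]
        lam = 80.0
        assert abs(len(sub) - lam) < 4 * np.sqrt(lam)

    def test_deterministic_fastq_bytes(self, small_genome, small_panel, tmp_path):
        line = small_panel.get("B-full")
        paths = []
        for trial in (1, 2):
            rs = simulate_reads(small_genome, line, coverage=0.1, seed=9)
            p = tmp_path / f"reads{trial}.fastq"
            write_fastq(p, rs)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_parameter_validation(self, small_genome, small_panel):
        line = small_panel.get("B-full")
        with pytest.raises(ValueError):
            simulate_reads(small_genome, line, coverage=0.0)
        with pytest.raises(ValueError):
            simulate_reads(small_genome, line, error_rate=0.5)


class TestMidpointReads:
    def test_zero_sigma_midpoints_on_dyad(self, rng):
        monomer = dna.random_dna(rng, 150)
        chip, _ = simulate_midpoint_reads(monomer, 20, [40], n_pairs=200,
                                          sigma=0.0, seed=10)
        mids = chip.truth["midpoint"].to_numpy()
        assert np.all(mids % 150 == 40)

    def test_input_midpoints_uniform(self, rng):
        monomer = dna.random_dna(rng, 150)
        _, inp = simulate_midpoint_reads(monomer, 40, [40], n_pairs=10_000,
                                         seed=11)
        offsets = inp.truth["midpoint"].to_numpy() % 150
        counts = np.bincount(offsets, minlength=150)
        _, p = sstats.chisquare(counts)
        assert p > 0.01

    def test_bad_parameters(self, rng):
        monomer = dna.random_dna(rng, 150)
        with pytest.raises(ValueError):
            simulate_midpoint_reads(monomer, 20, [200], n_pairs=10)
        with pytest.raises(ValueError):
            simulate_midpoint_reads(monomer, 20, [40], n_pairs=0)
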