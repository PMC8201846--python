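"""Nucleosome midpoint profiling on a centromeric tandem repeat.

Simulates ChIP and input mate pairs with two major and three minor
planted dyads on a satellite array, merges the pairs, folds fragment
midpoints onto the monomer via a consensus trimer, calls enrichment
peaks, and reports dyad recovery and the flatness of the input profile.
Writes the per-offset profile and the ranked peak table.
"""
import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bchrom import dna, workflows
from bchrom.repeatscan import call_peaks, merge_read_pairs, midpoint_profile
from bchrom.simulate import simulate_midpoint_reads

SEED = 20240601
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    r = workflows.midpoint_experiment(SEED)

    s_mono, s_chip = workflows._spawn(SEED, 2)
    monomer = dna.random_dna(np.random.default_rng(s_mono), 150)
    chip, inp = simulate_midpoint_reads(
        monomer, 40, list(workflows.MIDPOINT_DYADS),
        weights=list(workflows.MIDPOINT_WEIGHTS), n_pairs=10_000,
        seed=s_chip)
    profile = midpoint_profile(merge_read_pairs(chip), merge_read_pairs(inp),
                               monomer)
    profile.to_frame().to_csv(OUT / "midpoint_profile.tsv", sep="\t",
                              index=False)
    peaks = call_peaks(profile)
    peaks.to_csv(OUT / "midpoint_peaks.tsv", sep="\t", index=False)

    print(f"planted dyads {workflows.MIDPOINT_DYADS} "
          f"(weights {workflows.MIDPOINT_WEIGHTS})")
    print(f"peaks recovered: {r['n_peaks']}, max offset error "
          f"{r['max_offset_error_bp']} bp, major/minor partition correct: "
          f"{r['major_minor_ok']}")
    print(f"input profile chi-square flatness p = "
          f"{r['input_flatness_p']:.3f} (uniform as expected)")
    (OUT / "midpoint_summary.json").write_text(json.dumps(r, indent=2) + "\n")
    print(f"tables in {OUT}/: midpoint_profile.tsv, midpoint_peaks.tsv")


if __name__ == "__main__":
    main()
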