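"""Assign scaffolds to the B chromosome by k-mer profiling.

Profiles mixed A- and B-derived scaffolds against an A-genome k-mer index
and an index of 20x B-enriched reads, classifies them, and compares the
labels with the hidden origin.  Writes the per-scaffold report TSV.
"""
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bchrom import workflows

SEED = 20240601
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    r = workflows.classification_experiment(SEED)
    print("k-mer classification against hidden scaffold origin:")
    print(f"  A-origin scaffolds mislabelled B: {r['a_scaffolds_called_b']}")
    print(f"  B-origin scaffolds labelled B:    {r['b_scaffolds_called_b']} "
          f"/ {r['b_scaffolds_informative']}")
    print(f"  repeat-only scaffolds routed separately: {r['n_repeat_only']}")
    import json
    (OUT / "classification_summary.json").write_text(
        json.dumps(r, indent=2) + "\n")
    print(f"summary written to {OUT / 'classification_summary.json'}")


if __name__ == "__main__":
    main()
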