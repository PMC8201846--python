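"""FASTA / BED / TSV readers and writers for the pipeline artifacts.

FASTA goes through Biopython; BED tables are plain pandas frames with
0-based half-open coordinates (the convention used everywhere in this
package).  AGP 2.1 IO lives next to the pseudomolecule builder in
``bchrom.defmap.build``.
"""
from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(path, table: pd.DataFrame) -> None:
    cols = [c for c in BED_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    table.columns = BED_COLUMNS[: table.shape[1]]
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)
    return table


def intervals_to_bed(intervals, chrom: str, name: str = ".") -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": chrom, "start": [s for s, _ in intervals],
         "end": [e for _, e in intervals], "name": name}
    )
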