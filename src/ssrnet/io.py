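"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a header row of sample/array IDs and a first
column of gene IDs; promoters as FASTA (gene ID as record ID); motif tables
as 2-column TSV; gene lists as one ID per line.  Writers use a fixed float
format and sorted ordering so repeated runs are byte-identical.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifPattern
from .synthetic import RatioTable

FLOAT_FMT = "%.8g"


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_ratio_table(values_path, arrays_path) -> RatioTable:
    values = read_matrix_tsv(values_path)
    arrays = pd.read_csv(arrays_path, sep="\t")
    return RatioTable(values, arrays)


def write_ratio_table(table: RatioTable, values_path, arrays_path) -> None:
    write_matrix_tsv(table.values, values_path)
    table.arrays.to_csv(arrays_path, sep="\t", index=False)


def read_promoters_fasta(path) -> dict[str, str]:
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in promoters:
            raise ValueError(f"duplicate promoter ID {record.id!r}")
        promoters[record.id] = str(record.seq).upper()
    return promoters


def write_promoters_fasta(promoters: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


def read_motif_table(path) -> list[MotifPattern]:
    df = pd.read_csv(path, sep="\t")
    return [MotifPattern(str(r["name"]), str(r["pattern"])) for _, r in df.iterrows()]


def write_motif_table(motifs: list[MotifPattern], path) -> None:
    pd.DataFrame({"name": [m.name for m in motifs],
                  "pattern": [m.pattern for m in motifs]}).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
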