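"""Readers and writers for the plain-text table dialects used throughout.

All tabular formats are TSV; sequences are FASTA via Biopython.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_guide_table(path: str | Path) -> pd.DataFrame:
    table = read_tsv(path)
    required = {"guide_id", "gene"}
    if not required <= set(table.columns):
        raise ValueError(f"guide table missing columns {sorted(required - set(table.columns))}")
    return table


def read_rpf_table(path: str | Path) -> pd.DataFrame:
    table = read_tsv(path)
    required = {"transcript", "five_prime_pos", "read_length", "count"}
    if not required <= set(table.columns):
        raise ValueError(f"RPF table missing columns {sorted(required - set(table.columns))}")
    return table


def read_isotopologue_table(path: str | Path) -> pd.DataFrame:
    table = read_tsv(path)
    if "compound" not in table.columns or "carbons" not in table.columns:
        raise ValueError("isotopologue table needs 'compound' and 'carbons' columns")
    return table


def read_protein_quant(path: str | Path) -> pd.DataFrame:
    table = read_tsv(path)
    required = {"protein", "log2_ratio"}
    if not required <= set(table.columns):
        raise ValueError(f"protein table missing columns {sorted(required - set(table.columns))}")
    return table
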