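"""Thin FASTA/TSV helpers shared across stages."""

from __future__ import annotations

from os import PathLike
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly_qc import SITE_COLUMNS


def read_fasta(path: str | PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_site_table(path: str | PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    df["is_snp"] = df["is_snp"].astype(bool)
    df["is_indel"] = df["is_indel"].astype(bool)
    return df


def write_site_table(df: pd.DataFrame, path: str | PathLike) -> None:
    out = df.copy()
    out["is_snp"] = out["is_snp"].astype(int)
    out["is_indel"] = out["is_indel"].astype(int)
    out.to_csv(path, sep="\t", index=False)
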