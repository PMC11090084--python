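"""TPM quantification and the lantern-expression filter.

TPM (transcripts per kilobase million): counts are first normalized by
transcript length, then scaled so the table sums to 1e6. The effective length
is the annotated transcript length (no fragment-length correction). The
expression screen used downstream keeps ids with TPM strictly above a
threshold (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CountRecord",
    "compute_tpm",
    "expressed_filter",
    "gene_level_tpm",
    "read_counts",
    "write_tpm",
]

logger = logging.getLogger(__name__)

MILLION = 1e6


@dataclass(frozen=True)
class CountRecord:
    transcript_id: str
    length_bp: int
    count: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.transcript_id}: length_bp must be >= 1")
        if self.count < 0:
            raise ValueError(f"{self.transcript_id}: negative count")


def compute_tpm(records: Iterable[CountRecord]) -> dict[str, float]:
    """TPM_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6.

    Returns an id -> TPM mapping in input order. An all-zero count table
    yields an all-zero table (with a warning) rather than dividing by zero.
    """
    recs = list(records)
    if not recs:
        raise ValueError("empty count table")
    rates = {r.transcript_id: r.count / r.length_bp for r in recs}
    if len(rates) != len(recs):
        raise ValueError("duplicate transcript ids in count table")
    total = sum(rates.values())
    if total == 0:
        logger.warning("all counts are zero; TPM table is all-zero")
        return {tid: 0.0 for tid in rates}
    return {tid: rate / total * MILLION for tid, rate in rates.items()}


def expressed_filter(table: Mapping[str, float], threshold: float = 10.0) -> set[str]:
    """Ids with TPM strictly greater than the threshold (TPM == 10 is out)."""
    return {tid for tid, tpm in table.items() if tpm > threshold}


def gene_level_tpm(
    table: Mapping[str, float], transcript_to_gene: Mapping[str, str]
) -> dict[str, float]:
    """Gene-level TPM as the sum of the gene's transcript TPMs."""
    out: dict[str, float] = {}
    for tid, tpm in table.items():
        gene = transcript_to_gene.get(tid, tid)
        out[gene] = out.get(gene, 0.0) + tpm
    return out


def read_counts(path: str | PathLike) -> list[CountRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "length_bp", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    return [
        CountRecord(str(r.transcript_id), int(r.length_bp), float(r.count))
        for r in df.itertuples(index=False)
    ]


def write_tpm(table: Mapping[str, float], path: str | PathLike) -> None:
    pd.DataFrame(
        {"transcript_id": list(table), "tpm": [table[t] for t in table]}
    ).to_csv(path, sep="\t", index=False)
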