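"""Assembly statistics and the read/scaffold/site filter cascade.

The cascade mirrors a standard short-read genome QC workflow: drop scaffolds
under 1 kb, remove reads within edit distance 3 of the mitochondrial genome,
keep only unique non-duplicate alignments above 92% identity, restrict to
callable sites (depth within half to twice the mean, both strands covered,
outside +-10 bp indel windows), and estimate heterozygosity as SNPs per
callable base.

Site tables are handled as pandas DataFrames with one row per position
(columns: scaffold, pos, depth, fwd_reads, rev_reads, is_snp, is_indel);
:func:`sites_to_frame` converts lists of :class:`SiteRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Scaffold",
    "AssemblyStats",
    "AlignmentSummary",
    "SiteRecord",
    "CallableMask",
    "HetEstimate",
    "scaffold_stats",
    "filter_scaffolds",
    "mito_read_filter",
    "filter_alignments",
    "callable_mask",
    "heterozygosity",
    "sites_to_frame",
]

_NT = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")

SITE_COLUMNS = ["scaffold", "pos", "depth", "fwd_reads", "rev_reads", "is_snp", "is_indel"]


@dataclass(frozen=True)
class Scaffold:
    """A named nucleotide sequence (A/C/G/T/N)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")
        letters = set(self.sequence)
        if not letters <= _NT:
            bad = "".join(sorted(letters - _NT))
            raise ValueError(f"scaffold {self.id!r}: invalid characters {bad!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    n_scaffolds: int
    n50_bp: int
    gc_percent: float


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-read mapping summary consumed from an upstream aligner."""

    read_id: str
    identity: float
    is_unique: bool
    is_duplicate: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class SiteRecord:
    """Per-position alignment summary (1-based position)."""

    scaffold: str
    pos: int
    depth: int
    fwd_reads: int
    rev_reads: int
    is_snp: bool
    is_indel: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.depth != self.fwd_reads + self.rev_reads:
            raise ValueError("depth must equal fwd_reads + rev_reads")


@dataclass
class CallableMask:
    """Per-scaffold boolean callable vectors (index 0 == position 1)."""

    masks: dict[str, np.ndarray]
    mean_depth: float

    @property
    def callable_bp(self) -> int:
        return int(sum(int(m.sum()) for m in self.masks.values()))

    def is_callable(self, scaffold: str, pos: int) -> bool:
        m = self.masks.get(scaffold)
        if m is None or not 1 <= pos <= len(m):
            return False
        return bool(m[pos - 1])


@dataclass(frozen=True)
class HetEstimate:
    snp_count: int
    callable_bp: int
    het_percent: float  # NaN when callable_bp == 0 (undefined, flagged)


def sites_to_frame(sites: Iterable[SiteRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        missing = set(SITE_COLUMNS) - set(sites.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        return sites
    return pd.DataFrame(
        [(s.scaffold, s.pos, s.depth, s.fwd_reads, s.rev_reads, s.is_snp, s.is_indel) for s in sites],
        columns=SITE_COLUMNS,
    )


def scaffold_stats(scaffolds: Sequence[Scaffold]) -> AssemblyStats:
    """Total size, scaffold count, N50 and GC% of an assembly.

    N50 is the length of the scaffold at which the cumulative length, taken in
    descending length order, first reaches half the total. GC% is computed
    over A/C/G/T bases only (N excluded from the denominator).
    """
    if not scaffolds:
        raise ValueError("empty scaffold set")
    lengths = sorted((len(s) for s in scaffolds), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break
    gc = at = 0
    for s in scaffolds:
        gc += s.sequence.count("G") + s.sequence.count("C")
        at += s.sequence.count("A") + s.sequence.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0
    return AssemblyStats(total_bp=total, n_scaffolds=len(scaffolds), n50_bp=n50, gc_percent=gc_percent)


def filter_scaffolds(scaffolds: Sequence[Scaffold], min_len: int = 1000) -> list[Scaffold]:
    """Keep scaffolds of length >= min_len (the 1 kb boundary itself is kept)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [s for s in scaffolds if len(s) >= min_len]


def _min_semiglobal_edit(read: str, mito: str, k: int) -> int | None:
    """Minimum edit distance of `read` against any window of `mito` (either
    strand), or None if it exceeds k. Read is aligned end-to-end; mito ends
    are free (edlib HW mode)."""
    best: int | None = None
    for query in (read, read.translate(_RC)[::-1]):
        res = edlib.align(query, mito, mode="HW", task="distance", k=k)
        d = res["editDistance"]
        if d != -1 and (best is None or d < best):
            best = d
    return best


def mito_read_filter(
    reads: Mapping[str, str], mito: Scaffold, max_edit: int = 3
) -> dict[str, str]:
    """Remove reads within `max_edit` edits of the mitochondrial reference.

    A read is removed iff its minimum semiglobal edit distance to the mito
    sequence, on either strand, is <= max_edit (default 3, i.e. "less than
    4"). Returns the retained reads, order preserved.
    """
    if len(mito.sequence) == 0:  # pragma: no cover - Scaffold forbids this
        raise ValueError("empty mitochondrial reference")
    retained: dict[str, str] = {}
    for rid, seq in reads.items():
        if _min_semiglobal_edit(seq, mito.sequence, max_edit) is None:
            retained[rid] = seq
    return retained


def filter_alignments(
    records: Iterable[AlignmentSummary], min_identity: float = 0.92
) -> list[AlignmentSummary]:
    """Keep unique, non-duplicate alignments with identity strictly above
    min_identity (a read at exactly 92% is dropped)."""
    return [
        r for r in records if r.is_unique and not r.is_duplicate and r.identity > min_identity
    ]


def _scaffold_blocks(scaf: np.ndarray, pos: np.ndarray) -> list[tuple[str, int, int]]:
    """Contiguous (scaffold, start_row, end_row) blocks of a sorted table;
    raises if scaffolds recur or positions are not strictly increasing."""
    if len(scaf) == 0:
        return []
    change = np.flatnonzero(scaf[1:] != scaf[:-1])
    starts = np.r_[0, change + 1]
    ends = np.r_[change + 1, len(scaf)]
    names = [str(scaf[s]) for s in starts]
    if len(set(names)) != len(names):
        raise ValueError("site table not sorted by (scaffold, pos)")
    within = np.ones(max(len(pos) - 1, 0), dtype=bool)
    within[change] = False
    if np.any((pos[1:] <= pos[:-1]) & within):
        raise ValueError("site table not sorted by (scaffold, pos)")
    return [(n, int(s), int(e)) for n, s, e in zip(names, starts, ends)]


def callable_mask(
    sites: Iterable[SiteRecord] | pd.DataFrame,
    indel_window: int = 10,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> CallableMask:
    """Compute the callable-region mask from a sorted per-site table.

    A position is callable iff its depth lies within [mean/2, 2*mean]
    (inclusive bounds), at least one read maps on each strand, and it is not
    within +-indel_window of an indel (the indel position itself is also
    excluded; 21 positions are masked per indel with the default window).
    Positions absent from the table are uncallable. The mean depth is taken
    over all rows of the table.
    """
    df = sites_to_frame(sites)
    if df.empty:
        return CallableMask(masks={}, mean_depth=0.0)
    scaf = np.asarray(df["scaffold"])
    all_pos = df["pos"].to_numpy()
    all_depth = df["depth"].to_numpy(dtype=float)
    all_fwd = df["fwd_reads"].to_numpy()
    all_rev = df["rev_reads"].to_numpy()
    all_indel = df["is_indel"].to_numpy(dtype=bool)
    blocks = _scaffold_blocks(scaf, all_pos)
    mean_depth = float(all_depth.mean())
    lo, hi = 0.5 * mean_depth, 2.0 * mean_depth
    masks: dict[str, np.ndarray] = {}
    for scaffold, b0, b1 in blocks:
        pos = all_pos[b0:b1]
        depth = all_depth[b0:b1]
        length = int(scaffold_lengths[scaffold]) if scaffold_lengths else int(pos[-1])
        mask = np.zeros(length, dtype=bool)
        ok = (
            (depth >= lo)
            & (depth <= hi)
            & (all_fwd[b0:b1] >= 1)
            & (all_rev[b0:b1] >= 1)
        )
        idx = pos - 1
        keep = idx < length
        mask[idx[keep]] = ok[keep]
        for p in pos[all_indel[b0:b1]]:
            mask[max(0, p - 1 - indel_window) : p + indel_window] = False
        masks[scaffold] = mask
    return CallableMask(masks=masks, mean_depth=mean_depth)


def heterozygosity(
    sites: Iterable[SiteRecord] | pd.DataFrame, mask: CallableMask
) -> HetEstimate:
    """SNPs per callable base, as a percentage.

    Only SNP sites at callable positions count. With zero callable bases the
    estimate is undefined and het_percent is NaN.
    """
    df = sites_to_frame(sites)
    scaf = np.asarray(df["scaffold"])
    all_pos = df["pos"].to_numpy()
    all_snp = df["is_snp"].to_numpy(dtype=bool)
    snp_count = 0
    for scaffold, b0, b1 in _scaffold_blocks(scaf, all_pos):
        m = mask.masks.get(scaffold)
        if m is None:
            continue
        pos = all_pos[b0:b1][all_snp[b0:b1]]
        keep = pos <= len(m)
        snp_count += int(m[pos[keep] - 1].sum())
    callable_bp = mask.callable_bp
    if callable_bp == 0:
        return HetEstimate(snp_count=snp_count, callable_bp=0, het_percent=math.nan)
    return HetEstimate(
        snp_count=snp_count,
        callable_bp=callable_bp,
        het_percent=100.0 * snp_count / callable_bp,
    )
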