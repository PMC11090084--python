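"""Comparative stages: RBH orthology, microsynteny blocks, NG86 Ka/Ks.

Reciprocal best hits (RBH) between two proteomes serve as the ortholog
proxy; microsynteny blocks chain ortholog anchors that appear in consistent
order (allowing one global orientation flip and a bounded number of
intervening unanchored genes); Ka/Ks is estimated with the Nei-Gojobori
(1986) counting method with Jukes-Cantor correction and a normal-
approximation test on pN - pS. A Ka/Ks ratio well below 1 with a small
p-value indicates purifying selection, the signature expected of a
functionally constrained enzyme such as the luciferin-regenerating
thioesterase ACOT1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from scipy.stats import norm

from .protein_screen import make_aligner, pairwise_identity

__all__ = [
    "AlignmentResult",
    "OrthologPair",
    "GeneOrder",
    "SyntenyBlock",
    "CodonAlignment",
    "KaKsResult",
    "SaturationError",
    "global_align",
    "rbh_orthologs",
    "synteny_blocks",
    "ng86_counts",
    "ng86_kaks",
    "STOP_CODONS",
    "synonymous_fraction",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()


class SaturationError(ValueError):
    """Raised when p-distances reach the Jukes-Cantor singularity (>= 0.75)."""


@dataclass(frozen=True)
class AlignmentResult:
    query: str
    target: str
    score: float
    identity: float


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    score: float


@dataclass
class GeneOrder:
    """Ordered (gene id, strand) list along one scaffold."""

    scaffold: str
    genes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.scaffold}: duplicate gene ids in order")

    def index(self) -> dict[str, int]:
        return {g: i for i, (g, _) in enumerate(self.genes)}


@dataclass
class SyntenyBlock:
    pairs: list[tuple[str, str]]
    scaffold_a: str
    scaffold_b: str
    orientation: str  # "forward" | "inverted"
    n_gaps: int


@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-free, equal-length, internally stop-free codon sequences."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            if len(seq) % 3 != 0:
                raise ValueError(f"{name}: length not divisible by 3")
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name}: non-ACGT characters")
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences differ in length")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError("internal stop codon in alignment")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None  # None when Ks == 0 (undefined)
    p_value: float


def global_align(
    a: str,
    b: str,
    aligner: PairwiseAligner | None = None,
    query_id: str = "a",
    target_id: str = "b",
) -> AlignmentResult:
    """Optimal global affine-gap alignment score and identity."""
    if not a or not b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    try:
        score = float(aligner.score(a, b))
    except ValueError as err:
        raise ValueError(f"residue outside the matrix alphabet: {err}")
    identity = pairwise_identity(a, b, aligner)
    return AlignmentResult(query=query_id, target=target_id, score=score, identity=identity)


def _unique_best(scores: Mapping[str, float]) -> str | None:
    """Key of the strict maximum, or None on a tie for the top score."""
    best_key, best, tie = None, -math.inf, False
    for key, val in scores.items():
        if val > best:
            best_key, best, tie = key, val, False
        elif val == best:
            tie = True
    return None if tie else best_key


def rbh_orthologs(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    aligner: PairwiseAligner | None = None,
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes.

    (x, y) is emitted iff y is the unique top-scoring target of x in B and x
    the unique top-scoring target of y in A. Ties for the top score drop the
    query (conservative). Pairs are returned sorted by id_a.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    ids_a, ids_b = list(proteome_a), list(proteome_b)
    scores = {
        (x, y): float(aligner.score(proteome_a[x], proteome_b[y]))
        for x in ids_a
        for y in ids_b
    }
    best_in_b = {x: _unique_best({y: scores[x, y] for y in ids_b}) for x in ids_a}
    best_in_a = {y: _unique_best({x: scores[x, y] for x in ids_a}) for y in ids_b}
    pairs = [
        OrthologPair(id_a=x, id_b=y, score=scores[x, y])
        for x, y in ((x, best_in_b[x]) for x in ids_a)
        if y is not None and best_in_a[y] == x
    ]
    return sorted(pairs, key=lambda p: p.id_a)


# --- microsynteny ------------------------------------------------------------


def _best_chain(
    anchors: Sequence[tuple[int, int]], max_gap: int
) -> tuple[tuple[int, ...], str] | None:
    """Best monotone chain over anchor (i, j) positions.

    Considers forward (i, j both increasing) and inverted (j decreasing)
    chains with per-step gaps <= max_gap in both genomes. Returns (anchor
    index tuple, orientation) maximizing (length, forward-first,
    lexicographically smallest (i, j) sequence), or None if empty.
    """
    if not anchors:
        return None

    def better(a: tuple[int, tuple[int, ...]], b: tuple[int, tuple[int, ...]]) -> bool:
        """(length, chain) preference: longer, then smaller (i, j) key."""
        if a[0] != b[0]:
            return a[0] > b[0]
        return _chain_key(a[1], anchors) < _chain_key(b[1], anchors)

    def best_oriented(js: Sequence[int]) -> tuple[int, ...]:
        order = sorted(range(len(anchors)), key=lambda k: (anchors[k][0], js[k]))
        # dp[k] = best (length, chain of anchor indices) ending at anchor k
        dp: dict[int, tuple[int, tuple[int, ...]]] = {}
        for t, k in enumerate(order):
            ik, jk = anchors[k][0], js[k]
            best = (1, (k,))
            for u in order[:t]:
                iu, ju = anchors[u][0], js[u]
                if iu < ik and ju < jk and ik - iu - 1 <= max_gap and jk - ju - 1 <= max_gap:
                    cand = (dp[u][0] + 1, dp[u][1] + (k,))
                    if better(cand, best):
                        best = cand
            dp[k] = best
        top = None
        for entry in dp.values():
            if top is None or better(entry, top):
                top = entry
        assert top is not None
        return top[1]

    fwd = best_oriented([j for _, j in anchors])
    inv = best_oriented([-j for _, j in anchors])
    if len(inv) > len(fwd):
        return inv, "inverted"
    return fwd, "forward"  # forward preferred on equal length


def _chain_key(chain: Sequence[int], anchors: Sequence[tuple[int, int]]) -> tuple[int, ...]:
    return tuple(x for k in chain for x in anchors[k])


def synteny_blocks(
    order_a: GeneOrder,
    order_b: GeneOrder,
    pairs: Iterable[OrthologPair],
    max_gap: int = 2,
    min_anchors: int = 2,
) -> list[SyntenyBlock]:
    """Chain ortholog anchors into microsynteny blocks.

    Anchors are ortholog pairs present in both gene orders. Blocks are
    extracted greedily: repeatedly take the longest valid chain (strictly
    monotone in both orders, one global orientation per block, <= max_gap
    intervening genes per step in either genome) among unused anchors, until
    none of at least `min_anchors` remains. Single-anchor blocks are
    suppressed by default.
    """
    idx_a, idx_b = order_a.index(), order_b.index()
    anchors: list[tuple[int, int]] = []
    anchor_pairs: list[tuple[str, str]] = []
    for p in sorted(pairs, key=lambda p: p.id_a):
        if p.id_a in idx_a and p.id_b in idx_b:
            anchors.append((idx_a[p.id_a], idx_b[p.id_b]))
            anchor_pairs.append((p.id_a, p.id_b))
    blocks: list[SyntenyBlock] = []
    remaining = list(range(len(anchors)))
    while remaining:
        sub = [anchors[k] for k in remaining]
        best = _best_chain(sub, max_gap)
        if best is None or len(best[0]) < min_anchors:
            break
        chain_local, orientation = best
        chain = [remaining[k] for k in chain_local]
        n_gaps = 0
        for k1, k2 in zip(chain, chain[1:]):
            n_gaps += abs(anchors[k2][0] - anchors[k1][0]) - 1
            n_gaps += abs(anchors[k2][1] - anchors[k1][1]) - 1
        blocks.append(
            SyntenyBlock(
                pairs=[anchor_pairs[k] for k in chain],
                scaffold_a=order_a.scaffold,
                scaffold_b=order_b.scaffold,
                orientation=orientation,
                n_gaps=n_gaps,
            )
        )
        used = set(chain)
        remaining = [k for k in remaining if k not in used]
    return blocks


# --- NG86 Ka/Ks --------------------------------------------------------------


def synonymous_fraction(codon: str, position: int) -> float:
    """Fraction of the non-stop single-nucleotide changes at `position` of
    `codon` that are synonymous (the NG86 site weight for that position)."""
    aa = _CODON_TABLE[codon]
    syn = nonstop = 0
    for nt in "ACGT":
        if nt == codon[position]:
            continue
        mutant = codon[:position] + nt + codon[position + 1 :]
        if mutant in STOP_CODONS:
            continue
        nonstop += 1
        if _CODON_TABLE[mutant] == aa:
            syn += 1
    return syn / nonstop if nonstop else 0.0


def _codon_sites(codon: str) -> tuple[float, float]:
    s = sum(synonymous_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over minimal mutational
    pathways from c1 to c2, excluding pathways through stop intermediates
    (renormalized; if every pathway is blocked, all pathways count)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for perm in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if blocked else valid).append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_counts(aln: CodonAlignment) -> tuple[float, float, float, float]:
    """NG86 site and difference counts (S, N, Sd, Nd).

    Sites are averaged over the two sequences (S + N = 3 x codons exactly);
    differences are averaged over minimal mutational pathways per codon pair.
    """
    S = N = Sd = Nd = 0.0
    for i in range(0, len(aln.seq_a), 3):
        ca, cb = aln.seq_a[i : i + 3], aln.seq_b[i : i + 3]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    pS = Sd/S and pN = Nd/N from :func:`ng86_counts` are corrected as
    K = -3/4 ln(1 - 4p/3). The p-value is a two-sided z-test on pN - pS with
    binomial variances. Identical sequences give Ka = Ks = 0, an undefined
    ratio, and p = 1. p-distances >= 0.75 raise :class:`SaturationError`.
    """
    S, N, Sd, Nd = ng86_counts(aln)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if pS >= 0.75 or pN >= 0.75:
        raise SaturationError(
            f"p-distance saturated (pS={pS:.3f}, pN={pN:.3f}); JC correction undefined"
        )
    Ks = -0.75 * math.log1p(-4.0 * pS / 3.0)
    Ka = -0.75 * math.log1p(-4.0 * pN / 3.0)
    ratio = Ka / Ks if Ks > 0 else None
    var = (pS * (1 - pS) / S if S > 0 else 0.0) + (pN * (1 - pN) / N if N > 0 else 0.0)
    if var > 0:
        z = (pN - pS) / math.sqrt(var)
        p_value = float(2.0 * norm.sf(abs(z)))
    else:
        p_value = 1.0
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio, p_value=p_value
    )
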