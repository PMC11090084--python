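"""Independent brute-force oracles used only by the test suite.

Each oracle reimplements a quantity from first principles (full dynamic
programming, exhaustive enumeration) without touching the library code paths
it checks.
"""

from __future__ import annotations

import itertools

# --- N50 ---------------------------------------------------------------------


def n50_bruteforce(lengths: list[int]) -> int:
    """Enumerate cumulative sums of the descending lengths explicitly."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    running = 0
    for length in ordered:
        running += length
        if 2 * running >= total:
            return length
    raise AssertionError("unreachable")


# --- semiglobal edit distance ------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def semiglobal_edit_distance(read: str, ref: str) -> int:
    """Full (unbanded) DP: read aligned end-to-end, free ref ends, both
    strands."""

    def one_strand(q: str) -> int:
        m, n = len(q), len(ref)
        prev = [0] * (n + 1)  # free start anywhere in ref
        for i in range(1, m + 1):
            cur = [i] + [0] * n
            qi = q[i - 1]
            for j in range(1, n + 1):
                sub = prev[j - 1] + (qi != ref[j - 1])
                cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
            prev = cur
        return min(prev)

    return min(one_strand(read), one_strand(revcomp(read)))


# --- global affine alignment -------------------------------------------------

NEG = float("-inf")


def gotoh_global_score(
    a: str, b: str, matrix, gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Affine-gap global alignment score; the first gap residue costs
    gap_open, each further residue gap_extend."""
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (a consumed)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s
            Ix[i][j] = max(
                M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend, Iy[i - 1][j] + gap_open
            )
            Iy[i][j] = max(
                M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend, Ix[i][j - 1] + gap_open
            )
    return max(M[m][n], Ix[m][n], Iy[m][n])


def enumerate_alignment_best_score(
    a: str, b: str, matrix, gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Exhaustively enumerate every global alignment (tiny inputs only)."""

    best = [NEG]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "x" else gap_open
            rec(i + 1, j, score + cost, "x")
        if j < len(b):
            cost = gap_extend if last == "y" else gap_open
            rec(i, j + 1, score + cost, "y")

    rec(0, 0, 0.0, "m")
    return best[0]


# --- NG86 counting -----------------------------------------------------------

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    b1 + b2 + b3: _AMINO[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon by explicit
    enumeration of every single-nucleotide change."""
    s_total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOPS:
                continue
            valid += 1
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


def ng86_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Average syn/nonsyn steps over all stop-free minimal pathways."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(positions):
        codon = c1
        sd = nd = 0
        through_stop = False
        for p in order:
            nxt = codon[:p] + c2[p] + codon[p + 1 :]
            if nxt in STOPS:
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[codon]:
                sd += 1
            else:
                nd += 1
            codon = nxt
        (dirty if through_stop else clean).append((sd, nd))
    use = clean if clean else dirty
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def ng86_counts_oracle(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = ng86_sites_oracle(ca)
        sb, nb = ng86_sites_oracle(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_diffs_oracle(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


# --- synteny chains ----------------------------------------------------------


def _all_chains(anchors, js, max_gap):
    """Every strictly monotone chain under the per-step gap bound."""
    n = len(anchors)
    chains = []

    def extend(chain):
        chains.append(chain)
        last = chain[-1]
        for k in range(n):
            if k in chain:
                continue
            ik, jk = anchors[k][0], js[k]
            il, jl = anchors[last][0], js[last]
            if il < ik and jl < jk and ik - il - 1 <= max_gap and jk - jl - 1 <= max_gap:
                extend(chain + (k,))

    for k in range(n):
        extend((k,))
    return chains


def best_chain_oracle(anchors, max_gap):
    """Best chain by exhaustive enumeration with the library's tie rules:
    longest; inverted only if strictly longer than the best forward; within
    an orientation the lexicographically smallest (i, j) sequence."""
    if not anchors:
        return None

    def key(chain):
        return tuple(x for k in chain for x in anchors[k])

    def best_for(js):
        cands = _all_chains(anchors, js, max_gap)
        best_len = max(len(c) for c in cands)
        return min((c for c in cands if len(c) == best_len), key=key)

    fwd = best_for([j for _, j in anchors])
    inv = best_for([-j for _, j in anchors])
    if len(inv) > len(fwd):
        return inv, "inverted"
    return fwd, "forward"


def synteny_blocks_oracle(anchors, max_gap, min_anchors=2):
    """Greedy block extraction mirroring the library contract, with the
    best chain found by exhaustive enumeration."""
    remaining = list(range(len(anchors)))
    blocks = []
    while remaining:
        sub = [anchors[k] for k in remaining]
        got = best_chain_oracle(sub, max_gap)
        if got is None or len(got[0]) < min_anchors:
            break
        chain_local, orientation = got
        chain = [remaining[k] for k in chain_local]
        blocks.append((tuple(chain), orientation))
        used = set(chain)
        remaining = [k for k in remaining if k not in used]
    return blocks


# --- locus grouping ----------------------------------------------------------


def locus_components_oracle(models) -> set[frozenset[str]]:
    """Connected components of the all-pairs CDS-overlap graph (union-find)."""
    ids = [m.id for m in models]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def overlap(m1, m2):
        if m1.scaffold != m2.scaffold or m1.strand != m2.strand:
            return False
        return any(
            s1 <= e2 and s2 <= e1 for s1, e1 in m1.cds for s2, e2 in m2.cds
        )

    for m1, m2 in itertools.combinations(models, 2):
        if overlap(m1, m2):
            parent[find(m1.id)] = find(m2.id)
    comps: dict[str, set[str]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}
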