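"""Luciferase-like (luc-like) candidate screen over an ACS protein set.

Firefly luciferases sit inside the acyl-CoA synthetase (ACS) superfamily.
The screen mirrors the field's operational definition of a luciferase-like
candidate: the protein (i) belongs to the luciferase-anchored identity
cluster (greedy clustering at 30% identity), (ii) carries the
Firefly-Luc-like domain motif (scored with a PSSM over sliding windows), and
(iii) is expressed in the lantern (TPM strictly above 10). Peroxisomal
targeting (PTS1, the C-terminal tripeptide) is annotated alongside but is
deliberately not part of the definition — the interesting candidates are
precisely the motif-positive, lantern-expressed proteins lacking PTS1.

The module ships a synthetic fixture PSSM and a transparent PTS1 tripeptide
PWM (canonical classes [SAC][KRH][LM] weighted highest); any
whitespace-delimited matrix file with a residue header row can be loaded in
their place. No claim is made of reproducing CDD or web-predictor scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "MotifPSSM",
    "PTS1Model",
    "Cluster",
    "make_aligner",
    "pairwise_identity",
    "greedy_cluster",
    "scan_motif",
    "predict_pts1",
    "classify_luc_like",
    "screen_proteins",
    "load_matrix",
    "default_motif_pssm",
    "default_pts1_model",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

NEG_INF = float("-inf")


@dataclass
class ProteinRecord:
    """A protein with its screen annotations."""

    id: str
    sequence: str
    tpm: float = 0.0
    cluster_id: str | None = None
    motif_score: float = NEG_INF
    motif_hit: bool = False
    pts1_score: float = NEG_INF
    pts1_positive: bool = False
    luc_like: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")


def _parse_matrix(text: str) -> tuple[np.ndarray, float | None]:
    """Parse a whitespace-delimited matrix with a residue header row.

    An optional comment line '# threshold <x>' carries the score threshold.
    Columns are reordered to the canonical AMINO_ACIDS order.
    """
    threshold: float | None = None
    header: list[str] | None = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0].lower() == "threshold":
                threshold = float(parts[1])
            continue
        if header is None:
            header = line.split()
            if sorted(header) != sorted(AMINO_ACIDS):
                raise ValueError("matrix header must list the 20 amino acids")
        else:
            rows.append([float(x) for x in line.split()])
    if header is None or not rows:
        raise ValueError("empty matrix file")
    raw = np.asarray(rows, dtype=float)
    if raw.shape[1] != 20:
        raise ValueError("each matrix row must have 20 scores")
    order = [header.index(aa) for aa in AMINO_ACIDS]
    return raw[:, order], threshold


@dataclass
class MotifPSSM:
    """Position-specific scoring matrix (log-odds vs uniform background)."""

    scores: np.ndarray  # (width, 20), columns in AMINO_ACIDS order
    threshold: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20 or self.scores.shape[0] < 3:
            raise ValueError("PSSM must be (width >= 3) x 20")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM entries must be finite")

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @classmethod
    def load(cls, path: str | PathLike, threshold: float | None = None) -> "MotifPSSM":
        scores, file_threshold = _parse_matrix(open(path).read())
        thr = threshold if threshold is not None else file_threshold
        if thr is None:
            raise ValueError("no threshold in file and none given")
        return cls(scores=scores, threshold=thr)


@dataclass
class PTS1Model:
    """3 x 20 position weight matrix scored over the C-terminal tripeptide."""

    weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (3, 20):
            raise ValueError("PTS1 model must be a 3 x 20 matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PTS1 entries must be finite")

    @classmethod
    def load(cls, path: str | PathLike, threshold: float | None = None) -> "PTS1Model":
        weights, file_threshold = _parse_matrix(open(path).read())
        thr = threshold if threshold is not None else file_threshold
        if thr is None:
            raise ValueError("no threshold in file and none given")
        return cls(weights=weights, threshold=thr)


def load_matrix(path: str | PathLike) -> tuple[np.ndarray, float | None]:
    """Load any PSSM/PWM text matrix; returns (scores, threshold-or-None)."""
    return _parse_matrix(open(path).read())


def default_motif_pssm() -> MotifPSSM:
    """The shipped synthetic Firefly-Luc-like fixture PSSM."""
    ref = resources.files("lumigene") / "data" / "luc_motif.pssm"
    scores, thr = _parse_matrix(ref.read_text())
    assert thr is not None
    return MotifPSSM(scores=scores, threshold=thr)


def default_pts1_model() -> PTS1Model:
    ref = resources.files("lumigene") / "data" / "pts1.pwm"
    weights, thr = _parse_matrix(ref.read_text())
    assert thr is not None
    return PTS1Model(weights=weights, threshold=thr)


@dataclass
class Cluster:
    id: str
    representative: str
    members: list[str] = field(default_factory=list)


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    """Global affine-gap protein aligner (defaults: BLOSUM62, 11/1 gaps)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity of the optimal global alignment of `a` and `b`.

    The denominator is the full alignment length, gap columns included
    (the conservative choice among the definitions tools offer).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except ValueError as err:
        raise ValueError(f"sequence contains residues outside the matrix alphabet: {err}")
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_cluster(
    proteins: Mapping[str, str],
    min_id: float = 0.30,
    aligner: Align.PairwiseAligner | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Proteins are processed in descending length order (ties by id); each one
    joins the first existing cluster whose *representative* it matches at
    identity >= min_id (inclusive), else founds a new cluster. Mirrors the
    easy-cluster workflow at --min-seq-id 0.3 without its prefilter
    heuristics; order-independent by construction.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    if aligner is None:
        aligner = make_aligner()
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    clusters: list[Cluster] = []
    for pid in order:
        seq = proteins[pid]
        for cluster in clusters:
            if pairwise_identity(seq, proteins[cluster.representative], aligner) >= min_id:
                cluster.members.append(pid)
                break
        else:
            clusters.append(Cluster(id=f"cluster{len(clusters) + 1}", representative=pid, members=[pid]))
    return clusters


def scan_motif(sequence: str, pssm: MotifPSSM) -> tuple[float, bool]:
    """Best PSSM window score over the sequence and the hit call.

    Sequences shorter than the motif width score -inf and cannot hit.
    Residues outside the 20-letter alphabet (e.g. X) contribute 0.
    """
    n, w = len(sequence), pssm.width
    if n < w:
        return NEG_INF, False
    # extra zero column for unknown residues
    ext = np.hstack([pssm.scores, np.zeros((w, 1))])
    idx = np.fromiter((_AA_INDEX.get(c, 20) for c in sequence), dtype=np.intp, count=n)
    totals = np.zeros(n - w + 1)
    for j in range(w):
        totals += ext[j, idx[j : j + n - w + 1]]
    best = float(totals.max())
    return best, best >= pssm.threshold


def predict_pts1(sequence: str, model: PTS1Model) -> tuple[float, bool]:
    """Score the C-terminal tripeptide against the PTS1 PWM.

    Only the last three residues are scored; shorter sequences are negative
    with a -inf sentinel. Unknown residues contribute 0.
    """
    if len(sequence) < 3:
        return NEG_INF, False
    tail = sequence[-3:]
    score = 0.0
    for j, c in enumerate(tail):
        i = _AA_INDEX.get(c)
        if i is not None:
            score += float(model.weights[j, i])
    return score, score >= model.threshold


def classify_luc_like(
    motif_hit: bool, tpm: float, in_luciferase_cluster: bool, tpm_threshold: float = 10.0
) -> bool:
    """luc-like iff in the luciferase-anchored cluster, motif-positive, and
    lantern TPM strictly above the threshold. PTS1 plays no role here."""
    return in_luciferase_cluster and motif_hit and tpm > tpm_threshold


def screen_proteins(
    proteins: Mapping[str, str],
    tpm: Mapping[str, float],
    pssm: MotifPSSM,
    pts1: PTS1Model,
    anchor: str,
    min_id: float = 0.30,
    tpm_threshold: float = 10.0,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[ProteinRecord], list[Cluster]]:
    """Run the full screen: cluster, scan, annotate PTS1, classify.

    `anchor` designates the known luciferase (e.g. LUC1); its cluster is the
    luciferase-related cluster. Returns annotated records (input order) and
    the clusters.
    """
    if anchor not in proteins:
        raise ValueError(f"anchor {anchor!r} not in protein set")
    clusters = greedy_cluster(proteins, min_id=min_id, aligner=aligner)
    cluster_of = {pid: c.id for c in clusters for pid in c.members}
    anchor_cluster = cluster_of[anchor]
    records = []
    for pid, seq in proteins.items():
        motif_score, motif_hit = scan_motif(seq, pssm)
        pts1_score, pts1_positive = predict_pts1(seq, pts1)
        t = float(tpm.get(pid, 0.0))
        in_cluster = cluster_of[pid] == anchor_cluster
        records.append(
            ProteinRecord(
                id=pid,
                sequence=seq,
                tpm=t,
                cluster_id=cluster_of[pid],
                motif_score=motif_score,
                motif_hit=motif_hit,
                pts1_score=pts1_score,
                pts1_positive=pts1_positive,
                luc_like=classify_luc_like(motif_hit, t, in_cluster, tpm_threshold),
            )
        )
    return records, clusters
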