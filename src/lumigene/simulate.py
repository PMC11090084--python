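"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its configuration and seed, so a fixed
seed reproduces byte-identical files. The planted truth (representative
models, luc-like calls, ortholog pairs, divergence targets, heterozygosity)
is returned alongside the data so downstream stages can be tested for exact
recovery.

Modelling choices are deliberately simple: nucleotide composition is i.i.d.
per base with a GC parameter (no repeat structure); read counts are
multinomial with probabilities proportional to planted TPM x length (which
inverts the TPM formula exactly in expectation); codon divergence is planted
per position at the rates implied by the target Ks and Ka/Ks through the
inverse Jukes-Cantor map, with stop-creating changes resampled.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .assembly_qc import SITE_COLUMNS, AlignmentSummary, Scaffold
from .comparative import (
    CodonAlignment,
    GeneOrder,
    STOP_CODONS,
    _CODON_TABLE,
    synonymous_fraction,
)
from .expression import MILLION, CountRecord
from .geneset import GeneModel
from .protein_screen import AMINO_ACIDS, MotifPSSM, PTS1Model, scan_motif, predict_pts1

__all__ = [
    "SynthConfig",
    "TruthSet",
    "PlacementError",
    "UnreachableTargetError",
    "make_genome",
    "make_mito",
    "make_reads",
    "make_alignment_summaries",
    "make_evidence_tracks",
    "make_expression",
    "make_protein_families",
    "make_ortholog_proteome",
    "make_gene_orders",
    "make_divergent_codon_pair",
    "make_site_table",
]

_NT = np.frombuffer(b"ACGT", dtype="S1")
_ALL_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class PlacementError(ValueError):
    """Requested loci do not fit in the genome."""


class UnreachableTargetError(ValueError):
    """Divergence target beyond what the simulator/estimator can represent."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data generators.

    The GC default matches the AT-rich firefly genome (28.4% GC); planted
    heterozygosity defaults to 1.0% and mean mapping depth to 30x.
    """

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length_range: tuple[int, int] = (200_000, 300_000)
    gc_target: float = 0.284
    n_loci: int = 50
    exon_count_range: tuple[int, int] = (2, 6)
    track_noise: float = 0.1
    het_rate: float = 0.01
    depth_mean: float = 30.0

    def __post_init__(self) -> None:
        for name in ("gc_target", "track_noise", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.scaffold_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid scaffold_length_range")
        elo, ehi = self.exon_count_range
        if not 2 <= elo <= ehi:
            raise ValueError("exon_count_range minimum must be >= 2")


@dataclass
class TruthSet:
    """Planted ground truth; every id resolves in the emitted files."""

    representative_per_locus: dict[str, str] = field(default_factory=dict)
    variant_ids: dict[str, set[str]] = field(default_factory=dict)
    locus_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    mergeable_abinitio_ids: set[str] = field(default_factory=set)
    unmergeable_abinitio_ids: set[str] = field(default_factory=set)
    luc_like_ids: set[str] = field(default_factory=set)
    pts1_negative_luc_like_ids: set[str] = field(default_factory=set)
    family_of_protein: dict[str, str] = field(default_factory=dict)
    anchor_id: str | None = None
    ortholog_pairs: set[tuple[str, str]] = field(default_factory=set)
    paralog_ids: set[str] = field(default_factory=set)
    synteny_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_tpm: dict[str, float] = field(default_factory=dict)
    planted_ka: float | None = None
    planted_ks: float | None = None
    planted_het: float | None = None
    snp_positions: dict[str, list[int]] = field(default_factory=dict)
    indel_positions: dict[str, list[int]] = field(default_factory=dict)
    mito_read_ids: set[str] = field(default_factory=set)
    retained_alignment_ids: set[str] = field(default_factory=set)

    def variant_sets_by_representative(self) -> dict[str, frozenset[str]]:
        return {
            rep: frozenset(self.variant_ids[locus])
            for locus, rep in self.representative_per_locus.items()
        }

    def merge(self, other: "TruthSet") -> "TruthSet":
        """Fold `other`'s planted truth into this set (in place)."""
        for f in dataclasses.fields(TruthSet):
            mine, theirs = getattr(self, f.name), getattr(other, f.name)
            if isinstance(mine, (dict, set)):
                mine.update(theirs)
            elif isinstance(mine, list):
                mine.extend(theirs)
            elif theirs is not None:
                setattr(self, f.name, theirs)
        return self

    def to_json(self, path: str | PathLike) -> None:
        def enc(v):
            if isinstance(v, set):
                return sorted(list(x) if isinstance(x, tuple) else x for x in v)
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            return v

        payload = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(TruthSet)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "TruthSet":
        raw = json.load(open(path))
        ts = cls()
        ts.representative_per_locus = dict(raw["representative_per_locus"])
        ts.variant_ids = {k: set(v) for k, v in raw["variant_ids"].items()}
        ts.locus_spans = {k: tuple(v) for k, v in raw["locus_spans"].items()}
        ts.mergeable_abinitio_ids = set(raw["mergeable_abinitio_ids"])
        ts.unmergeable_abinitio_ids = set(raw["unmergeable_abinitio_ids"])
        ts.luc_like_ids = set(raw["luc_like_ids"])
        ts.pts1_negative_luc_like_ids = set(raw["pts1_negative_luc_like_ids"])
        ts.family_of_protein = dict(raw["family_of_protein"])
        ts.anchor_id = raw["anchor_id"]
        ts.ortholog_pairs = {tuple(p) for p in raw["ortholog_pairs"]}
        ts.paralog_ids = set(raw["paralog_ids"])
        ts.synteny_pairs = [tuple(p) for p in raw["synteny_pairs"]]
        ts.planted_tpm = {k: float(v) for k, v in raw["planted_tpm"].items()}
        ts.planted_ka = raw["planted_ka"]
        ts.planted_ks = raw["planted_ks"]
        ts.planted_het = raw["planted_het"]
        ts.snp_positions = {k: list(v) for k, v in raw["snp_positions"].items()}
        ts.indel_positions = {k: list(v) for k, v in raw["indel_positions"].items()}
        ts.mito_read_ids = set(raw["mito_read_ids"])
        ts.retained_alignment_ids = set(raw["retained_alignment_ids"])
        return ts


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _NT[idx].tobytes().decode()


def make_genome(cfg: SynthConfig) -> tuple[list[Scaffold], TruthSet]:
    """Multi-scaffold genome with i.i.d. composition at the target GC."""
    if cfg.n_scaffolds == 0:
        raise ValueError("n_scaffolds must be >= 1 (empty genome)")
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.scaffold_length_range
    scaffolds = []
    for i in range(cfg.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        scaffolds.append(
            Scaffold(id=f"scaffold_{i + 1}", sequence=_random_dna(rng, length, cfg.gc_target))
        )
    return scaffolds, TruthSet()


def make_mito(cfg: SynthConfig, length: int = 16_000, gc: float = 0.20) -> Scaffold:
    """AT-rich mitochondrial reference, independent of the nuclear genome."""
    rng = np.random.default_rng([cfg.seed, 7])
    return Scaffold(id="mito", sequence=_random_dna(rng, length, gc))


def _mutate_dna(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        alt = [c for c in "ACGT" if c != chars[pos]]
        chars[pos] = alt[int(rng.integers(3))]
    return "".join(chars)


def make_reads(
    scaffolds: Sequence[Scaffold],
    mito: Scaffold,
    cfg: SynthConfig,
    n_genomic: int = 60,
    n_mito_like: int = 20,
    n_near_mito: int = 10,
    read_len: int = 100,
) -> tuple[dict[str, str], TruthSet]:
    """Reads for the mitochondrial filter: genomic reads (retained), reads
    within edit distance 3 of the mito reference (planted for removal), and
    mito-derived reads pushed beyond distance 3 (retained)."""
    rng = np.random.default_rng([cfg.seed, 8])
    truth = TruthSet()
    reads: dict[str, str] = {}
    for i in range(n_genomic):
        scaf = scaffolds[int(rng.integers(len(scaffolds)))]
        start = int(rng.integers(0, len(scaf.sequence) - read_len))
        reads[f"read_g{i + 1}"] = scaf.sequence[start : start + read_len]
    for i in range(n_mito_like):
        start = int(rng.integers(0, len(mito.sequence) - read_len))
        window = mito.sequence[start : start + read_len]
        rid = f"read_m{i + 1}"
        reads[rid] = _mutate_dna(rng, window, int(rng.integers(0, 4)))
        truth.mito_read_ids.add(rid)
    for i in range(n_near_mito):
        start = int(rng.integers(0, len(mito.sequence) - read_len))
        seq = _mutate_dna(rng, mito.sequence[start : start + read_len], 10)
        # guarantee the read is genuinely beyond the removal distance
        while edlib.align(seq, mito.sequence, mode="HW", task="distance", k=3)["editDistance"] != -1:
            seq = _mutate_dna(rng, seq, 2)
        reads[f"read_n{i + 1}"] = seq
    return reads, truth


def make_alignment_summaries(
    cfg: SynthConfig, n: int = 200, min_identity: float = 0.92
) -> tuple[list[AlignmentSummary], TruthSet]:
    """Mapping summaries with known retained set under the identity/unique/
    duplicate rule."""
    rng = np.random.default_rng([cfg.seed, 9])
    truth = TruthSet()
    records = []
    for i in range(n):
        rec = AlignmentSummary(
            read_id=f"aln{i + 1}",
            identity=float(rng.uniform(0.80, 1.0)),
            is_unique=bool(rng.random() < 0.9),
            is_duplicate=bool(rng.random() < 0.1),
        )
        records.append(rec)
        if rec.is_unique and not rec.is_duplicate and rec.identity > min_identity:
            truth.retained_alignment_ids.add(rec.read_id)
    return records, truth


# --- evidence tracks ---------------------------------------------------------


def make_evidence_tracks(
    scaffolds: Sequence[Scaffold], cfg: SynthConfig
) -> tuple[dict[str, list[GeneModel]], TruthSet]:
    """Three candidate tracks with a known best model per locus.

    Per locus the designated best model (longest CDS) goes to the rnaseq or
    homology track; the other track receives a truncation sharing its exons
    exactly; an ab initio candidate overlaps the locus (must not merge) and,
    after some loci, an intergenic ab initio model is planted (high
    confidence: must merge; low: must not). With probability `track_noise`
    extra shorter exon-sharing candidates are emitted.
    """
    if not scaffolds:
        raise ValueError("empty genome")
    rng = np.random.default_rng([cfg.seed, 1])
    tracks: dict[str, list[GeneModel]] = {"rnaseq": [], "homology": [], "abinitio": []}
    truth = TruthSet()
    placed = 0
    scaffold_iter = iter(scaffolds)
    scaf = next(scaffold_iter)
    cursor = 500
    while placed < cfg.n_loci:
        k = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(30, 81, size=k) * 3
        intron_lens = rng.integers(60, 401, size=k - 1)
        footprint = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(700, 1200))
        if cursor + footprint + gap + 500 > len(scaf.sequence):
            try:
                scaf = next(scaffold_iter)
            except StopIteration:
                raise PlacementError(
                    f"placed {placed} of {cfg.n_loci} loci; genome capacity exceeded"
                )
            cursor = 500
            continue
        placed += 1
        idx = placed
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = cursor
        for j in range(k):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos = exons[-1][1] + 1 + (int(intron_lens[j]) if j < k - 1 else 0)
        locus_end = exons[-1][1]

        best_track = "rnaseq" if rng.random() < 0.5 else "homology"
        other_track = "homology" if best_track == "rnaseq" else "rnaseq"
        prefix = {"rnaseq": "r", "homology": "h"}
        best_id = f"{prefix[best_track]}{idx:04d}.1"
        other_id = f"{prefix[other_track]}{idx:04d}.1"
        tracks[best_track].append(
            GeneModel(best_id, scaf.id, strand, list(exons), list(exons), best_track)
        )
        short = exons[:-1]
        tracks[other_track].append(
            GeneModel(other_id, scaf.id, strand, short, short, other_track)
        )
        # ab initio candidate overlapping the locus: never merged
        ab_id = f"a{idx:04d}.1"
        ab_conf = "high" if rng.random() < 0.5 else "low"
        tracks["abinitio"].append(
            GeneModel(ab_id, scaf.id, strand, list(exons), list(exons), "abinitio", ab_conf)
        )
        truth.unmergeable_abinitio_ids.add(ab_id)

        locus_key = f"pl{idx:04d}"
        truth.representative_per_locus[locus_key] = best_id
        truth.variant_ids[locus_key] = {best_id, other_id}
        truth.locus_spans[locus_key] = (scaf.id, exons[0][0], locus_end)

        n_extra = 2
        suffix = 2
        for _ in range(n_extra):
            if rng.random() < cfg.track_noise:
                track = "rnaseq" if rng.random() < 0.5 else "homology"
                i0 = int(rng.integers(0, k - 1))
                j0 = int(rng.integers(i0 + 1, k))  # proper subset: at most k-1 exons
                sub = exons[i0:j0]
                nid = f"{prefix[track]}{idx:04d}.{suffix}"
                suffix += 1
                tracks[track].append(GeneModel(nid, scaf.id, strand, sub, sub, track))
                truth.variant_ids[locus_key].add(nid)

        # intergenic ab initio in the trailing gap
        if rng.random() < 0.5:
            ig_len = int(rng.integers(50, 101)) * 3
            ig_start = locus_end + 200
            ig_conf = "high" if rng.random() < 0.7 else "low"
            ig_id = f"a{idx:04d}.ig"
            ig_strand = "+" if rng.random() < 0.5 else "-"
            tracks["abinitio"].append(
                GeneModel(
                    ig_id, scaf.id, ig_strand,
                    [(ig_start, ig_start + ig_len - 1)],
                    [(ig_start, ig_start + ig_len - 1)],
                    "abinitio", ig_conf,
                )
            )
            (truth.mergeable_abinitio_ids if ig_conf == "high" else truth.unmergeable_abinitio_ids).add(ig_id)
        cursor = locus_end + gap
    return tracks, truth


def make_expression(
    planted_tpm: Mapping[str, float],
    lengths: Mapping[str, int],
    total_reads: int = 1_000_000,
    seed: int = 0,
) -> list[CountRecord]:
    """Counts drawn multinomially with p proportional to planted TPM x length,
    so the TPM formula recovers the planted values in expectation."""
    ids = list(planted_tpm)
    tpm = np.array([planted_tpm[t] for t in ids], dtype=float)
    if np.any(tpm < 0):
        raise ValueError("negative planted TPM")
    if abs(tpm.sum() - MILLION) > 1e-6 * MILLION:
        raise ValueError(f"planted TPM must sum to 1e6, got {tpm.sum()}")
    lens = np.array([lengths[t] for t in ids], dtype=float)
    weights = tpm * lens
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_reads, p)
    return [
        CountRecord(transcript_id=t, length_bp=int(lengths[t]), count=float(c))
        for t, c in zip(ids, counts)
    ]


# --- protein families --------------------------------------------------------

_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


def _family_sequence(
    rng: np.random.Generator, ancestor: np.ndarray, comp: np.ndarray, rate: float
) -> np.ndarray:
    seq = ancestor.copy()
    mut = rng.random(len(seq)) < rate
    seq[mut] = rng.choice(20, size=int(mut.sum()), p=comp)
    return seq


def _ensure_no_motif(
    rng: np.random.Generator, seq: str, pssm: MotifPSSM, comp: np.ndarray
) -> str:
    score, hit = scan_motif(seq, pssm)
    while hit:  # vanishingly rare; rewrite random positions until clean
        chars = np.frombuffer(seq.encode(), dtype="S1").copy()
        pos = rng.choice(len(chars), size=pssm.width, replace=False)
        chars[pos] = _AA_ARRAY[rng.choice(20, size=pssm.width, p=comp)]
        seq = chars.tobytes().decode()
        score, hit = scan_motif(seq, pssm)
    return seq


def make_protein_families(
    cfg: SynthConfig, motif_pssm: MotifPSSM, pts1_pwm: PTS1Model
) -> tuple[dict[str, str], TruthSet]:
    """Protein families with planted motif, PTS1 and expression states.

    The anchor family (containing LUC1) carries seven planted luc-like
    proteins — LUC1/LUC2 (PTS1-positive) and LLp1-3, LLa1-2 (PTS1-negative) —
    plus in-cluster decoys failing the expression or motif condition.
    Background families are motif-negative with distinct compositions so
    cross-family identity stays far below the 0.30 clustering threshold.
    Planted TPMs (fillers included) sum to 1e6.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    length = 300
    # (id, motif, pts1, tpm, luc_like) for the anchor family
    anchor_members = [
        ("LUC1", True, True, 350.0, True),
        ("LUC2", True, True, 120.0, True),
        ("LLp1", True, False, 90.0, True),
        ("LLp2", True, False, 400.0, True),
        ("LLp3", True, False, 45.0, True),
        ("LLa1", True, False, 60.0, True),
        ("LLa2", True, False, 800.0, True),
        ("ACSlow1", True, True, 2.0, False),      # motif+ but not expressed
        ("ACSnomotif1", False, True, 150.0, False),  # expressed but motif-
        ("ACSquiet1", False, False, 1.0, False),
    ]
    families = {
        "lucfam": anchor_members,
        "fam2": [(f"BG2_{i}", False, i == 0, float(t), False)
                 for i, t in enumerate([200.0, 5.0, 3.0, 0.0, 7.0, 2.0])],
        "fam3": [(f"BG3_{i}", False, False, float(t), False)
                 for i, t in enumerate([4.0, 0.5, 8.0, 6.0, 1.5])],
    }
    pts1_pos_tails = ["SKL", "AKL", "SRL", "SKM"]
    pts1_neg_tails = ["DDE", "GGE", "EED"]
    proteins: dict[str, str] = {}
    truth = TruthSet(anchor_id="LUC1")
    for fam_name, members in families.items():
        comp = rng.dirichlet(np.full(20, 0.3))
        comp = 0.8 * comp + 0.2 / 20  # keep all residues reachable
        ancestor = rng.choice(20, size=length, p=comp)
        for pid, motif, pts1, tpm, luc in members:
            seq_arr = _family_sequence(rng, ancestor, comp, rate=0.12)
            seq = _AA_ARRAY[seq_arr].tobytes().decode()
            if motif:
                mid = length // 2
                seq = seq[:mid] + motif_pssm.consensus + seq[mid + motif_pssm.width :]
            tail = (
                pts1_pos_tails[int(rng.integers(len(pts1_pos_tails)))]
                if pts1
                else pts1_neg_tails[int(rng.integers(len(pts1_neg_tails)))]
            )
            seq = seq[:-3] + tail
            while not motif and scan_motif(seq, motif_pssm)[1]:
                # scrub accidental motif hits while keeping the planted tail
                seq = _ensure_no_motif(rng, seq, motif_pssm, comp)[:-3] + tail
            _, positive = predict_pts1(seq, pts1_pwm)
            if positive != pts1:
                raise ValueError(
                    f"{pid}: planted tail {tail!r} disagrees with the supplied PTS1 model"
                )
            proteins[pid] = seq
            truth.family_of_protein[pid] = fam_name
            truth.planted_tpm[pid] = tpm
            if luc:
                truth.luc_like_ids.add(pid)
                if not pts1:
                    truth.pts1_negative_luc_like_ids.add(pid)
    # fillers absorb the remaining TPM mass so the table sums to 1e6
    assigned = sum(truth.planted_tpm.values())
    n_fill = 20
    for i in range(n_fill):
        truth.planted_tpm[f"bulk{i + 1}"] = (MILLION - assigned) / n_fill
    return proteins, truth


def make_ortholog_proteome(
    proteins: Mapping[str, str],
    cfg: SynthConfig,
    divergence: float = 0.10,
    paralog_divergence: float = 0.40,
) -> tuple[dict[str, str], TruthSet]:
    """Second-species proteome: one ortholog per input protein at the given
    divergence, plus one highly diverged paralog that must stay unpaired."""
    rng = np.random.default_rng([cfg.seed, 3])
    truth = TruthSet()
    proteome_b: dict[str, str] = {}
    for pid, seq in proteins.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        mut = rng.random(len(arr)) < divergence
        arr[mut] = _AA_ARRAY[rng.integers(0, 20, size=int(mut.sum()))]
        bid = f"{pid}_B"
        proteome_b[bid] = arr.tobytes().decode()
        truth.ortholog_pairs.add((pid, bid))
    template = sorted(proteins)[0]
    arr = np.frombuffer(proteins[template].encode(), dtype="S1").copy()
    mut = rng.random(len(arr)) < paralog_divergence
    arr[mut] = _AA_ARRAY[rng.integers(0, 20, size=int(mut.sum()))]
    proteome_b["PARA_B"] = arr.tobytes().decode()
    truth.paralog_ids.add("PARA_B")
    return proteome_b, truth


def make_gene_orders(
    pair_ids: Sequence[tuple[str, str]],
    cfg: SynthConfig,
    n_inserted: int = 1,
    invert: bool = False,
) -> tuple[GeneOrder, GeneOrder, TruthSet]:
    """Collinear gene orders for two genomes from ortholog pairs, with
    `n_inserted` unanchored genes in genome B and an optional inversion."""
    rng = np.random.default_rng([cfg.seed, 4])
    genes_a = [(a, "+" if rng.random() < 0.5 else "-") for a, _ in pair_ids]
    genes_b = [(b, "+" if rng.random() < 0.5 else "-") for _, b in pair_ids]
    for i in range(n_inserted):
        pos = int(rng.integers(1, len(genes_b)))
        genes_b.insert(pos, (f"fillerB{i + 1}", "+"))
    if invert:
        genes_b = genes_b[::-1]
    truth = TruthSet(synteny_pairs=list(pair_ids))
    return GeneOrder("chrA", genes_a), GeneOrder("chrB", genes_b), truth


def make_divergent_codon_pair(
    length_codons: int, target_ks: float, target_kaks: float, seed: int
) -> tuple[CodonAlignment, TruthSet]:
    """Codon-alignment pair with planted synonymous divergence and omega.

    Substitutions are planted per position: with probability pS x f a
    synonymous change, with probability pN x (1 - f) a nonsynonymous one,
    where f is the NG86 synonymous fraction of the position and pS/pN the
    p-distances implied by the targets through the inverse Jukes-Cantor map.
    Stop-creating codons are resampled; the pair stays gap-free.
    """
    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    if target_ks < 0 or target_kaks < 0:
        raise ValueError("targets must be >= 0")
    p_syn = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    p_non = 0.75 * (1.0 - math.exp(-4.0 * target_ks * target_kaks / 3.0))
    if p_syn >= 0.70 or p_non >= 0.70:
        raise UnreachableTargetError(
            f"target divergence saturates the estimator (pS={p_syn:.3f}, pN={p_non:.3f})"
        )
    rng = np.random.default_rng(seed)
    codons_a = [_ALL_CODONS[int(i)] for i in rng.integers(0, len(_ALL_CODONS), length_codons)]
    codons_b: list[str] = []
    for codon in codons_a:
        for _ in range(100):
            chars = list(codon)
            for pos in range(3):
                f = synonymous_fraction(codon, pos)
                aa = _translate(codon)
                syn_nts, non_nts = [], []
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    mutant = codon[:pos] + nt + codon[pos + 1 :]
                    if mutant in STOP_CODONS:
                        continue
                    (syn_nts if _translate(mutant) == aa else non_nts).append(nt)
                u = rng.random()
                if u < p_syn * f and syn_nts:
                    chars[pos] = syn_nts[int(rng.integers(len(syn_nts)))]
                elif u < p_syn * f + p_non * (1 - f) and non_nts:
                    chars[pos] = non_nts[int(rng.integers(len(non_nts)))]
            mutated = "".join(chars)
            if mutated not in STOP_CODONS:
                codons_b.append(mutated)
                break
        else:
            codons_b.append(codon)
    aln = CodonAlignment(
        id_a="seqA", id_b="seqB", seq_a="".join(codons_a), seq_b="".join(codons_b)
    )
    truth = TruthSet(planted_ks=target_ks, planted_ka=target_ks * target_kaks)
    return aln, truth


def _translate(codon: str) -> str:
    return _CODON_TABLE[codon]


def make_site_table(
    genome_length: int,
    het_rate: float,
    depth_mean: float,
    n_indels: int,
    seed: int,
    scaffold: str = "chr1",
    uncallable_frac: float = 0.0,
    force_callable: bool = False,
) -> tuple[pd.DataFrame, TruthSet]:
    """Per-site alignment summary with Bernoulli SNPs and Poisson depth.

    `uncallable_frac` forces a fraction of sites to violate the depth or
    strand rules; `force_callable` clips depths into the callable band and
    guarantees both strands, for estimator calibration runs.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not 0.0 <= het_rate <= 0.2:
        raise ValueError("het_rate must be in [0, 0.2]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    L = genome_length
    depth = rng.poisson(depth_mean, L)
    if force_callable:
        depth = np.clip(depth, max(2, math.ceil(0.6 * depth_mean)), int(1.8 * depth_mean))
    fwd = rng.binomial(depth, 0.5)
    if force_callable:
        fwd = np.clip(fwd, 1, np.maximum(depth - 1, 1))
    is_snp = rng.random(L) < het_rate
    is_indel = np.zeros(L, dtype=bool)
    indel_pos: list[int] = []
    if n_indels > 0:
        chosen = np.sort(rng.choice(L, size=min(n_indels, L), replace=False))
        is_indel[chosen] = True
        indel_pos = [int(p) + 1 for p in chosen]
    if uncallable_frac > 0:
        k = int(round(uncallable_frac * L))
        bad = rng.choice(L, size=k, replace=False)
        half = k // 2
        depth[bad[:half]] = 0
        fwd[bad[:half]] = 0
        hi = int(3 * depth_mean)
        depth[bad[half:]] = hi
        fwd[bad[half:]] = hi  # single-strand and over-depth violation
    rev = depth - fwd
    df = pd.DataFrame(
        {
            "scaffold": pd.Categorical.from_codes(np.zeros(L, dtype=np.int8), [scaffold]),
            "pos": np.arange(1, L + 1, dtype=np.int64),
            "depth": depth.astype(np.int64),
            "fwd_reads": fwd.astype(np.int64),
            "rev_reads": rev.astype(np.int64),
            "is_snp": is_snp,
            "is_indel": is_indel,
        },
        columns=SITE_COLUMNS,
    )
    truth = TruthSet(
        planted_het=het_rate,
        snp_positions={scaffold: [int(p) + 1 for p in np.flatnonzero(is_snp)]},
        indel_positions={scaffold: indel_pos},
    )
    return df, truth
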