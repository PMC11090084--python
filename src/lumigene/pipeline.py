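"""Pipeline orchestration: demo dataset, configuration, stages, manifest.

`demo_dataset` writes a complete miniature two-species dataset (~1 Mb genome,
50 planted loci) with its truth files; `run_pipeline` executes
qc -> geneset -> tpm -> screen -> compare -> kaks on any conforming inputs
and records a manifest (config hash, input checksums, per-stage counts).
Every stochastic component derives from the single seed in the config, so a
rerun with the same seed and inputs reproduces identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assembly_qc, comparative, expression, geneset, io, protein_screen, simulate

logger = logging.getLogger(__name__)

STAGES = ("qc", "geneset", "tpm", "screen", "compare", "kaks")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; round-trips through JSON."""

    data_dir: str = "."
    out_dir: str = "results"
    genome: str = "genome.fa"
    mito: str = "mito.fa"
    reads: str = "reads.fa"
    alignments: str = "alignments.tsv"
    sites: str = "sites.tsv"
    rnaseq_track: str = "rnaseq.gff3"
    homology_track: str = "homology.gff3"
    abinitio_track: str = "abinitio.gff3"
    counts: str = "counts.tsv"
    proteins_a: str = "proteins_a.fa"
    proteins_b: str = "proteins_b.fa"
    orders_a: str = "orders_a.tsv"
    orders_b: str = "orders_b.tsv"
    codon_pairs: str = "codon_pairs.fa"
    motif_pssm: str = "luc_motif.pssm"
    pts1_pwm: str = "pts1.pwm"
    anchor: str = "LUC1"
    min_scaffold_len: int = 1000
    max_edit: int = 3
    min_identity: float = 0.92
    indel_window: int = 10
    min_seq_id: float = 0.30
    tpm_threshold: float = 10.0
    max_gap: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_scaffold_len < 1 or self.max_edit < 0 or self.indel_window < 0:
            raise ValueError("invalid threshold")
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_seq_id <= 1):
            raise ValueError("identity thresholds must be fractions")
        if self.tpm_threshold < 0 or self.max_gap < 0:
            raise ValueError("invalid threshold")

    def path(self, name: str) -> Path:
        return Path(self.data_dir) / getattr(self, name)

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "PipelineConfig":
        return cls(**json.load(open(path)))

    def digest(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    version: str = __version__
    timestamp: float = 0.0
    failed_stage: str | None = None

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


INPUT_FILES = (
    "genome", "mito", "reads", "alignments", "sites",
    "rnaseq_track", "homology_track", "abinitio_track",
    "counts", "proteins_a", "proteins_b", "orders_a", "orders_b",
    "codon_pairs", "motif_pssm", "pts1_pwm",
)


def _read_orders(path: Path) -> comparative.GeneOrder:
    df = pd.read_csv(path, sep="\t").sort_values("rank")
    scaffold = str(df["scaffold"].iloc[0])
    return comparative.GeneOrder(
        scaffold=scaffold,
        genes=[(str(r.gene_id), str(r.strand)) for r in df.itertuples(index=False)],
    )


def _write_orders(order: comparative.GeneOrder, path: Path) -> None:
    pd.DataFrame(
        {
            "scaffold": order.scaffold,
            "rank": range(1, len(order.genes) + 1),
            "gene_id": [g for g, _ in order.genes],
            "strand": [s for _, s in order.genes],
        }
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order; fail before any stage if an input is
    missing. On a stage failure, partial outputs are preserved and the
    manifest marks the failure point."""
    logging.basicConfig(level=config.log_level)
    missing = [n for n in INPUT_FILES if not config.path(n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing inputs: {', '.join(str(config.path(n)) for n in missing)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.digest(),
        input_checksums={n: _sha256(config.path(n)) for n in INPUT_FILES},
        timestamp=time.time(),
    )
    current = "qc"
    try:
        # --- qc ---
        scaffolds = [
            assembly_qc.Scaffold(i, s) for i, s in io.read_fasta(config.path("genome")).items()
        ]
        kept = assembly_qc.filter_scaffolds(scaffolds, config.min_scaffold_len)
        stats = assembly_qc.scaffold_stats(kept)
        mito = assembly_qc.Scaffold(*next(iter(io.read_fasta(config.path("mito")).items())))
        reads = io.read_fasta(config.path("reads"))
        kept_reads = assembly_qc.mito_read_filter(reads, mito, config.max_edit)
        aln_df = pd.read_csv(config.path("alignments"), sep="\t")
        summaries = [
            assembly_qc.AlignmentSummary(
                str(r.read_id), float(r.identity), bool(r.is_unique), bool(r.is_duplicate)
            )
            for r in aln_df.itertuples(index=False)
        ]
        kept_aln = assembly_qc.filter_alignments(summaries, config.min_identity)
        sites = io.read_site_table(config.path("sites"))
        mask = assembly_qc.callable_mask(sites, config.indel_window)
        het = assembly_qc.heterozygosity(sites, mask)
        qc_report = {
            "assembly": dataclasses.asdict(stats),
            "n_scaffolds_in": len(scaffolds),
            "n_scaffolds_kept": len(kept),
            "n_reads_in": len(reads),
            "n_reads_kept": len(kept_reads),
            "n_alignments_in": len(summaries),
            "n_alignments_kept": len(kept_aln),
            "mean_depth": mask.mean_depth,
            "callable_bp": het.callable_bp,
            "snp_count": het.snp_count,
            "het_percent": None if math.isnan(het.het_percent) else het.het_percent,
        }
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=1, sort_keys=True)
        manifest.stage_counts["qc"] = {
            "scaffolds_kept": len(kept),
            "reads_kept": len(kept_reads),
            "alignments_kept": len(kept_aln),
            "snp_count": het.snp_count,
        }

        # --- geneset ---
        current = "geneset"
        rnaseq = geneset.read_gff3(config.path("rnaseq_track"))
        homology = geneset.read_gff3(config.path("homology_track"))
        abinitio = geneset.read_gff3(config.path("abinitio_track"))
        gene_set = geneset.consolidate(rnaseq, homology, abinitio)
        geneset.write_geneset_gff3(gene_set, out / "final.gff3")
        pd.DataFrame(
            [
                {
                    "locus": l.id,
                    "n_candidates": len(l.members),
                    "representative": l.representative,
                    "n_variants": len(l.variants),
                    "n_dropped": len(l.members) - len(l.variants),
                }
                for l in gene_set.loci
            ]
        ).to_csv(out / "geneset_report.tsv", sep="\t", index=False)
        manifest.stage_counts["geneset"] = {
            "loci": len(gene_set.loci),
            "transcripts": len(gene_set.transcripts),
        }

        # --- tpm ---
        current = "tpm"
        records = expression.read_counts(config.path("counts"))
        tpm_table = expression.compute_tpm(records)
        expression.write_tpm(tpm_table, out / "tpm.tsv")
        manifest.stage_counts["tpm"] = {
            "transcripts": len(tpm_table),
            "expressed": len(expression.expressed_filter(tpm_table, config.tpm_threshold)),
        }

        # --- screen ---
        current = "screen"
        proteins = io.read_fasta(config.path("proteins_a"))
        pssm = protein_screen.MotifPSSM.load(config.path("motif_pssm"))
        pts1 = protein_screen.PTS1Model.load(config.path("pts1_pwm"))
        screen_records, clusters = protein_screen.screen_proteins(
            proteins,
            tpm_table,
            pssm,
            pts1,
            anchor=config.anchor,
            min_id=config.min_seq_id,
            tpm_threshold=config.tpm_threshold,
        )
        pd.DataFrame(
            [
                {
                    "id": r.id,
                    "cluster": r.cluster_id,
                    "motif_score": r.motif_score,
                    "motif_hit": int(r.motif_hit),
                    "pts1_score": r.pts1_score,
                    "pts1_positive": int(r.pts1_positive),
                    "tpm": r.tpm,
                    "luc_like": int(r.luc_like),
                }
                for r in screen_records
            ]
        ).to_csv(out / "screen.tsv", sep="\t", index=False)
        manifest.stage_counts["screen"] = {
            "proteins": len(screen_records),
            "clusters": len(clusters),
            "luc_like": sum(r.luc_like for r in screen_records),
        }

        # --- compare ---
        current = "compare"
        proteome_b = io.read_fasta(config.path("proteins_b"))
        pairs = comparative.rbh_orthologs(proteins, proteome_b)
        pd.DataFrame(
            [{"id_a": p.id_a, "id_b": p.id_b, "score": p.score} for p in pairs]
        ).to_csv(out / "orthologs.tsv", sep="\t", index=False)
        order_a = _read_orders(config.path("orders_a"))
        order_b = _read_orders(config.path("orders_b"))
        blocks = comparative.synteny_blocks(order_a, order_b, pairs, config.max_gap)
        pd.DataFrame(
            [
                {
                    "block_id": f"block{i + 1}",
                    "scaffold_a": b.scaffold_a,
                    "scaffold_b": b.scaffold_b,
                    "orientation": b.orientation,
                    "n_anchors": len(b.pairs),
                    "n_gaps": b.n_gaps,
                    "pairs": ",".join(f"{a}|{bb}" for a, bb in b.pairs),
                }
                for i, b in enumerate(blocks)
            ]
        ).to_csv(out / "blocks.tsv", sep="\t", index=False)
        manifest.stage_counts["compare"] = {"orthologs": len(pairs), "blocks": len(blocks)}

        # --- kaks ---
        current = "kaks"
        codon_seqs = io.read_fasta(config.path("codon_pairs"))
        ids = list(codon_seqs)
        if len(ids) % 2 != 0:
            raise ValueError("codon-pair FASTA must contain an even number of records")
        rows = []
        for i in range(0, len(ids), 2):
            a, b = ids[i], ids[i + 1]
            aln = comparative.CodonAlignment(a, b, codon_seqs[a], codon_seqs[b])
            res = comparative.ng86_kaks(aln)
            rows.append(
                {
                    "id_a": a, "id_b": b,
                    "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                    "pS": res.pS, "pN": res.pN, "Ka": res.Ka, "Ks": res.Ks,
                    "ratio": res.ratio if res.ratio is not None else float("nan"),
                    "p_value": res.p_value,
                }
            )
        pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
        manifest.stage_counts["kaks"] = {"pairs": len(rows)}
    except Exception as err:
        manifest.failed_stage = current
        manifest.to_json(out / "manifest.json")
        raise StageFailure(current, err) from err
    manifest.to_json(out / "manifest.json")
    return manifest


def demo_dataset(out_dir: str | PathLike, seed: int = 0) -> tuple[PipelineConfig, simulate.TruthSet]:
    """Write the miniature demo dataset (two synthetic species, planted
    truth) and its pipeline config; returns (config, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SynthConfig(seed=seed)
    truth = simulate.TruthSet()

    scaffolds, t = simulate.make_genome(cfg)
    truth.merge(t)
    io.write_fasta({s.id: s.sequence for s in scaffolds}, out / "genome.fa")
    mito = simulate.make_mito(cfg)
    io.write_fasta({mito.id: mito.sequence}, out / "mito.fa")
    reads, t = simulate.make_reads(scaffolds, mito, cfg)
    truth.merge(t)
    io.write_fasta(reads, out / "reads.fa")
    summaries, t = simulate.make_alignment_summaries(cfg)
    truth.merge(t)
    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "identity": r.identity,
                "is_unique": int(r.is_unique),
                "is_duplicate": int(r.is_duplicate),
            }
            for r in summaries
        ]
    ).to_csv(out / "alignments.tsv", sep="\t", index=False)

    tracks, t = simulate.make_evidence_tracks(scaffolds, cfg)
    truth.merge(t)
    geneset.write_models_gff3(tracks["rnaseq"], out / "rnaseq.gff3")
    geneset.write_models_gff3(tracks["homology"], out / "homology.gff3")
    geneset.write_models_gff3(tracks["abinitio"], out / "abinitio.gff3")

    sites, t = simulate.make_site_table(
        genome_length=200_000,
        het_rate=cfg.het_rate,
        depth_mean=cfg.depth_mean,
        n_indels=20,
        seed=seed,
        scaffold=scaffolds[0].id,
        uncallable_frac=0.02,
    )
    truth.merge(t)
    io.write_site_table(sites, out / "sites.tsv")

    pssm = protein_screen.default_motif_pssm()
    pts1 = protein_screen.default_pts1_model()
    data = resources.files("lumigene") / "data"
    (out / "luc_motif.pssm").write_text((data / "luc_motif.pssm").read_text())
    (out / "pts1.pwm").write_text((data / "pts1.pwm").read_text())

    proteins, t = simulate.make_protein_families(cfg, pssm, pts1)
    truth.merge(t)
    io.write_fasta(proteins, out / "proteins_a.fa")
    lengths = {pid: 3 * len(seq) for pid, seq in proteins.items()}
    lengths.update({tid: 1000 for tid in truth.planted_tpm if tid.startswith("bulk")})
    counts = simulate.make_expression(
        truth.planted_tpm, lengths, total_reads=2_000_000, seed=seed + 101
    )
    pd.DataFrame(
        [
            {"transcript_id": c.transcript_id, "length_bp": c.length_bp, "count": c.count}
            for c in counts
        ]
    ).to_csv(out / "counts.tsv", sep="\t", index=False)

    proteome_b, t = simulate.make_ortholog_proteome(proteins, cfg)
    truth.merge(t)
    io.write_fasta(proteome_b, out / "proteins_b.fa")
    cluster_ids = [pid for pid, fam in truth.family_of_protein.items() if fam == "lucfam"]
    order_pairs = [(pid, f"{pid}_B") for pid in cluster_ids]
    order_a, order_b, t = simulate.make_gene_orders(order_pairs, cfg, n_inserted=1)
    truth.merge(t)
    _write_orders(order_a, out / "orders_a.tsv")
    _write_orders(order_b, out / "orders_b.tsv")

    aln, t = simulate.make_divergent_codon_pair(
        length_codons=3000, target_ks=0.10, target_kaks=0.05, seed=seed + 202
    )
    truth.merge(t)
    io.write_fasta({"ACOT1_A": aln.seq_a, "ACOT1_B": aln.seq_b}, out / "codon_pairs.fa")

    config = PipelineConfig(data_dir=str(out), out_dir=str(out / "results"), seed=seed)
    config.to_json(out / "config.json")
    truth.to_json(out / "truth.json")
    return config, truth
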