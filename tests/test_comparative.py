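import math

import numpy as np
import pytest

from lumigene.comparative import (
    CodonAlignment,
    GeneOrder,
    OrthologPair,
    SaturationError,
    global_align,
    ng86_counts,
    ng86_kaks,
    rbh_orthologs,
    synteny_blocks,
)
from lumigene.protein_screen import AMINO_ACIDS
from lumigene.simulate import (
    SynthConfig,
    UnreachableTargetError,
    make_divergent_codon_pair,
    make_gene_orders,
    make_ortholog_proteome,
    make_protein_families,
)

from _oracles import (
    enumerate_alignment_best_score,
    gotoh_global_score,
    ng86_counts_oracle,
    synteny_blocks_oracle,
)


class TestGlobalAlign:
    def test_self_alignment_sums_diagonal(self, aligner, blosum62):
        seq = "MKVLAWGKEVHH"
        res = global_align(seq, seq, aligner)
        assert res.score == pytest.approx(sum(blosum62[c, c] for c in seq))
        assert res.identity == 1.0

    def test_single_residue_mismatch_scores_matrix_entry(self, aligner, blosum62):
        res = global_align("M", "W", aligner)
        assert res.score == pytest.approx(blosum62["M", "W"])

    def test_matches_gotoh_oracle_on_random_pairs(self, aligner, blosum62):
        rng = np.random.default_rng(31)
        for _ in range(40):
            a = "".join(rng.choice(list(AMINO_ACIDS), int(rng.integers(1, 31))))
            b = "".join(rng.choice(list(AMINO_ACIDS), int(rng.integers(1, 31))))
            expected = gotoh_global_score(a, b, blosum62)
            assert global_align(a, b, aligner).score == pytest.approx(expected)

    def test_gotoh_oracle_matches_exhaustive_enumeration_tiny(self, blosum62):
        rng = np.random.default_rng(37)
        for _ in range(10):
            a = "".join(rng.choice(list(AMINO_ACIDS), int(rng.integers(1, 6))))
            b = "".join(rng.choice(list(AMINO_ACIDS), int(rng.integers(1, 6))))
            assert gotoh_global_score(a, b, blosum62) == pytest.approx(
                enumerate_alignment_best_score(a, b, blosum62)
            )

    def test_invalid_residue_rejected(self, aligner):
        with pytest.raises(ValueError):
            global_align("MKV", "MK1", aligner)


class TestRbh:
    def test_copied_proteome_pairs_everything(self, aligner):
        rng = np.random.default_rng(41)
        a = {
            f"g{i}": "".join(rng.choice(list(AMINO_ACIDS), 60)) for i in range(6)
        }
        b = {f"{k}_B": v for k, v in a.items()}
        pairs = rbh_orthologs(a, b, aligner)
        assert {(p.id_a, p.id_b) for p in pairs} == {(k, f"{k}_B") for k in a}

    def test_exact_tie_emits_no_pair(self, aligner):
        a = {"x": "MKVLAW"}
        b = {"y1": "MKVLAW", "y2": "MKVLAW"}
        assert rbh_orthologs(a, b, aligner) == []

    def test_symmetry(self, aligner, motif_pssm, pts1_model):
        cfg = SynthConfig(seed=19)
        proteins, _ = make_protein_families(cfg, motif_pssm, pts1_model)
        sub = {k: proteins[k] for k in list(proteins)[:8]}
        other, _ = make_ortholog_proteome(sub, cfg)
        ab = {(p.id_a, p.id_b) for p in rbh_orthologs(sub, other, aligner)}
        ba = {(p.id_b, p.id_a) for p in rbh_orthologs(other, sub, aligner)}
        assert ab == ba

    def test_planted_orthologs_recovered_paralog_unpaired(self, aligner, motif_pssm, pts1_model):
        cfg = SynthConfig(seed=29)
        proteins, _ = make_protein_families(cfg, motif_pssm, pts1_model)
        proteome_b, truth = make_ortholog_proteome(proteins, cfg)
        pairs = rbh_orthologs(proteins, proteome_b, aligner)
        assert {(p.id_a, p.id_b) for p in pairs} == truth.ortholog_pairs
        assert all(p.id_b not in truth.paralog_ids for p in pairs)


def _orders_and_pairs(genes_a, genes_b):
    order_a = GeneOrder("cA", [(g, "+") for g in genes_a])
    order_b = GeneOrder("cB", [(g, "+") for g in genes_b])
    shared = set(genes_a) & set(genes_b)
    pairs = [OrthologPair(g, g, 1.0) for g in sorted(shared)]
    return order_a, order_b, pairs


class TestSynteny:
    def test_identical_orders_single_block(self):
        genes = [f"g{i}" for i in range(6)]
        oa, ob, pairs = _orders_and_pairs(genes, genes)
        blocks = synteny_blocks(oa, ob, pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert blocks[0].n_gaps == 0
        assert [a for a, _ in blocks[0].pairs] == genes

    def test_insertion_respects_max_gap(self):
        genes = [f"g{i}" for i in range(5)]
        with_insert = genes[:2] + ["filler"] + genes[2:]
        oa, ob, pairs = _orders_and_pairs(genes, with_insert)
        one = synteny_blocks(oa, ob, pairs, max_gap=1)
        assert len(one) == 1 and one[0].n_gaps == 1
        strict = synteny_blocks(oa, ob, pairs, max_gap=0)
        assert len(strict) == 2

    def test_reversed_order_reports_inverted_block(self):
        genes = [f"g{i}" for i in range(6)]
        oa, ob, pairs = _orders_and_pairs(genes, list(reversed(genes)))
        blocks = synteny_blocks(oa, ob, pairs)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_matches_exhaustive_chain_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            perm = rng.permutation(n)
            keep = rng.random(n) < 0.8
            genes_a = [f"g{i}" for i in range(n)]
            genes_b = [f"g{i}" for i in perm if keep[i]]
            max_gap = int(rng.integers(0, 3))
            oa, ob, pairs = _orders_and_pairs(genes_a, genes_b)
            blocks = synteny_blocks(oa, ob, pairs, max_gap=max_gap)
            idx_a, idx_b = oa.index(), ob.index()
            anchors = [
                (idx_a[p.id_a], idx_b[p.id_b]) for p in pairs
            ]
            expected = synteny_blocks_oracle(anchors, max_gap)
            got = [
                (
                    tuple(anchors.index((idx_a[a], idx_b[b])) for a, b in blk.pairs),
                    blk.orientation,
                )
                for blk in blocks
            ]
            assert got == expected

    def test_demo_orders_recover_planted_cluster(self, motif_pssm, pts1_model, aligner):
        cfg = SynthConfig(seed=61)
        proteins, truth = make_protein_families(cfg, motif_pssm, pts1_model)
        cluster = [p for p, f in truth.family_of_protein.items() if f == "lucfam"]
        pair_ids = [(p, f"{p}_B") for p in cluster]
        oa, ob, _ = make_gene_orders(pair_ids, cfg, n_inserted=1)
        pairs = [OrthologPair(a, b, 1.0) for a, b in pair_ids]
        blocks = synteny_blocks(oa, ob, pairs)
        assert len(blocks) == 1
        assert blocks[0].pairs == pair_ids
        assert blocks[0].n_gaps == 1


class TestNg86:
    def test_identical_sequences(self):
        aln = CodonAlignment("a", "b", "ATGGCT", "ATGGCT")
        res = ng86_kaks(aln)
        assert res.Sd == res.Nd == 0.0
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None
        assert res.p_value == 1.0
        assert res.S + res.N == pytest.approx(6.0)

    def test_two_codon_example_matches_pathway_oracle(self):
        aln = CodonAlignment("a", "b", "TTTGGG", "TTCGGG")
        S, N, Sd, Nd = ng86_counts(aln)
        oS, oN, oSd, oNd = ng86_counts_oracle("TTTGGG", "TTCGGG")
        assert (S, N, Sd, Nd) == pytest.approx((oS, oN, oSd, oNd), abs=1e-9)
        assert Sd == pytest.approx(1.0)  # TTT->TTC is synonymous (Phe)

    def test_random_pairs_match_oracle_to_1e9(self):
        for i in range(50):
            aln, _ = make_divergent_codon_pair(30, 0.4, 0.6, seed=1000 + i)
            got = ng86_counts(aln)
            want = ng86_counts_oracle(aln.seq_a, aln.seq_b)
            assert got == pytest.approx(want, abs=1e-9)
            assert got[0] + got[1] == pytest.approx(3 * aln.n_codons, abs=1e-9)

    def test_purifying_selection_signature_at_moderate_length(self):
        aln, _ = make_divergent_codon_pair(400, 0.10, 0.05, seed=77)
        res = ng86_kaks(aln)
        assert res.ratio is not None and res.ratio < 0.3
        assert res.p_value < 0.05

    def test_omega_recovered_at_large_length(self):
        aln, truth = make_divergent_codon_pair(10_000, 0.10, 0.05, seed=13)
        res = ng86_kaks(aln)
        assert res.ratio == pytest.approx(0.05, abs=0.02)
        assert res.Ks == pytest.approx(truth.planted_ks, abs=0.02)

    def test_estimator_bias_shrinks_with_length(self):
        errs = []
        for n in (300, 1500, 6000):
            reps = [
                ng86_kaks(make_divergent_codon_pair(n, 0.10, 0.05, seed=200 + n + r)[0])
                for r in range(3)
            ]
            errs.append(abs(np.mean([r.Ks for r in reps]) - 0.10))
        assert errs[2] < errs[0] + 0.01

    def test_saturation_raises(self):
        # every codon maximally diverged (Phe -> Arg): pN far above 0.75
        aln = CodonAlignment("a", "b", "TTT" * 30, "AGG" * 30)
        with pytest.raises(SaturationError):
            ng86_kaks(aln)

    def test_stop_codon_alignment_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment("a", "b", "ATGTAA", "ATGGCT")


class TestCodonPairGenerator:
    def test_zero_divergence_identical(self):
        aln, _ = make_divergent_codon_pair(50, 0.0, 0.5, seed=1)
        assert aln.seq_a == aln.seq_b

    def test_no_stop_codons_emitted(self):
        aln, _ = make_divergent_codon_pair(500, 0.5, 1.0, seed=5)
        for seq in (aln.seq_a, aln.seq_b):
            for i in range(0, len(seq), 3):
                assert seq[i : i + 3] not in {"TAA", "TAG", "TGA"}

    def test_unreachable_target_rejected(self):
        with pytest.raises(UnreachableTargetError):
            make_divergent_codon_pair(100, 5.0, 1.0, seed=1)
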