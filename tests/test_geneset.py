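import numpy as np
import pytest

from lumigene.geneset import (
    GeneModel,
    GeneSet,
    collect_variants,
    consolidate,
    group_loci,
    merge_abinitio,
    read_gff3,
    select_representative,
    write_geneset_gff3,
    write_models_gff3,
)
from lumigene.simulate import SynthConfig, make_evidence_tracks, make_genome

from _oracles import locus_components_oracle


def model(mid, exons, evidence="rnaseq", strand="+", scaffold="s1", cds=None, confidence="n/a"):
    return GeneModel(mid, scaffold, strand, exons, cds or exons, evidence, confidence)


class TestGroupLoci:
    def test_overlapping_cds_same_strand_one_locus(self):
        loci = group_loci([model("a", [(100, 200)]), model("b", [(150, 300)])])
        assert len(loci) == 1
        assert set(loci[0].members) == {"a", "b"}

    def test_opposite_strands_two_loci(self):
        loci = group_loci(
            [model("a", [(100, 200)]), model("b", [(100, 200)], strand="-")]
        )
        assert len(loci) == 2

    def test_transitive_chain_merges(self):
        loci = group_loci(
            [
                model("a", [(100, 200)]),
                model("b", [(180, 400)]),
                model("c", [(380, 500)]),
            ]
        )
        assert len(loci) == 1 and set(loci[0].members) == {"a", "b", "c"}

    def test_abinitio_rejected(self):
        with pytest.raises(ValueError):
            group_loci([model("a", [(1, 10)], evidence="abinitio", confidence="high")])

    def test_random_inputs_match_union_find_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            models = []
            for i in range(int(rng.integers(1, 15))):
                start = int(rng.integers(1, 2000))
                n_ex = int(rng.integers(1, 4))
                exons = []
                pos = start
                for _ in range(n_ex):
                    end = pos + int(rng.integers(20, 120))
                    exons.append((pos, end))
                    pos = end + int(rng.integers(10, 80)) + 1
                models.append(
                    model(f"m{i}", exons, strand="+" if rng.random() < 0.7 else "-")
                )
            got = {frozenset(l.members) for l in group_loci(models)}
            assert got == locus_components_oracle(models)


class TestRepresentative:
    def test_longest_cds_wins_across_tracks(self):
        a = model("rna1", [(100, 399)])  # 300 bp
        b = model("hom1", [(100, 549)], evidence="homology")  # 450 bp
        assert select_representative([a, b]) == "hom1"

    def test_abinitio_ineligible_even_if_longer(self):
        a = model("rna1", [(100, 399)])
        b = model("ab1", [(50, 649)], evidence="abinitio", confidence="high")
        assert select_representative([a, b]) == "rna1"

    def test_tie_broken_by_start_then_id(self):
        a = model("z", [(100, 399)])
        b = model("a", [(120, 419)], evidence="homology")
        assert select_representative([a, b]) == "z"  # smaller start
        c = model("a2", [(100, 399)], evidence="homology")
        assert select_representative([a, c]) == "a2"  # same start, lex id

    def test_no_eligible_member_is_error(self):
        with pytest.raises(ValueError):
            select_representative(
                [model("ab", [(1, 300)], evidence="abinitio", confidence="low")]
            )


class TestVariants:
    def _locus(self, members):
        loci = group_loci(members)
        assert len(loci) == 1
        return loci[0]

    def test_exact_shared_exon_is_variant(self):
        rep = model("rep", [(100, 200), (300, 400)])
        var = model("var", [(300, 400)])
        locus = self._locus([rep, var])
        assert collect_variants(locus, "rep") == ["rep", "var"]

    def test_overlap_without_exact_exon_dropped(self):
        rep = model("rep", [(100, 200)])
        near = model("near", [(90, 210)])
        locus = self._locus([rep, near])
        assert collect_variants(locus, "rep") == ["rep"]

    def test_tolerant_mode_accepts_shifted_boundaries(self):
        rep = model("rep", [(100, 200)])
        near = model("near", [(98, 203)])
        locus = self._locus([rep, near])
        assert collect_variants(locus, "rep", mode="tolerant", tolerance=5) == ["rep", "near"]

    def test_representative_alone(self):
        rep = model("rep", [(100, 200)])
        locus = self._locus([rep])
        assert collect_variants(locus, "rep") == ["rep"]


class TestMergeAbinitio:
    def _base(self):
        rep = model("rep", [(1000, 1600)])
        loci = group_loci([rep])
        loci[0].representative = "rep"
        loci[0].variants = ["rep"]
        return GeneSet(loci=loci)

    def test_intergenic_high_confidence_added(self):
        ab = model("ab", [(5000, 5300)], evidence="abinitio", confidence="high")
        out = merge_abinitio(self._base(), [ab])
        assert len(out.loci) == 2
        assert out.loci[1].representative == "ab"

    def test_overlapping_high_confidence_not_added(self):
        ab = model("ab", [(1500, 1800)], evidence="abinitio", confidence="high")
        assert len(merge_abinitio(self._base(), [ab]).loci) == 1

    def test_opposite_strand_overlap_still_blocks(self):
        ab = model("ab", [(1500, 1800)], evidence="abinitio", confidence="high", strand="-")
        assert len(merge_abinitio(self._base(), [ab]).loci) == 1

    def test_low_confidence_intergenic_not_added(self):
        ab = model("ab", [(5000, 5300)], evidence="abinitio", confidence="low")
        assert len(merge_abinitio(self._base(), [ab]).loci) == 1

    def test_added_loci_never_overlap_each_other(self):
        ab1 = model("ab1", [(5000, 5300)], evidence="abinitio", confidence="high")
        ab2 = model("ab2", [(5200, 5500)], evidence="abinitio", confidence="high")
        out = merge_abinitio(self._base(), [ab1, ab2])
        assert [l.representative for l in out.loci[1:]] == ["ab1"]


class TestConsolidate:
    def test_noise_free_tracks_recover_planted_truth(self, small_cfg):
        scaffolds, _ = make_genome(small_cfg)
        tracks, truth = make_evidence_tracks(scaffolds, small_cfg)
        # noise-free: exactly one candidate per track per locus
        assert len(tracks["rnaseq"]) + len(tracks["homology"]) == 2 * small_cfg.n_loci
        gene_set = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        got = {
            l.representative: frozenset(l.variants)
            for l in gene_set.loci
            if l.representative not in truth.mergeable_abinitio_ids
        }
        assert got == dict(truth.variant_sets_by_representative())
        merged = {
            l.representative for l in gene_set.loci
        } - set(truth.representative_per_locus.values())
        assert merged == truth.mergeable_abinitio_ids

    def test_noisy_tracks_still_recover_representatives(self):
        cfg = SynthConfig(seed=23, n_loci=30, track_noise=0.3)
        scaffolds, _ = make_genome(cfg)
        tracks, truth = make_evidence_tracks(scaffolds, cfg)
        gene_set = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        got = {
            l.representative: frozenset(l.variants)
            for l in gene_set.loci
            if l.representative not in truth.mergeable_abinitio_ids
        }
        assert got == dict(truth.variant_sets_by_representative())

    def test_empty_abinitio_track(self, small_cfg):
        scaffolds, _ = make_genome(small_cfg)
        tracks, _ = make_evidence_tracks(scaffolds, small_cfg)
        a = consolidate(tracks["rnaseq"], tracks["homology"], ())
        b = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        kept = [l for l in b.loci if l.members.keys() & {m.id for m in tracks["abinitio"]} == set()]
        assert {l.representative for l in a.loci} == {l.representative for l in kept}

    def test_consolidation_is_idempotent(self, small_cfg, tmp_path):
        scaffolds, _ = make_genome(small_cfg)
        tracks, _ = make_evidence_tracks(scaffolds, small_cfg)
        gene_set = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        path = tmp_path / "final.gff3"
        write_geneset_gff3(gene_set, path)
        reread = read_gff3(path)
        again = consolidate(
            [m for m in reread if m.evidence == "rnaseq"],
            [m for m in reread if m.evidence == "homology"],
            [m for m in reread if m.evidence == "abinitio"],
        )
        # isomorphic: same loci spans and member sets
        def shape(gs):
            return {
                (l.scaffold, l.strand, l.span, frozenset(l.members)) for l in gs.loci
            }

        assert shape(again) == shape(gene_set)

    def test_locus_cds_disjointness_invariant(self, small_cfg):
        scaffolds, _ = make_genome(small_cfg)
        tracks, _ = make_evidence_tracks(scaffolds, small_cfg)
        gene_set = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        by_key = {}
        for l in gene_set.loci:
            by_key.setdefault((l.scaffold, l.strand), []).append(l)
        for loci in by_key.values():
            spans = sorted(l.span for l in loci)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_representative_has_maximal_cds(self, small_cfg):
        scaffolds, _ = make_genome(small_cfg)
        tracks, _ = make_evidence_tracks(scaffolds, small_cfg)
        gene_set = consolidate(tracks["rnaseq"], tracks["homology"], tracks["abinitio"])
        for l in gene_set.loci:
            rep_len = l.members[l.representative].cds_length
            for m in l.members.values():
                if m.evidence in ("rnaseq", "homology"):
                    assert m.cds_length <= rep_len


class TestGFF3RoundTrip:
    def test_track_round_trip(self, small_cfg, tmp_path):
        scaffolds, _ = make_genome(small_cfg)
        tracks, _ = make_evidence_tracks(scaffolds, small_cfg)
        path = tmp_path / "t.gff3"
        write_models_gff3(tracks["abinitio"], path)
        back = read_gff3(path)
        assert {(m.id, tuple(m.exons), m.confidence) for m in back} == {
            (m.id, tuple(m.exons), m.confidence) for m in tracks["abinitio"]
        }

    def test_id_collision_renamed(self):
        a = model("dup", [(100, 200)])
        b = model("dup", [(150, 260)], evidence="homology")
        gene_set = consolidate([a], [b], ())
        ids = {tid for l in gene_set.loci for tid in l.members}
        assert ids == {"dup", "homology:dup"}
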