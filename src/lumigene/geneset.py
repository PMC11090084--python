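"""Gene-set consolidation from multi-evidence gene-model tracks.

Three GFF3 tracks of transcript candidates feed the final gene set: RNA-seq
alignments, protein-homology alignments, and ab initio predictions carrying a
high/low confidence flag. Consolidation proceeds per locus:

1. Loci are connected components of same-scaffold, same-strand candidates
   whose CDS segments overlap by >= 1 bp (ab initio models excluded here).
2. The representative is the candidate with the longest CDS among the
   RNA-seq and homology candidates (ties: smaller start, then id).
3. Transcript variants are the candidates sharing at least one exon with the
   representative at exact coordinates (configurable tolerance); candidates
   sharing none are dropped with a warning.
4. High-confidence ab initio models located in intergenic regions (their
   exon span overlapping no locus span on either strand) are merged in as
   new single-transcript loci; all other ab initio models are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Literal, Sequence

import gffutils

__all__ = [
    "GeneModel",
    "Locus",
    "GeneSet",
    "group_loci",
    "select_representative",
    "collect_variants",
    "merge_abinitio",
    "consolidate",
    "read_gff3",
    "write_models_gff3",
    "write_geneset_gff3",
]

logger = logging.getLogger(__name__)

Evidence = Literal["rnaseq", "homology", "abinitio"]
Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One transcript candidate: exons + CDS + evidence class on a scaffold.

    Coordinates are 1-based inclusive (GFF3 convention); exons are sorted and
    non-overlapping. `confidence` is meaningful only for ab initio models.
    """

    id: str
    scaffold: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    evidence: str
    confidence: str = "n/a"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        if self.evidence not in ("rnaseq", "homology", "abinitio"):
            raise ValueError(f"{self.id}: unknown evidence class {self.evidence!r}")
        if (self.confidence != "n/a") != (self.evidence == "abinitio"):
            raise ValueError(f"{self.id}: confidence flag only valid on abinitio models")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            if not ivs:
                raise ValueError(f"{self.id}: empty {name}")
            for s, e in ivs:
                if not (1 <= s <= e):
                    raise ValueError(f"{self.id}: malformed {name} interval ({s}, {e})")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.id}: {name} not sorted/disjoint")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class Locus:
    id: str
    scaffold: str
    strand: str
    span: Interval
    members: dict[str, GeneModel]
    representative: str | None = None
    variants: list[str] = field(default_factory=list)


@dataclass
class GeneSet:
    loci: list[Locus]

    @property
    def transcripts(self) -> list[GeneModel]:
        out = []
        for locus in self.loci:
            out.extend(locus.members[v] for v in locus.variants)
        return out


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def group_loci(models: Sequence[GeneModel]) -> list[Locus]:
    """Group candidates into loci: connected components under same-scaffold,
    same-strand CDS overlap (>= 1 bp between any CDS segments).

    Ab initio models must be excluded by the caller (they are merged later).
    Locus ids are assigned in (scaffold, start) order.
    """
    for m in models:
        if m.evidence == "abinitio":
            raise ValueError(f"{m.id}: abinitio models are not grouped into loci")
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        groups.setdefault((m.scaffold, m.strand), []).append(m)
    loci: list[Locus] = []
    for (scaffold, strand), members in sorted(groups.items()):
        # interval-graph components: sweep CDS segments in start order
        segs = sorted(
            (s, e, i) for i, m in enumerate(members) for s, e in m.cds
        )
        comp_of = list(range(len(members)))

        def find(i: int) -> int:
            while comp_of[i] != i:
                comp_of[i] = comp_of[comp_of[i]]
                i = comp_of[i]
            return i

        cur_end = -1
        cur_root = -1
        for s, e, i in segs:
            if s <= cur_end:
                ra, rb = find(cur_root), find(i)
                comp_of[ra] = rb
                cur_root = rb
            else:
                cur_root = i
            cur_end = max(cur_end, e)
        comps: dict[int, list[GeneModel]] = {}
        for i, m in enumerate(members):
            comps.setdefault(find(i), []).append(m)
        for comp in comps.values():
            span = (
                min(m.span[0] for m in comp),
                max(m.span[1] for m in comp),
            )
            loci.append(
                Locus(
                    id="",
                    scaffold=scaffold,
                    strand=strand,
                    span=span,
                    members={m.id: m for m in comp},
                )
            )
    loci.sort(key=lambda l: (l.scaffold, l.span[0], l.strand))
    for n, locus in enumerate(loci, start=1):
        locus.id = f"locus{n:05d}"
    return loci


def select_representative(members: Iterable[GeneModel]) -> str:
    """The longest-CDS model among RNA-seq and homology candidates.

    Ab initio members are ineligible. Ties go to the smaller start
    coordinate, then the lexicographically smaller id.
    """
    eligible = [m for m in members if m.evidence in ("rnaseq", "homology")]
    if not eligible:
        raise ValueError("locus has no rnaseq/homology member")
    eligible.sort(key=lambda m: (-m.cds_length, m.span[0], m.id))
    return eligible[0].id


def collect_variants(
    locus: Locus,
    representative: str,
    mode: Literal["exact", "tolerant"] = "exact",
    tolerance: int = 0,
) -> list[str]:
    """Members sharing >= 1 exon with the representative, representative first.

    "Sharing" defaults to exact (start, end) coordinate identity; in
    "tolerant" mode both boundaries may differ by up to `tolerance` bp.
    Members sharing no exon are dropped (logged).
    """
    rep = locus.members[representative]

    def shares(m: GeneModel) -> bool:
        for s, e in m.exons:
            for rs, re_ in rep.exons:
                if mode == "exact":
                    if (s, e) == (rs, re_):
                        return True
                elif abs(s - rs) <= tolerance and abs(e - re_) <= tolerance:
                    return True
        return False

    others = [
        m for mid, m in locus.members.items() if mid != representative
    ]
    others.sort(key=lambda m: (m.span[0], m.id))
    variants = [representative]
    for m in others:
        if shares(m):
            variants.append(m.id)
        else:
            logger.warning(
                "locus %s: candidate %s shares no exon with representative %s; dropped",
                locus.id,
                m.id,
                representative,
            )
    return variants


def merge_abinitio(gene_set: GeneSet, abinitio: Sequence[GeneModel]) -> GeneSet:
    """Add high-confidence ab initio models lying in intergenic regions.

    A model qualifies iff confidence == "high" and its exon span overlaps no
    existing locus span on its scaffold, on either strand. Qualifying models
    become new single-transcript loci; models overlapping loci already added
    in this pass are also rejected, keeping loci non-overlapping. All other
    ab initio models are discarded.
    """
    spans: dict[str, list[Interval]] = {}
    for locus in gene_set.loci:
        spans.setdefault(locus.scaffold, []).append(locus.span)
    added: list[Locus] = []
    n_existing = len(gene_set.loci)
    for m in sorted(abinitio, key=lambda m: (m.scaffold, m.span[0], m.id)):
        if m.confidence != "high":
            continue
        if any(_overlaps(m.span, sp) for sp in spans.get(m.scaffold, [])):
            continue
        locus = Locus(
            id=f"locus{n_existing + len(added) + 1:05d}",
            scaffold=m.scaffold,
            strand=m.strand,
            span=m.span,
            members={m.id: m},
            representative=m.id,
            variants=[m.id],
        )
        added.append(locus)
        spans.setdefault(m.scaffold, []).append(m.span)
    return GeneSet(loci=gene_set.loci + added)


def _dedupe_ids(tracks: dict[str, list[GeneModel]]) -> None:
    seen: dict[str, str] = {}
    for evidence, models in tracks.items():
        for i, m in enumerate(models):
            if m.id in seen:
                new_id = f"{evidence}:{m.id}"
                logger.warning(
                    "id %s appears in both %s and %s tracks; renamed to %s",
                    m.id,
                    seen[m.id],
                    evidence,
                    new_id,
                )
                models[i] = GeneModel(
                    new_id, m.scaffold, m.strand, m.exons, m.cds, m.evidence, m.confidence
                )
                seen[new_id] = evidence
            else:
                seen[m.id] = evidence


def consolidate(
    rnaseq: Sequence[GeneModel],
    homology: Sequence[GeneModel],
    abinitio: Sequence[GeneModel] = (),
    variant_mode: Literal["exact", "tolerant"] = "exact",
    variant_tolerance: int = 0,
) -> GeneSet:
    """Run the full consolidation: loci, representatives, variants, then the
    intergenic high-confidence ab initio merge."""
    tracks = {
        "rnaseq": list(rnaseq),
        "homology": list(homology),
        "abinitio": list(abinitio),
    }
    _dedupe_ids(tracks)
    loci = group_loci(tracks["rnaseq"] + tracks["homology"])
    for locus in loci:
        locus.representative = select_representative(locus.members.values())
        locus.variants = collect_variants(
            locus, locus.representative, mode=variant_mode, tolerance=variant_tolerance
        )
    return merge_abinitio(GeneSet(loci=loci), tracks["abinitio"])


# --- GFF3 I/O ---------------------------------------------------------------


def read_gff3(path: str | PathLike) -> list[GeneModel]:
    """Read transcript candidates from a GFF3 track.

    mRNA features carry the candidate id; the `source` column carries the
    evidence class; ab initio records carry a `confidence=high|low`
    attribute. Exon/CDS children are collected by Parent.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        evidence = mrna.attributes.get("evidence", [mrna.source])[0]
        confidence = mrna.attributes.get("confidence", ["n/a"])[0]
        if evidence != "abinitio":
            confidence = "n/a"
        models.append(
            GeneModel(
                id=mrna.id,
                scaffold=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds or exons,
                evidence=evidence,
                confidence=confidence,
            )
        )
    return models


def _feature_line(
    scaffold: str, source: str, ftype: str, start: int, end: int, strand: str, attrs: str
) -> str:
    return f"{scaffold}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def write_models_gff3(models: Sequence[GeneModel], path: str | PathLike) -> None:
    """Write a flat candidate track (mRNA + exon + CDS records)."""
    lines = ["##gff-version 3"]
    for m in models:
        attrs = f"ID={m.id}"
        if m.evidence == "abinitio":
            attrs += f";confidence={m.confidence}"
        lines.append(
            _feature_line(m.scaffold, m.evidence, "mRNA", m.span[0], m.span[1], m.strand, attrs)
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                _feature_line(
                    m.scaffold, m.evidence, "exon", s, e, m.strand,
                    f"ID={m.id}.exon{i};Parent={m.id}",
                )
            )
        for i, (s, e) in enumerate(m.cds, 1):
            lines.append(
                _feature_line(
                    m.scaffold, m.evidence, "CDS", s, e, m.strand,
                    f"ID={m.id}.cds{i};Parent={m.id}",
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_geneset_gff3(gene_set: GeneSet, path: str | PathLike) -> None:
    """Write the consolidated gene set as a gene/mRNA/exon/CDS hierarchy with
    provenance attributes (evidence, confidence, representative flag)."""
    lines = ["##gff-version 3"]
    for locus in gene_set.loci:
        lines.append(
            _feature_line(
                locus.scaffold, "lumigene", "gene",
                locus.span[0], locus.span[1], locus.strand, f"ID={locus.id}",
            )
        )
        for tid in locus.variants:
            m = locus.members[tid]
            rep = "true" if tid == locus.representative else "false"
            attrs = (
                f"ID={m.id};Parent={locus.id};evidence={m.evidence};"
                f"representative={rep}"
            )
            if m.evidence == "abinitio":
                attrs += f";confidence={m.confidence}"
            lines.append(
                _feature_line(
                    m.scaffold, "lumigene", "mRNA", m.span[0], m.span[1], m.strand, attrs
                )
            )
            for i, (s, e) in enumerate(m.exons, 1):
                lines.append(
                    _feature_line(
                        m.scaffold, "lumigene", "exon", s, e, m.strand,
                        f"ID={m.id}.exon{i};Parent={m.id}",
                    )
                )
            for i, (s, e) in enumerate(m.cds, 1):
                lines.append(
                    _feature_line(
                        m.scaffold, "lumigene", "CDS", s, e, m.strand,
                        f"ID={m.id}.cds{i};Parent={m.id}",
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
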