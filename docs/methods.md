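# Methods

This note documents the models and procedures implemented in `lumigene`,
the parameters that matter, what the synthetic data emulate (and what they
do not), and the design choices made where the underlying analysis left the
definition open.

## Assembly QC and heterozygosity

`scaffold_stats` computes total size, scaffold count, N50 and GC%. N50 is
the length of the scaffold at which the cumulative length in descending
order first reaches half the total; GC% excludes N bases from the
denominator. The filter cascade applies, in order: scaffold length ≥ 1000 bp
(the boundary itself kept); mitochondrial read removal at semiglobal edit
distance ≤ 3 ("less than 4"), read aligned end-to-end against either strand
of the mitochondrial reference with free reference ends, computed with a
banded DP (edlib, band = max_edit); alignment retention iff unique ∧
non-duplicate ∧ identity strictly > 0.92; and the callable-site rule —
depth within [mean/2, 2·mean] with inclusive bounds, at least one read per
strand, and not within ±10 bp of an indel (the indel position itself also
masked, so each indel masks 21 positions). Heterozygosity is
100 · SNPs-at-callable-sites / callable bp; with zero callable bases the
estimate is reported as NaN rather than 0 so a degenerate run is visible.

Boundary semantics (inclusive depth bounds, strict identity, kept 1 kb
scaffolds, symmetric indel window) follow the stated inequality directions
literally; where a direction was not stated (depth-bound inclusivity) the
inclusive reading was chosen and is asserted in tests. Upstream mapping,
duplicate marking and variant calling are consumed as a per-site summary
table (scaffold, pos, depth, fwd/rev reads, SNP and indel flags), not
recomputed. Whether the identity is gap-compressed is likewise delegated to
the upstream aligner: the filter consumes a precomputed identity fraction.
Coordinates are 1-based inclusive throughout, matching GFF3.

## Gene-set consolidation

Candidates arrive as three GFF3 tracks (`source` column = evidence class;
ab initio records carry `confidence=high|low`). A *locus* is a connected
component of same-scaffold, same-strand candidates whose CDS segments
overlap by ≥ 1 bp — CDS overlap, not exon overlap, because the
representative rule is about coding length. The representative is the
longest-CDS candidate among the RNA-seq and homology classes (ab initio
candidates are never eligible); ties break deterministically by smaller
start, then id. Variants are members sharing ≥ 1 exon with the
representative at exact coordinates; a boundary-tolerant mode (±k bp) is
available but exact is the default, since "sharing an exon" names a
structure rather than an overlap. Members sharing no exon are dropped with a
warning. Finally, high-confidence ab initio models whose exon span overlaps
no locus span on either strand (the intergenic test is deliberately
strand-agnostic) are merged in as new single-transcript loci; models are
processed in coordinate order and also checked against loci added earlier in
the pass, so merged loci never overlap each other. Consolidation is
idempotent: re-consolidating its own output reproduces an isomorphic gene
set.

## Expression

TPM_i = (count_i/length_i) / Σ_j (count_j/length_j) × 10⁶. The effective
length is the annotated transcript length — no fragment-length correction,
because no fragment model is part of the pipeline's inputs; this is a
documented divergence from assembly-guided quantifiers. An all-zero count
table yields an all-zero TPM table with a warning. Gene-level TPM, used to
attach expression to proteins, is the sum of the gene's transcript TPMs; the
expression screen threshold (TPM > 10, strict) is applied at that level and
is configurable.

## Luc-like screen

Proteins are clustered greedily in descending length order: each protein
joins the first cluster whose representative it matches at identity ≥ 0.30,
else founds a cluster. Identity is matches / full alignment length (gap
columns included in the denominator) from an optimal global affine-gap
alignment — the most conservative of the identity definitions clustering
tools offer. The substitution matrix and gap penalties are configuration
values (defaults BLOSUM62, open 11, extend 1). The ordering is internal
(length, then id), so the clustering is invariant to input order; the
inclusive threshold means a member at exactly 0.30 joins. The
"luciferase-related" cluster is the cluster containing a user-designated
anchor id (LUC1 in the shipped demo).

The Firefly-Luc-like domain motif is scored with a position-specific scoring
matrix over all windows; the hit threshold ships with the matrix file.
Because the authoritative domain PSSM is not reproducible here, the package
ships (a) a loader for any whitespace-delimited PSSM/PWM with a residue
header row and (b) a synthetic fixture PSSM used by the demo and tests; no
claim is made of reproducing CDD scores. PTS1 presence is predicted by a
transparent 3×20 PWM over the C-terminal tripeptide with the canonical
classes [SAC][KRH][LM] weighted highest — a deliberately simple, fully
specified stand-in for species-specific web predictors; only
presence/absence enters downstream logic. Unknown residues (X) contribute 0
in both scans; sequences shorter than the motif width (or than 3 residues
for PTS1) score −∞ and cannot hit.

A protein is *luc-like* iff it is in the anchor cluster, has a motif hit,
and has TPM strictly above 10. PTS1 is annotated but excluded from the
definition by design: the scientifically interesting outcome is precisely a
motif-positive, lantern-expressed candidate lacking PTS1, and the synthetic
families plant several such proteins.

## Comparative stages

**RBH orthology.** All-pairs global affine-gap alignment scores between two
proteomes; (x, y) is an ortholog pair iff each is the unique top score of
the other. Ties for the top score drop the query rather than choosing
arbitrarily — determinism without hidden order dependence.

**Microsynteny.** Anchors are ortholog pairs present in both gene orders.
Blocks are strictly monotone chains (increasing in both orders, or
decreasing in the second for inverted blocks) with at most `max_gap`
(default 2) intervening unanchored genes per step in either genome. Blocks
are extracted greedily — repeatedly take the longest valid chain among
unused anchors — with fully specified tie-breaks (longer chain; forward
over inverted at equal length; lexicographically smallest anchor sequence
within an orientation), so an exhaustive chain-enumeration oracle can check
the output exactly. Single-anchor blocks are suppressed by default.

**Ka/Ks.** The Nei–Gojobori (1986) counting method on gap-free codon
alignments. Sites: at each codon position the synonymous fraction is taken
over the non-stop single-nucleotide changes; per-codon sites are averaged
over the two sequences, so S + N = 3 × codons exactly. Differences:
averaged over the minimal mutational pathways between each codon pair,
renormalizing over pathways that avoid stop intermediates (if every pathway
passes through a stop, all pathways count). Correction: Jukes–Cantor,
K = −¾ ln(1 − 4p/3); p ≥ 0.75 raises a saturation error rather than
returning a complex value. Significance: a two-sided normal-approximation
z-test on pN − pS with binomial variances — not a likelihood test, chosen
because it is fully specifiable and oracle-testable. Identical sequences
give Ka = Ks = 0 with the ratio reported as undefined, not 0/0. NG86 with
this test is a deliberate methodological substitution for model-averaged
Ka/Ks tools; exact replication of any particular tool's output is not
claimed.

## Synthetic data

Every generator is a pure function of (config, seed) via a dedicated
`numpy` Generator stream, so fixed seeds reproduce byte-identical files.
Defaults encode the study conditions: GC 28.4% (the AT-rich firefly
genome), planted heterozygosity 1.0%, mean depth 30×, 50 loci, clustering
families separated far below the 0.30 identity threshold, a
purifying-selection codon pair at ω = 0.05.

- **Genome**: i.i.d. bases with a GC parameter. No repeat structure, no
  k-mer composition, no long-range correlation — repeat modelling is out of
  scope, so passing QC tests says nothing about repeat-rich real assemblies.
- **Evidence tracks**: per locus, the designated best model (all exons) goes
  to the RNA-seq or homology track; the other track receives a truncation
  sharing its exons exactly; an ab initio model overlaps the locus (merge
  must reject it) and intergenic ab initio models are planted in the gaps
  (high confidence: must merge). Track noise adds only shorter,
  exon-sharing candidates, so truth recovery remains exact by construction —
  the generator does not model conflicting gene structures or chimeric
  models.
- **Counts**: multinomial over transcripts with probabilities ∝ planted
  TPM × length, which inverts the TPM formula exactly in expectation.
  Planted expression levels keep a wide margin around the TPM = 10 screen
  threshold so multinomial noise cannot flip a call at the demo depths.
- **Protein families**: per-family residue compositions (Dirichlet-drawn)
  and ~12% within-family mutation keep within-family identity high and
  cross-family identity far below 0.30. Motif-positive proteins carry the
  PSSM consensus verbatim; PTS1 states are planted as canonical or
  clearly non-canonical tails. The second species is made by ~10% point
  mutation per ortholog plus one 40%-diverged paralog that RBH must leave
  unpaired. No indels, domain shuffling, or rate heterogeneity.
- **Codon pairs**: per position, a synonymous change is planted with
  probability pS·f and a nonsynonymous one with pN·(1−f), where f is the
  NG86 synonymous fraction and pS/pN come from the target Ks and Ka through
  the inverse Jukes–Cantor map; stop-creating codons are resampled. Targets
  implying p ≥ 0.70 are rejected as unreachable (the correction is singular
  at 0.75). Expected NG86 counts equal the targets by construction; at
  10,000 codons the estimator recovers ω = 0.05 within ±0.02.
- **Site tables**: Poisson depth, binomial strand split, Bernoulli SNPs; a
  configurable fraction of sites violates the depth/strand rules, and a
  `force_callable` mode clips depths into the callable band for estimator
  calibration runs.

Problem sizes in the shipped demo (~1 Mb genome, 50 loci, 21 + 22 proteins,
200 kb site table, 3,000-codon pair) were chosen so the full pipeline runs
in seconds while keeping every statistical check comfortably powered; the
calibration suites use 1 Mb tables over 100 seeds and a 10,000-codon pair.

## Known limitations

- The synthetic data's idealizations (no repeats, no indels in proteins, no
  structurally conflicting gene models) mean exact truth recovery here does
  not imply exact recovery on real annotation tracks; it validates the
  decision rules, not robustness to upstream noise beyond what is modelled.
- Identity-based clustering uses representative-only comparisons (greedy
  incremental), not the full graph clustering of production tools; with
  min-id 0.30 and well-separated families the result coincides, but dense
  identity gradients could split differently.
- NG86 assumes equal base frequencies and no transition/transversion bias;
  the simulator matches these assumptions, real data do not.
- The heterozygosity estimator inherits whatever biases the upstream variant
  caller has; only the masking and counting are implemented here.
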