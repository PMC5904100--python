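# Methods

This note documents the models and procedures implemented in `amoatax`, the
defaults they run with, and what the synthetic corpus can and cannot show.

## Curation

Raw records pass four screens, each logged with a reason:

1. **Alphabet** — records containing ambiguity codes (N, …) or empty
   sequences are removed, mirroring the exclusion of ambiguous database
   entries from a curated marker-gene set.
2. **In-frame extraction** — the longest stop-free codon run over both
   strands and all three frame offsets; fragments shorter than 194 codons
   (582 nt) are rejected. The floor of 582 nt keeps sequences with up to
   three biological codon deletions relative to the 591-nt common coding
   region. Rejection reasons are decidable without ground truth: below
   582 nt → `short`; length ≢ 0 (mod 3) → `frameshift` (an indel destroyed
   the frame); otherwise → `stop`. Ties between equally long fragments
   prefer the forward strand, then the lower frame offset; a consequence is
   that exact cross-strand ties (palindromes, homopolymers) resolve to each
   input's own forward orientation, so strand invariance is guaranteed for
   fragment length, and for the fragment itself whenever one strand strictly
   wins.
3. **Frameshift screen** — each gene is globally aligned (affine gaps:
   match +1, mismatch −1, open −5, extend −1, free end gaps) to its nearest
   reference by shared 8-mers, excluding itself. Any internal gap run whose
   length is not a multiple of 3 fails; whole-codon gaps are allowed up to 3
   codons in total. This replaces a protein-profile frame corrector with a
   simpler contract that the synthetic corpus can verify exactly.
4. **Global trim** — genes already spanning the 591-column frame pass
   through; genes of 582–588 nt (whole codons) are gap-placed into the frame
   against their nearest full-length neighbour; anything shorter is excluded.
   All synthetic sequences share one frame by construction, so placement is
   columnar bookkeeping; for real data the pipeline accepts an externally
   aligned input instead of shipping an aligner.

Dereplication collapses exact duplicates and keeps multiplicities; the
pipeline is idempotent on its own output.

## Chimera screen

**Reference set.** A sequence is trusted if (a) its exact sequence occurs at
least 5 times in the corpus (chimeras essentially never recur across
independent Sanger libraries), (b) it shares ≥99% identity with at least two
other sequences including one from a different study, or (c) it is flagged as
genome-derived. The admitted set is clustered at 97% identity
(average-neighbour) and medoids are kept.

**Scorer.** For a query Q, the top-k (default 8) reference candidates by
shared 8-mers that clear an 80% identity gate are considered. For every
ordered pair (A, B) and every breakpoint column b, the two-parent model is
`M = A[1..b] + B[b+1..L]`. With `m_QM` the matching columns of the best model
and `m_QT` those of the best single parent,

    d = 100 · (m_QM − m_QT) / L .

Ties in the best model resolve to the smallest b, then the lexicographically
smallest (A, B). The vote score compares, on each side of b, the side's own
parent against the other parent: a column where Q matches the own parent but
not the other votes **yes**, the reverse votes **no**, everything else
abstains; each side scores `Y / (Y + 8·N + 0.5·A)` and `h` is the minimum of
the two sides, so both halves must carry independent chimeric signal. The
decision is *chimeric* iff `d ≥ mindiv` and `h ≥ minh`, with defaults 1.7 and
0.10 — the thresholds tuned for this marker gene in the UCHIME parameter
space whose semantics the scorer preserves. A whitelist of verified false
positives is honoured at the filtering step, and a slot for external
second-opinion labels allows union/intersection filtering with a second
detector without re-implementing it. A branch-length outlier report supports
the manual tree-based chimera hunt; nothing is removed automatically.

With ~5% parent divergence and a central breakpoint, h sits near its decision
boundary (≈0.10–0.13) by construction of the vote weights; the synthetic
generator's parent-divergence window (5–25%) therefore exercises the
threshold honestly rather than trivially.

## OTU clustering

Distances are mismatch fractions over the common frame; columns gapped in
either sequence are excluded from numerator and denominator (configurable to
gap-as-mismatch). Clustering is agglomerative average linkage cut at
1 − identity — merging continues while the minimum average inter-cluster
distance stays within the cutoff — computed via scipy's linkage/fcluster and
checked in the test suite against a naive O(n³) agglomerator. Representatives
are medoids with lexicographic tie-breaks. New sequences map to the highest-
identity representative, unassigned below the threshold (boundary inclusive).

## Taxonomy

Internal branches carry (UFBoot %, SH-aLRT %); a branch survives collapsing
iff UFBoot ≥ 95 **and** SH-aLRT ≥ 85, both boundaries inclusive. Collapsing
contracts the branch and re-attaches its children; it is idempotent and never
removes leaves.

Rank assignment starts from seeded order-level clades — the MRCAs of anchor
leaves carrying the order prefixes (NC, NS, NT, NP) — and recurses: children
with ≥3 leaves are rank-eligible; exactly-2-leaf children are named
`<parent>-IS` (*incertae sedis*); a new rank level opens only when ≥2
eligible children need distinguishing, otherwise the parent is terminal.
Labels are Greek letters at the first level and integers below, handed out in
descending stem-branch-length order ("start from the longest branch",
completed to a full deterministic order with ties broken by leaf count, then
smallest member id). Manual overrides force a rank onto listed clades — the
escape hatch for conspicuously long-branched subclades — and fail loudly if
the listed clade is not monophyletic after collapsing. Singleton leaves carry
the parent's name; leaves outside every seeded order fall into a reserved
bucket. If more than 24 siblings ever need Greek labels the alphabet recycles
with a numeric suffix.

Note that the number of *named* taxa is not monotone in the support
thresholds even though the retained clade set is: collapsing the stem of a
parent's only eligible child splices that child's subclades into the parent,
which can newly satisfy the two-children condition and open a rank level.

Classification of a new sequence takes the most specific taxon of its nearest
OTU representative at ≥96% identity, falls back to the deepest taxon covering
all representatives within a relaxed radius (default 90%), and otherwise
returns *unclassified*. This identity/LCA scheme stands in for
likelihood-based placement, which is out of scope along with tree inference
and post-collapse branch-length re-estimation.

## Tree congruence

For each internal bipartition of a focal tree, `f₁` is its relative frequency
across the candidate set and `f₂` that of its most frequent incompatible
bipartition; with `pᵢ = fᵢ/(f₁+f₂)`,

    IC = 1 + p₁·log₂p₁ + p₂·log₂p₂ ,

negated when `f₂ > f₁`, and 1 when no conflict is observed. This is the
two-most-prevalent normalisation of internode certainty. Frequencies count
trees, not bootstrap replicates; multifurcating candidates contribute each
resolved branch once. Tree certainty is ΣIC over a tree's internal branches;
the candidate with the highest TC is selected (ties: all reported, smallest
serialization returned). Shared-clade checks against a reference tree
classify each linked reference clade as *congruent* (monophyletic),
*compatible* (monophyletic once unlinked leaves are ignored — a formal proxy
for the expert judgement that non-monophyly is attributable to lineages
absent from the reference), or *conflicting*.

## Signatures

GC% and purine% are computed on the degapped coding strand (purine content is
strand-antisymmetric; the coding strand is the defined frame of reference).

**Nc.** Wright's estimator: per synonymous family with n ≥ 2 observed codons,
`F̂ = (n·Σp² − 1)/(n − 1)`; `F̄_k` averages F̂ over the observed families of
redundancy k (families with F̂ = 0 are excluded from the mean — they would
make the class term infinite); then
`Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped into [20, 61]. Met and Trp
(single-codon) are excluded; the 3-codon class is Ile alone under the
standard code; stop codons never count. An empty 3-codon class falls back to
`(F̄₂+F̄₄)/2` (Wright's interpolation); any other empty class falls back to
the uniform-usage expectation 1/k. These conventions are fixed here because
historical implementations differ version to version.

**gCAI.** Relative adaptiveness `w_c = f_c / max f` within each family from
pooled reference counts; codons absent from an observed family get the
pseudo-weight `0.5 / max count` to avoid log 0. The default *iterative* mode
repeatedly scores the references and keeps the best half until the set
reaches max(1% of references, 5) genes or the weights stabilise (L∞ change
< 1e-4), isolating the dominant bias of a heterogeneous reference set; the
mixture-recovery test (90% biased / 10% uniform references) validates the
schedule. *Fixed* mode is provided for cross-checks and genome-reference use.
The index itself is the geometric mean of w over degenerate sense codons.

**OTU deviations.** Per metric, the OTU mean minus the global average, where
the global average is the unweighted mean of OTU means — duplicating genes
inside one OTU cannot move it. SDs are taken over gene-level deviations
within the OTU. Gene-vs-genome relationships use ordinary least squares with
a residuals table exported for external diagnostics.

## Habitat profiles

Categories form a forest of arbitrary depth (e.g. marine → water → depth
zones; soils → pH classes); range-valued pH reports are explicit sibling
nodes (`acidic-neutral`, `neutral-alkaline`). Numeric binning helpers use the
200 m epipelagic boundary and pH 6.5/7.5. The level-fraction rule: at a node,
fractions over its children count only the group's sequences resolved to some
child; sequences annotated exactly at the node are excluded from the
denominator, so adding broader-only sequences never changes child fractions,
and an all-broader-only group is *undefined*, not zero. Hierarchical count
tables propagate multiplicity-weighted counts up both the taxonomy and the
habitat hierarchy (parent count = Σ children + direct members) and export to
Krona-style two-column text that round-trips. Conflicting duplicate
annotations keep the first and log the conflict; a configurable
minimum-count reporting filter mirrors the practice of profiling only
categories with substantial multi-study support.

## Synthetic corpus

The generator emulates the structure of a curated PCR-derived marker-gene
corpus with full ground truth:

- **Tree** — rooted, bifurcating; order-level clades on long (0.15–0.25
  substitutions/site), always-supported stems joined by a supported
  skeleton; within-clade branches 0.03–0.08. A configurable fraction
  (default 0.3) of within-clade branches draws sub-threshold support, with
  the failing measure chosen at random (UFBoot only, SH-aLRT only, or both)
  so each threshold is exercised separately; supported branches draw
  UFBoot ~ U[95,100] and SH-aLRT ~ U[85,100]. The true taxonomy is derived
  by contracting exactly the branches *flagged* unsupported at generation
  time and applying the rank rules — an independent route from the
  support-threshold collapse the pipeline performs.
- **Sequences** — one ancestral 197-codon sequence per clade, drawn from
  codon and amino-acid distributions under a single exponential GC tilt
  solved by bisection so the expected GC equals the clade target; the
  ancestor is additionally rejection-sampled to within ±1 GC point of the
  target so clade means stay ordered even at 6-point target spacing.
  Branches mutate codons with probability 3·μ·t (default μ = 1.0
  substitutions/site per branch-length unit), 90% synonymously, keeping
  clean sequences stop-free and clade composition distinct. Realised clade
  GC tracks the target to within ~2 points.
- **OTU pools** — each tree leaf (OTU representative) is emitted 5 times
  verbatim (so the abundance-≥5 reference rule has substrate) plus noisy
  members at 0.4–1.5% per-site divergence, each tagged with one of 6
  synthetic study labels.
- **Chimeras** — default 10% of the pool, two parents at 5–25% divergence,
  codon-aligned breakpoints uniform in the central 60% of columns (PCR
  template switching between homologous templates preserves frame);
  registry records (query, A, B, b) and chimeras are bit-reconstructable.
- **Corruption** — disjoint fractions of the pool (defaults 3/3/3/2%) get a
  1–2 nt indel, a premature stop at codons 3–193 (so no qualifying frame
  survives), truncation below 582 nt, or an ambiguity code; 20% of records
  are reverse-complemented (logged, not a corruption).
- **Metadata** — per-clade categorical habitat distributions over the
  default category tree; a broader-only fraction (default 10%) truncates
  paths to the parent to exercise the level-exclusion rule.

Everything derives from one integer seed through independent child streams,
so outputs are byte-identical given the seed.

**What the synthetic corpus does not show.** No alignment uncertainty (all
clean sequences share one frame), no realistic PCR error spectrum or
amplification bias, no coalescent-accurate tree shapes, chimeras always have
exactly two parents, and clade composition differences are stronger and
cleaner than in nature. Passing tests demonstrate the pipeline's rules are
implemented correctly and recover planted structure; they do not certify
detection rates on real corpora, where parent divergences, chimera breakpoint
distributions and annotation noise are less favourable.

## Problem sizes

The default corpus is 4 clades × 15 OTUs × 8 sequences (~530 raw records
including chimeras and corruptions) — large enough that every stage has
non-trivial structure (multi-level ranks, 57-member reference DB, 60 OTUs)
while a full pipeline run stays in seconds. Oracle-equivalence suites use
≤12-sequence clustering instances, ≤10-candidate chimera instances on
40-codon genes, and 8-leaf tree sets of 9 trees; taxonomy recovery uses 50
independent trees at 4 × 14 OTUs.
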