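# Methods

## Scope and model

`smorfscape` profiles small proteins (≤100 aa) from per-sample protein-level
metagenomic assemblies. Protein assembly itself (and read preprocessing) is
an external prerequisite: the pipeline's contract starts at an assembled
protein FASTA per sample, with an optional subprocess hook for invoking an
assembler. The pipeline stages are clustering, family calling, variant
observation, embedding, annotation, and quantification; a synthetic-data
module generates benchmark inputs with complete ground truth.

## Clustering

The clustering is a greedy linear-time procedure in the Linclust family:

- **k-mer anchoring.** Each sequence's distinct 10-mers are hashed with a
  keyed 64-bit blake2b (key = `hash_seed`); the m = 20 smallest-hash k-mers
  are selected. Sequences shorter than k contribute nothing and default to
  singletons. k = 10 and m = 20 were chosen so that sequences differing by
  up to ~5% per-residue substitutions virtually always share a selected
  k-mer at typical small-protein lengths (60–100 aa): a 10-mer survives a
  5% mutation rate with probability 0.95¹⁰ ≈ 0.60, so on the order of
  twelve of twenty selected anchors survive in expectation.
- **Centre election.** For each selected k-mer, the sequences sharing it
  form a group; the longest (ties: lexicographically smallest id) is the
  group centre.
- **Verification.** Each sequence is aligned globally (affine gaps, default
  open 11 / extend 1, BLOSUM62, via biotite's optimal aligner) against the
  centres of its groups — at most m alignments — and joins the passing
  centre with the highest score (ties: smallest centre id). A sequence
  passing no centre becomes its own cluster. A centre never competes with
  itself; chains (a centre that itself joined another centre) are flattened
  to a fixpoint, with any cycle broken at its smallest id.
- **Thresholds.** Defaults: identity ≥ 0.8 and bidirectional coverage
  ≥ 0.8 (both inclusive). Coverage modes `target` and `query` are
  available; coverage 0.5 is the documented relaxation for recovering
  strong truncations.

**Identity definition.** Identity = identical columns / aligned
(non-gap-in-both) columns; coverage of a sequence = aligned columns /
its length. Terminal truncations therefore reduce coverage, not identity.
This is the standard convention of modern clustering tools and is the only
definition under which relaxing coverage to 0.5 can rescue half-length
fragments while the default 0.8 coverage excludes them; an identity
denominator that counted gap columns would cap a half-length fragment's
identity near 0.5 and make it unclusterable at any coverage setting.

**Determinism.** Groups, elections, candidate lists and outputs are
processed in sorted order, so the partition depends only on the input
multiset, the parameters and the hash seed — not on input order. The seed
is recorded in the per-sample run manifest.

**Faithfulness.** This is a re-implementation of the linear-time greedy
idea, not a bit-compatible clone of any external tool; correctness is
defined by agreement with the all-pairs brute-force oracle
(`cluster_bruteforce`, greedy set-cover by descending length) on
well-separated inputs and by the mutation/truncation behavior properties.

## Family calling

Three rules, applied to the cluster partition:

1. small = length ≤ `max_small_length` (default 100, boundary inclusive on
   the small side);
2. a cluster containing **any** long member is disqualified outright — the
   conservative reading of "short sequences clustered with long sequences
   are removed", treating such short members as probable fragments of the
   long protein. The permissive alternative (drop only the long members,
   keep the rest) is available as `drop_members_only`;
3. `min_members` = 4: a family must re-occur at least four times in its
   sample. Singleton and small clusters are not used downstream.

## Variant observation

Families are aligned center-star around the representative: each member is
globally aligned to the representative and the pairwise alignments are
merged under "once a gap, always a gap" (insertion blocks are left-aligned
and right-padded with gaps; the insertion slot length at each centre
position is the maximum over members). Center-star is adequate here because
family members are near-identical by construction (they passed a ≥0.8
identity verification against a common centre); no external aligner is
required. Ungapping any row reproduces the member sequence exactly — this
round-trip is asserted in tests.

Per column, conservation = modal-symbol count / family size (gaps count as
symbols). Modal ties prefer the representative's symbol, then any residue
over the gap, then the alphabetically first residue. A variant site is any
column where at least `min_minor_count` (default 1) members differ from the
mode; the package observes candidate mutations but deliberately does not
attach confidence levels to individual substitutions. The consensus
sequence takes the modal residue per column and drops gap-modal columns.

## Embedding and landscape

The embedder interface is a callable `sequence -> D reals`; adapters for
external transformer models (D = 1280 is the conventional dimension)
plug in without any package change, and no model weights ship with the
repository. The built-in `composition` embedder computes the 400-bin
dipeptide-frequency profile (frequencies over observed dipeptides;
X-containing dipeptides ignored; sequences must have length ≥ 2) and
projects it to D dimensions through a fixed seeded projection (exactly
row-orthonormal via QR when D ≥ 400, scaled Gaussian otherwise). It is a
deterministic, CPU-only embedder whose geometry — near-copies of one
ancestor embed close together, unrelated random sequences far apart — is
what the annotation stage requires; it does not claim the semantic
structure of a learned language model.

Batch embedding is order-preserving and bit-identical between parallel and
sequential execution. The landscape is mean-centered PCA via SVD (no
scaling beyond centering), keeping two components, with each component's
sign fixed so its largest-magnitude loading is positive; projection maps
`(x − mean) · componentsᵀ`. Distances throughout are Euclidean on raw
vectors; neither choice is normalized away in the stored metadata.

## Annotation

Database construction: drop entries longer than 100 aa; drop entries whose
name contains "uncharacterized"/"unannotated" (case-insensitive) or that
carry no annotation at all; deduplicate by clustering at 80% identity,
keeping per cluster the most specifically annotated member (EC present >
taxon present > name only; ties to the longest, then smallest id) — the
preference maximizes downstream label yield; embed the survivors.

KNN annotation: k = 10 nearest database vectors (Euclidean; distance ties
to the smallest id; k beyond the database size returns everything). The
label heuristic, applied independently for EC and taxonomy: among neighbors
carrying the field, a unique modal label wins with its count as support; a
frequency tie is broken by the nearest tied neighbor; with no labeled
neighbor the family stays `UNANNOTATED` (support 0). Taxonomy labels can be
normalized to family rank by walking a plain `taxon / rank / parent` TSV
lineage table upward; unknown taxa or lineages without a family rank return
`UNRESOLVED`. Known-gene search aligns query genes against family
representatives (identity ≥ 0.9, bidirectional coverage ≥ 0.8 by default)
and reports per-sample summed family sizes, zero for absent genes.

## Quantification

`c(A) = Σ_{C∈A} s(C) × 10⁶ / Σ_C s(C)` per sample — copies per million
small-protein copies. The denominator includes unannotated families (the
total small-protein copy count of the sample); restricting it to annotated
families is an explicit sensitivity option. Column sums are therefore
≤ 10⁶ with equality exactly at full annotation coverage, and the table is
invariant to scaling all family sizes by a common factor.

The group screen keeps annotations present in every sample, runs one-way
ANOVA per annotation on untransformed values (a `log1p` option exists),
adjusts with Benjamini–Hochberg over all tested annotations, and sorts by
raw p with unique ranks (ties broken by label). All-equal values are
reported as F = 0, p = 1 (the generic ANOVA routine returns NaN there).
Raw-p ranking is retained deliberately — sparse small-protein counts often
fail BH — and q values are always emitted next to p so the caveat is
visible.

## Synthetic data

The generator emulates the structures the pipeline assumes and is the basis
of every quantitative test:

- family ancestors drawn i.i.d. uniform over the 20 residues, lengths
  uniform in 30–100 aa (uniform background; no compositional bias is
  modeled);
- members carry independent per-residue substitutions (default 2%; the
  clustering-tolerance studies sweep 1–8%) to a uniformly random different
  residue, with planted positions recorded;
- optional prefix truncations retaining a stated length fraction (ceil, so
  the fragment retains at least that fraction — relevant exactly at the
  0.5 coverage boundary);
- long proteins (default 120–300 aa) and singleton noise sequences;
- multi-sample studies share the family panel across samples with
  per-sample copy numbers, optional two-group structure, and one
  optionally enriched EC whose carrier families are scaled (default ×3) in
  the enriched group;
- the annotation source emits near-copies (1% mutation) of each annotated
  ancestor with Uniprot-style headers, plus "Uncharacterized protein" and
  over-length decoys to exercise the database filters.

Everything derives from one integer seed and is byte-deterministic,
including emitted files (manifest paths are written relative so generated
study directories are relocatable and comparable). What the generator does
**not** emulate: assembly and sequencing error, real amino-acid
composition, insertions/deletions by default (optional and off), shared
homology *between* families, and database scale. Passing tests therefore
demonstrate the algorithmic contracts — partition correctness, exact
variant recovery, exact copy-number arithmetic, label transfer under
cooperative neighborhoods — not recall on real communities.

## Problem sizes in tests and the acceptance sweep

Test studies use 2–16 samples of roughly 50–90 records (6–10 families),
database sources of tens of entries, and embedding dimensions of 32–64;
these sizes make every behavior assertable exactly against ground truth
while keeping the full suite fast. The mutation-tolerance sweep in
`scripts/acceptance.py` uses 100 proteins × 8 rates × 5 mutant copies
(4,000 co-clustering assessments) with all clustering parameters at their
defaults.

## Known limitations

- Center-star alignment can be suboptimal for families with many distinct
  indels; families here are near-identical, and an external aligner can be
  substituted upstream of `call_variants` if desired.
- The composition embedder cannot separate sequences with identical
  dipeptide composition (e.g. exact repeats of each other); learned
  embedders should be plugged in for real annotation work.
- Quantification is at family-copy resolution; read-level re-quantification
  is out of scope.
- No confidence model for individual variant calls.
- Clusters with fewer than four members, including singletons, are
  discarded rather than down-weighted.
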