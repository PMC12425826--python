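# Methods

This note documents the models, algorithms and numerical choices behind
`pankit`, in the spirit of the methods documentation of toolkits like
msprime or statsmodels: enough detail to know exactly what is computed,
which knobs matter, and where the boundaries of validity lie.

## The coordinate model

All genomes are expressed in one *matrix of corresponding positions*: rows
are accessions, columns are pangenome positions. Each cell holds either a
0-based position on one of that accession's chromosomes or a gap. Three
invariants are maintained and asserted after construction: per accession
the non-gap positions strictly increase along columns, every genome
position occurs in at most one column, and no column is entirely gaps.
Internally all coordinates are 0-based half-open; conversion to 1-based
happens only in the VCF writer. Accessions are inbred lines, so genotypes
are haploid. `N` runs are legal input and never count as matches.

## Pairwise correspondence

1. **Chopping.** The query is cut into consecutive 5,000-bp blocks
   (configurable, minimum 100 bp); a final partial block shorter than
   100 bp merges into its predecessor.
2. **Anchoring.** Each block is searched against every reference chromosome
   on both strands with an internal seed-and-extend aligner: exact 15-mer
   seeds grouped into runs on a single diagonal. Substitutions only delete
   the ~k seeds around them (the diagonal is unchanged), while indels split
   a region into runs on different diagonals, which is exactly the
   granularity the chaining step wants. Run identity is computed by direct
   base comparison (N never matches). Exactly one best hit is kept per
   block — the highest-scoring run, ties broken by lower reference
   chromosome index, then lower reference start. Seeds occurring more than
   64 times in the reference are dropped (satellite/low-complexity guard).
3. **Chaining.** Query-sorted hits join a chain when the gaps in both
   genomes are at most `max_join_gap` (default 20,000 nt, about four block
   lengths — chosen to bridge the largest common TE insertions without
   breaking chains) *and* the two gaps agree to within 8,000 nt. The second
   condition matters: the difference between the gaps is the net indel
   length between the anchors, so a paralogous anchor — a block matched
   against another copy of its repeat family — shows a small query gap but
   a multi-kilobase reference jump and must break the chain rather than
   drag it off-locus. Chains of length 1 are discarded as repeat noise,
   with one exception: a singleton colinear with an already accepted chain
   (typically a lone anchor in a chromosome tail) is rescued.
4. **Acceptance and filling.** Chains are accepted greedily by total score;
   a chain whose query or reference span is mostly (> 50%) covered by
   already accepted chains is a repeat-induced duplicate and is skipped.
   Base-level writing is first-come on both the query and the reference
   side, which keeps the map injective. The sequence between consecutive
   kept anchors (within and between chains) is resolved by a bounded
   second pass: small gap pairs (≤ 1.5 kb) are aligned globally and
   accepted only at ≥ 85% alignment identity — this is what leaves the
   unalignable satellite blocks unmatched — while larger gaps fall back to
   13-mer local hits with recursive fills between them. Chromosome-end
   stubs are aligned with end-anchored (semi-global) alignment, capped at
   `max_join_gap` so a broken chain's territory is never re-aligned
   wholesale. Minus-strand chains are recorded in a separate inversion
   table and excluded from the base-level map; the simulator plants no
   inversions and downstream analysis treats them as a separate small
   class.

## Reference rotation and intersection

`min(4, n)` accessions are rotated as references by default, chosen to be
spread out in k-mer (Jaccard) distance by greedy max-dispersion seeded with
the first accession — spread-out references catch reference bias best, and
more rotations give diminishing returns for their cost. Each rotation
yields a draft matrix whose columns are the reference's positions. The
skeleton keeps the columns where (a) every accession is aligned and (b) the
full correspondence tuple is identical in every draft. Restricting to
all-present columns is deliberate: only those columns *can* agree across
every rotation (each draft is complete on its own reference row), and it
gives the resolver unambiguous per-accession block boundaries. Gap-carrying
draft columns are simply re-derived by the block resolver. Two safety
passes follow: columns whose position deviates from a 51-column rolling
median by more than 5,000 nt are dropped (a single wrong-locus tuple that
survived intersection would otherwise poison the monotonic scan), then a
greedy scan enforces strict per-accession monotonicity.

## Resolving unaligned blocks

Between consecutive skeleton columns (chromosome ends count as anchors),
each accession owns a contiguous unplaced subsequence. If any subsequence
exceeds 30 kb the block is considered highly diverged and every accession's
sequence is kept as accession-private columns — retained, not dropped, so
pan-length accounting stays conservative. Otherwise the block is resolved
by a progressive multiple alignment and its columns spliced in.

The default block aligner is a star alignment against the longest member,
hardened in three ways that all address the same failure mode — alignment
between non-homologous sequence that happens to be similar or cheap:

* **End-walk anchoring.** Exactly matching prefixes and suffixes are fixed
  first. The block is flanked by alignment anchors, so matching ends are
  homologous by construction; a free global alignment of a short member
  against a long center would otherwise tie-score at many gap placements
  and scatter single-base matches.
* **Contiguous-run filtering.** Global (edit-distance) alignments of the
  middles keep only runs of at least 5 consecutive aligned pairs; isolated
  matched singletons under free gaps are noise, not homology.
* **Support-weighted anchoring.** For long centers, members are aligned by
  seeded runs chained colinearly, weighted by how many previously aligned
  members already matched those center positions, and members are aligned
  shortest first. This uses multi-genome consistency to resolve a genuinely
  pairwise-undecidable ambiguity: a truncated mobile-element copy aligns
  verbatim *into* a different full-length copy of its family carried by the
  center, and that wrong alignment outscores the true flank-to-flank one.
  The short members carry no TE copies, vote for the flank first, and the
  consensus then outweighs the repeat match.

A member whose confident pairs cover too little of the block (and with
fewer than 20 exactly matching end bases) is emitted as accession-private
columns instead — this is how mutually diverged satellite members stay
unaligned. When the star alignment still leaves more than 10% of member
sequence unanchored (or rejects members), and MAFFT is available on PATH,
the block is re-aligned with MAFFT and that result is used only if its
column mismatch fraction is at most 0.003 — an order of magnitude above the
true SNP density (~5 × 10⁻⁴ per lineage) but far below the ~10%+ produced
when non-homologous TE copies get smeared together. MAFFT supplies true
member-to-member consistency for large multi-insertion blocks; the gate
keeps its failure mode (forced alignment of unrelated sequence) out.

Finally, columns are stably sorted to be increasing in the first
accession's positions (ties by subsequent accessions, fill-forward keys for
gap entries) and a bidirectional genome-position ↔ column index is built.

## Variant extraction

* **SNPs**: gap-free columns with ≥ 2 distinct bases; columns containing N
  are disqualified in both modes (N is never evidence for or against a
  difference). *Isolated* mode additionally requires both neighbour columns
  gap-free and monomorphic (flank width 1 column; chromosome ends count as
  conserved flanks). Isolated mode suppresses differences manufactured by
  local alignment ambiguity; its count is never above the all-mode count.
* **SV loci**: maximal runs of gap-containing columns. Loci abutting
  chromosome ends are flagged `terminal` and excluded from frequency
  statistics by default (their polarity is unresolvable).
* **Classification**: with `L` the maximum allele length, a locus is sSV
  iff every allele length is `< (1 − s)·L` or `> s·L` (strict
  inequalities), else cSV. `s` is constrained to (0.5, 1]: below 0.5 the
  two intervals overlap and the rule is ill-posed. Relaxing `s` can only
  move loci from cSV to sSV (monotonicity).
* **Polarity**: presence in ≤ 3 accessions ⇒ likely insertion; absence in
  ≤ 3 ⇒ likely deletion; else unpolarized. Unambiguous only when
  n ≥ 2·3 + 1.
* **Consensus allele**: the medoid presence allele (maximal mean global
  identity to the others; a lone allele returns itself).

## Mobile-ome

Presence alleles of sSVs at least 100 nt long enter the nestedness search.
Edge A→B requires merged local hits of A against B to cover ≥ 85% of A at
≥ 85% identity. A semi-global placement of A inside B is used as a fast
path, but accepted outright only when coverage is safe even if every edit
hides uncovered sequence (an unrelated tail of length j costs only ~j/2
edits, so identity alone overstates coverage); marginal cases fall through
to explicit seed-run coverage. Mutually nested nodes (both coverages ≥ the
threshold) merge transitively into single nodes. TE-content categories use
the same 0.85 threshold for both the sequence-coverage fraction (a) and the
best single-element coverage fraction (b) — the threshold is unstated in
the source analysis and reusing the nestedness value keeps one coherent
similarity scale. The ORF scan translates all six frames with the standard
code, splits on stops, and returns all stretches longer than 100 codons,
else the single longest stretch if it exceeds 30 codons, else nothing (a
literal reading of the either/or rule). The protein-hit keyword classifier
is case-insensitive substring matching over fixed keyword lists.

## Summaries

Pan/core curves evaluate, for each sample size k, up to 20 unique subsets
(all of them when C(n,k) ≤ 20; rejection sampling otherwise, seeded): pan =
columns with ≥ 1 aligned member, core = columns with all members aligned;
sample standard deviation reported, 0 for a single subset. Note pan(1) =
core(1) = that genome's aligned length by definition — private sequence is
part of a single genome's core. Dilation emits (column, reference position)
pairs for the columns where the chosen reference is aligned. Pairwise
divergence counts differing gap-free columns (SNPs) and sSVs where exactly
one of the pair holds the presence allele, binned by presence-allele length
with fixed edges 1, 15, 100, 500, 1000, 5000, 20000 nt.

## Concordance and call taxonomy

Truth (whole-genome-alignment) SNPs classify as TP if called, uncalled if
the site lacks read coverage, else FN; calls classify as FP_het if
heterozygous (inbred lines — heterozygous calls are errors by
construction, and heterozygosity takes precedence over a truth match), TP
if in the truth, FP at a bona fide non-SNP if the site is aligned, else FP
at an unaligned site. FDR = all FP flavours / all calls (reported as
missing, never 0, when there are no calls); FNR = FN / (TP + FN), i.e.
uncovered sites do not enter. Expression concordance: excluded when
max(counts) < 6, discordant when min/max ≤ 0.7. Methylation level =
methylated / (methylated + unmethylated) reads — the ratio must lie in
[0, 1] for the min/max rule to be meaningful — missing when no reads;
concordance: excluded on missing, both-zero is concordant (equal),
discordant when min/max ≤ 0.5. Quantile normalization maps x to
(x − q20)/(q80 − q20) with type-7 (linear interpolation) quantiles — the
estimator matters because q20/q80 depend on it — and rejects constant
input.

## Gene ancestry

A group's homolog is the outgroup gene hit by ≥ 50% of members at ≥ 80%
identity and ≥ 80% coverage of the focal coding sequence (ties: higher
share, then higher mean identity, then gene id). Consecutive assigned
groups join a colinear segment when their homologs' outgroup ranks differ
by strictly less than 6 (strand ignored); unassigned groups break segments.
Membership in a segment of ≥ 2 groups ⇒ ancestral in position and
sequence; a homolog without such synteny ⇒ similar; none ⇒ non-ancestral.
Where members hit different outgroup genes, the single best-supported gene
wins for the whole group.

## The simulator

The synthetic pangenome defines the study conditions: by default 8
accessions from a 2 × 300 kb uniform-random ancestor under a star genealogy
(each accession mutated independently — the simplest model under which "a
presence allele in one accession is an insertion" is literally true), with
per-lineage SNP rate 5 × 10⁻⁴, 60 TE insertions drawn from a generated
6-family library (400–6,000 nt consensuses, pairwise global identity < 0.6
enforced by rejection sampling; 70% of insertions complete, 30% truncated
to a uniform 0.2–0.8 fraction), 40 deletions of 15–2,000 nt, and 4
satellite blocks (tandem unit ≤ 180 nt). Structural events are mutually
non-overlapping with a ≥ 50 nt margin; SNP sites are globally unique and
avoid structural intervals, with per-lineage Binomial(L, rate) counts so
the total matches n·L·rate in expectation. Carrier sets for structural
events are geometric-sized (p = 0.5, capped at n − 1), so shared derived
alleles — and hence the frequency-polarity logic — are exercised even
under the star genealogy. Satellite blocks are re-randomized per accession
(independent 25% per-site divergence, independent copy number), making
every pairwise identity ~0.55–0.60, well under the 0.85 alignment
threshold, i.e. genuinely unalignable. Simulated read-mapping call sets
drop covered truth SNPs with the target FNR, add false calls at non-truth
sites in a ratio targeting the FDR, remove coverage from a fraction of
sites, and inject heterozygous calls.

What the simulator does **not** model: base-composition bias, indel
sequencing error, recombination and linkage (no coalescent), segmental
duplications beyond TE copies, inversions and translocations, nested TE
insertion *within* planted insertions, and assembly error. Passing tests
therefore demonstrate correctness of the algorithms under idealized
assembly input, not robustness to misassembly or to repeat structures
richer than TE families plus satellite arrays.

## Problem sizes and verification

The end-to-end checks run the default study conditions above (one CPU,
roughly two minutes for the full pipeline). Under seeds 1, 2, 3, 7 and 11
the pipeline reaches SNP sensitivity 0.97–0.98 and precision ≥ 0.999
outside satellite blocks, recovers 94–100% of planted structural events as
sSVs with breakpoints within ±20 columns, polarizes recovered singleton
events 100% correctly, and clusters recovered insertions into nestedness
components that match the planted family labels with adjusted Rand index
1.0. The sSV classifier and the ORF scanner agree exactly with independent
brute-force oracles; planted FDR/FNR (0.07/0.20) are recovered within
exact binomial 99% intervals pooled over 50 replicates of 10,000 SNPs.

## Known limitations

* Clusters of several same-family TE events within a few kilobases can
  still collapse into complex loci — nearby events genuinely reclassify
  simple polymorphisms as complex, and the detector inherits that.
  The support-weighted MSA resolves most but not all cases.
* SNPs within ~5 bp of an indel breakpoint are occasionally assigned to a
  neighbouring column (alignment ambiguity); they account for most of the
  residual sensitivity gap.
* Inversions are detected and reported but not genotyped or entered into
  the coordinate matrix.
* The intersection requires all-accession presence, so regions deleted in
  even one accession are handled entirely by the block resolver; with many
  accessions and high deletion density the resolver does proportionally
  more work.
* Chromosome correspondence assumes each accession uses one source
  chromosome per pangenome chromosome (no translocation resolution).
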