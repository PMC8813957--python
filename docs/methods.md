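# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `pansv`, in the order the pipeline runs.

## Synthetic data

The generator produces i.i.d.-composition DNA (configurable GC), implants
non-overlapping variants by rejection sampling with a minimum spacing of
500 bp and a 2 kb chromosome-edge margin, and records truth in both
reference and derived coordinates. Implanted pure InDels are
left-normalized at generation time so truth and calls share one
representation. Variant classes: SNPs; small InDels 1–49 bp; canonical
InDels 50–1000 bp by default; complex replacements (50–300 bp of reference
replaced by an unrelated 50–500 bp sequence, lengths resampled until they
differ); inversions 5–50 kb; translocations 2–10 kb excised and
re-inserted elsewhere (another chromosome when available). Paired-end
reads are placed uniformly with Normal(insert, 0.1·insert) fragment
lengths and substitution errors only — no indel errors, adequate for the
depth and genotyping stages these reads feed. Truth placements are kept
per pair; "mapping" a read set to the other genome of a pair is simulated
by projecting placements through the unchanged-segment map (pieces < 20 bp
are dropped, mimicking clipped alignments).

Population panels are haploid-style (selfed inbred lines): genotype codes
0/2, with a diploid mode (binomial sampling, code 1 for hets) for the
genotyper's heterozygous path. Per-site wild/cultivated alternate-allele
frequencies are configuration — the allele-frequency spectrum is not
asserted. Expression tables are log-normal around 20 TPM with
multiplicative noise (σ = 0.05); implanted fold-changes are applied
exactly to the cultivated mean so recovery tests have a sharp target.

What this emulates — and what it does not: there is no repeat landscape,
GC heterogeneity, or sequencing-error structure, so anchor and flank
uniqueness is the common case. Passing tests demonstrate the correctness
of the algorithms under unambiguous alignment conditions, not performance
on repeat-rich real genomes.

## Whole-genome alignment

Seeding uses maximal exact matches whose seed k-mer (k = `min_anchor_len`,
default 20) is unique in the reference (MUM-like), found by a 2-bit
rolling-code index and stride-k/2 query scanning with maximal extension in
both directions; N never matches. Both query strands are scanned;
minus-strand features are stored on the forward query strand with a strand
flag.

Anchors co-linear within `max_anchor_gap` (default 1500 bp) on **both**
genomes merge into alignment segments; inter-anchor gaps are globally
aligned (edlib) and retained on the segment for later diffing. The gap
bound is deliberately larger than the default canonical-InDel range
(≤ 1000 bp) and smaller than the smallest rearrangement the generator
emits, so pointwise variants stay inside segments while inversions and
translocations force segment boundaries; larger InDels simply become
inter-segment gaps within a block and are still called. Identity is
matches over alignment columns, with columns approximated by
max(len ref, len qry) per gap (exact when edits are substitutions only).

One-to-one filtering drops segments below 90% identity or 200 bp, then
keeps the maximum-weight (identity × length) conflict-free subset: exact
branch-and-bound inside conflict components of ≤ 20 segments, greedy by
weight above that, ties toward the leftmost reference coordinate. Overlaps
of ≤ 30 bp are not conflicts — they arise when two maximal matches extend
into the same junction homology — and are trimmed diagonally afterwards,
so the final set is strictly non-overlapping on both genomes (a tested
invariant). Same-strand, order-consistent segments with gaps ≤ 50 kb on
both genomes chain into collinear blocks.

Rearrangements: per reference chromosome, the dominant query partner is
the chromosome with the largest aligned span; a maximum-weight increasing
run of query positions among plus-strand blocks defines the in-place
backbone. Minus-strand blocks are inversions (< 1 Mb) or megabase-scale
inversions (≥ 1 Mb, reported separately); a flip without in-place context
on both sides is flagged low-confidence rather than dropped. Blocks off
the backbone are intra-chromosomal translocations; blocks on a
non-dominant partner are inter-chromosomal; translocated segments
containing N are excluded. Inversion spans can exceed the truth interval
by a few bases of chance junction homology; breakpoint-exactness is
therefore only claimed for canonical InDels, which are normalized.

## Variant discovery

All differences live in the stored gap pairs (within segments) and
inter-segment gaps (within blocks). Each gap pair is globally aligned and
decomposed at exact runs ≥ `wordsize` (default 10); shorter exact runs do
not anchor and are absorbed into the flanking difference — this is what
turns a genuinely divergent replacement into one complex pair instead of
a cloud of micro-calls. Alleles are then trimmed to their minimal
representation (longest common prefix/suffix removed), which also
reverses the absorption of chance-matched flank bases; equal-length
differences decompose into per-base SNPs (an equal-length pair ≥ 50 bp
with > 50% mismatches — e.g. an undetected strand flip — is left
uncalled); pure InDels are left-normalized.

Classification follows the 50 bp boundary with 50 bp on the SV side.
Unequal-length replacements below 50 bp fold into the small-InDel classes
with both alleles preserved; equal-length substitutions longer than 1 bp
are rejected by `classify_variant` because the diff layer always
decomposes them first.

Complex calls are refined by re-aligning their 1 kb flanks: if the window
decomposes to a single pure InDel between perfectly collinear flanks
(anchor run ≥ 20), the call is promoted to canonical with updated,
left-normalized coordinates; allele content is conserved by construction.
Calls whose reference or query footprint lies mostly (> 50%) inside a
detected inversion or translocation are artifacts of that rearrangement
(a translocation surfaces as a deletion at its source plus an insertion at
its destination) and are suppressed before refinement.

Exclusion filters: SV alleles containing N are removed (counts reported
per class); positions with a quality-passing self-inconsistency (base
quality > 20, mapping quality > 30, 2 < depth < 200, matched in
query-genome coordinates) mask their variants.

Microhomology at a deletion is the longest k ≤ 25 with
`ref[start:start+k] == ref[end:end+k]` (right) or the mirrored left
check, capped at the deletion span; the longer side is reported, `both`
when equal and identical.

Gene-overlap annotation labels CDS-SV > promoter-SV (default window
3 kb upstream of the strand-aware TSS) > intron-SV > intergenic. A pure
InDel of length L fully inside one CDS exon with L ≡ 0 (mod 3) at a codon
boundary is in-frame (±L/3 amino acids); anything else touching CDS is a
frameshift.

Identifiers follow `SV_{INS|DEL|COMINS|COMDEL|INV|TRANS}_{chrom}G{index}`,
index assigned in reference-sorted order, zero-padded to six digits.
Duplicate calls from adjacent blocks are removed by identical
(chrom, start, end, alt, class).

## Read-depth support

Depth counts read placements with mapping quality ≥ 20 after collapsing
identical pair placements (PCR duplicates). Coverage is the arithmetic
mean of per-base depth, zeros included; flanks truncated at chromosome
ends are used at their reduced length. The rule:
`supported = flank_mean > 3 × region_mean AND region_mean < 3`, with the
fold ratio defined as +∞ when the region mean is 0 (supported — the
limiting case of "more than threefold"). Insertions are evaluated after
`swap_reference`, which exchanges the reference/query roles; the swap is
an exact involution for every precise SV. An external SAM/BAM can replace
simulated placements (`depth_from_sam`), with the same filters.

## Variation graph and genotyping

Reference chromosomes are split at the union of SV boundaries; deletions
add one bypass edge, insertions/replacements one alternative node with
two edges, inversions reuse the reference nodes with reversed-orientation
edges. Translocations are not part of the graph. The reference path
reproduces each chromosome byte-for-byte and every alternative subpath
spells exactly the SV's alternate allele between shared flanking nodes
(both tested invariants). GFA 1.0 output carries SN/SO tags on reference
nodes; write∘read∘write is idempotent (sites are an in-memory construct
and are not serialized).

Genotyping is allele-path re-alignment, not general graph alignment: for
each site the ref and alt spellings (allele plus 160 bp of reference-path
flank) are compared, and the k-mers (k = 31) private to one spelling
distinguish the alleles — exactly the breakpoint-spanning and
allele-internal content. A read (scanned at k-mer stride 7, both
orientations) supports an allele when it carries distinguishing k-mers of
that allele only; reads with mapping or base quality < 5 are excluded.
Genotype by alternate support fraction: ≥ 0.8 alt/alt, ≤ 0.2 ref/ref,
otherwise ref/alt (flagged as a conflict in haploid panels); fewer than 3
informative reads is missing. The 0.8/0.2 thresholds and the minimum
support are configurable design choices. Concordance against truth is
strict: a missing call counts as discordant.

## Selection statistics

π per window is Σ_sites 2p̂q̂·n/(n−1) divided by the window length
(unbiased per-site heterozygosity from haplotype counts; monomorphic
sites contribute 0), tiled at 10 kb/10 kb by default. Sweep windows are
the top floor(n·5%) by π_w/π_c (ties toward the lower coordinate; an
undefined ratio with π_c = 0 < π_w sorts as +∞), intersected with the top
set of any supplied per-window statistic (an externally computed XP-CLR
track fits here; π-ratio-only results are labeled by the absence of that
track), then merged when adjacent. dSV requires strictly more than 50%
of the SV's reference extent inside a sweep; zero-extent insertions count
by their anchor position. hdSV uses a two-sided Fisher exact test on
carrier counts (any alternate allele; missing calls leave the margins),
BH-corrected across all testable SVs, significant at FDR < 0.01.
π-ratio annotation flags an SV when its midpoint window has ratio ≥ 3
(π_c = 0 treated as +∞). The expression screen computes per-tissue
log₂((cult + 1)/(wild + 1)) for CDS- and promoter-context SV–gene links
(pseudocount 1 TPM stabilizes low expression) and flags |log₂FC| ≥ 1.5 in
any tissue.

## Pan-gene analysis

Pairwise similarity aligns the shorter CDS as an infix of the longer
(edlib HW): identity = matching columns / alignment columns, coverage =
columns where the shorter aligns to actual bases / shorter length — so a
truncated copy still reaches its family while the 95% identity bound
rejects diverged paralogs. Qualifying pairs (identity ≥ 0.95 AND coverage
≥ 0.50) are single-linkage clustered via union–find; the result is a
partition invariant to input order. Core means every accession present;
representative selection prefers the reference accession's gene, then the
longest CDS, then the lexicographically smaller id. Accumulation curves
count cumulative union (pan) and intersection (core) cluster totals over
seeded random orderings; per-ordering monotonicity and endpoint equality
are tested laws. Enrichment is a one-sided (over-representation) Fisher
test per term against the background, BH-corrected, significant at
FDR < 0.05.

## Statistical primitives

Fisher exact p-values come from `scipy.stats.fisher_exact` and BH
q-values from `statsmodels` (`fdr_bh`); both are verified in the test
suite against independent oracles — exhaustive hypergeometric tail
summation over all 2×2 tables with margins ≤ 30 (deduplicated by table
symmetry) and the hand-coded step-down formula q_i = min_{j≥i} p_(j)·m/j.
π is verified against direct mean-pairwise-difference enumeration for up
to 8 haplotypes.

## Problem sizes and determinism

The packaged evaluation runs at: 5 Mb (2 × 2.5 Mb) with 200 implanted
variants for caller recovery; 20 accessions × 50 SV sites on 200 kb at
error-free 20× for genotyping; 20 deletions/insertions on 300 kb at 30×
for the RD rule; 1 Mb, 10 000 sites, 20 + 20 haplotypes with a 50 kb
implanted sweep (10× cultivated diversity reduction) for the sweep scan.
These sizes exercise every code path with comfortable statistical margins
while keeping the full suite fast on a single CPU. Every stochastic
component takes an explicit seed; the full pipeline is deterministic
given one.

## Known limitations

- Anchor uniqueness is resolved in the reference only; repeat-rich
  regions of real genomes would fragment into unanchored gaps rather than
  mis-align, and recall there would fall.
- Variants nested inside inverted (minus-strand) blocks are not diffed;
  the generator never nests variants, so this costs nothing at the study
  conditions but matters for real inversions carrying internal variation.
- Translocation breakpoints are block-resolution, not base-resolution.
- Identity scoring approximates alignment columns by the longer gap
  length; exact column counting would lower identity slightly for
  indel-rich gaps.
- The graph genotyper is site-local; reads informative only through
  multi-site haplotype context are not used.
- XP-CLR is consumed as an optional external track, never computed.
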