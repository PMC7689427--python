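# Methods

## The identity model

All callers work on the match fraction of an alignment,
`identity = 100·(1 − mismatches/length)`, where `mismatches` counts SNP
and small-indel columns. The central calibration is the expected identity
between two sequences that diverged t years ago at per-site substitution
rate r: substitutions accumulate on both lineages, so

    E[identity] = 100·(1 − 2·r·t)

With the wheat repetitive/intergenic rate r = 1.6×10⁻⁸ nt⁻¹ yr⁻¹ and
t = 10,000 yr (roughly the age of the domesticated wheat gene pool) this
is 99.968%. The IBS threshold of 99.99% — one mismatch per 10 kb — is
deliberately *stricter* than that: sequence pairs at the 10-kyr
divergence level are classified "near-identical", not shared haplotype,
while the residual 0.01% allowance absorbs Ns and base errors in
low-complexity runs. Introgressions from wild relatives sit far below
both (< 99.5%).

## Whole-chromosome caller

1. Drop alignments < 20 kb (`min_aln_len`). Short alignments are
   dominated by non-syntenic retrotransposon matches (median ~9.6 kb in
   wheat) that carry no haplotype signal.
2. Assign each surviving alignment to the fixed-width bin (default
   5 Mbp; 2.5 and 1 Mbp for finer resolution) containing its reference
   midpoint ⌊(start+end)/2⌋. One alignment contributes its identity to
   exactly one bin — no double counting, matching midpoint-scatter
   semantics.
3. A bin is IBS when the **median** of its raw alignment identities
   (unweighted by length) is ≥ 99.99%. The ≥ comparison uses a 10⁻⁹
   guard on the percent scale; identities derive from integer mismatch
   counts, so exactness is well defined.
4. Stitching: consecutive IBS bins join into one block; runs of at most
   `max_err_run = 2` non-IBS bins between IBS bins are absorbed. Empty
   bins count as errors — N gaps legitimately empty a bin inside a true
   block. Blocks begin and end on IBS bins (no dangling error bins), and
   a single IBS bin is a valid block. The implementation is tested for
   exact agreement with brute-force enumeration of maximal valid runs
   over all bin vectors up to length 12.
5. Where both alignment directions exist, a block survives only if its
   lifted interval overlaps (≥ 1 bp) a block of the reciprocal
   direction. The overlap rule is the package's choice; any-overlap is
   the weakest consistent reading and is applied symmetrically.

Two readings of the stitch rule were open: the two-error allowance could
be per error run (implemented) or per block total, and edge absorption
could be permitted. We require per-run ≤ 2 and IBS-bin block edges,
which reproduces worked examples such as G,B,B,G → one block and
G,B,B,B,G → two single-bin blocks.

## Gene-window caller

Gene projections shared by all assemblies anchor a caller that needs no
whole-chromosome alignment (scaffold-level assemblies). Per gene pair the
largest HSP is kept (ties: bitscore, then identity); genes are dropped
when their projection count on the expected chromosome differs from one
or when the aligned sequence contains Ns. Windows of W = 25 consecutive
*surviving* genes (filtered genes are bridged, not window-breaking) are
scanned at step 1; the ⌈0.10·W⌉ = 3 lowest identities are trimmed and the
window is IBS iff the remaining mean equals 100% (10⁻⁹ tolerance).
Identical windows merge into maximal gene runs; a run spans the full
extent of its terminal genes and is lifted into each assembly's own
coordinates.

Combination rule: all whole-chromosome blocks, plus gene-window blocks
except those that overlap a whole-chromosome block *and* are shorter
than the bin size ("already represented"). Precision = fraction of
gene-window blocks overlapping ≥ 1 whole-chromosome block; recall = the
converse; F1 = 2PR/(P+R), with empty sets flagged and scored 0.

## Gene-anchored liftover

Anchors are the genes overlapping the source interval that project
unambiguously (exactly one placement) in both assemblies. Sorted by
target position, anchors join into runs while the gap in the target's
chromosome-wide projected-gene rank is ≤ 20 genes; the gap metric is the
package's choice (the rank order is what the sort establishes). Runs
with ≥ 10 genes are reported; if none qualifies, the single longest run
is returned with status `longest_only`. Run coordinates are the min/max
of member gene spans; orientation is ignored.

## Sharing, conservation and positional summaries

Pairwise sharing is the unioned block bp divided by the reference
cultivar's chromosome/genome size. Across cultivars, per-partner block
unions feed a sweep-line coverage profile counting partners per
position; coverage ≥ 1 gives "% of genome in at least one block" and
coverage ≥ 5 defines highly conserved regions (≥ 6 cultivars including
the reference), with positions also reported as % of chromosome length
for cross-assembly comparison.

Positional block statistics sample each chromosome every 500 kb (a block
registers at every grid point it spans, so a 5-Mb block appears at 10–12
points), scale positions to % chromosome length, take per-chromosome
medians in 1% bins, and aggregate bins into the R1/R2a/C/R2b/R3
recombination compartments supplied as a four-boundary TSV per
chromosome. Compartment medians are medians of chromosome-level bin
medians; min/max come from raw samples. Group contrasts use Mann–Whitney
rank tests with Benjamini–Hochberg adjustment (scipy/statsmodels).

## Sequence complexity

Complexity of a SNP ± 10 bp flank is the Shannon richness of overlapping
k-mers (k = 2): exp(−Σ pᵢ ln pᵢ) over the 2·10+1−k+1 k-mer frequencies,
i.e. the effective number of k-mer species, between 1 (homopolymer) and
min(4ᵏ, n_kmers). Whether the reference convention uses overlapping or
disjoint k-mers and which log base is not fixed by the source; the
implementation uses overlapping k-mers and natural logs and exposes
`as_entropy` for the raw entropy. Flanks containing N are excluded
before computation. In-block vs out-of-block comparisons subsample
10,000 SNPs per category (whole category when smaller) under a fixed
seed and use a two-sided rank-sum test.

## Marker panels and group assignment

Group profiles come from exemplar lines over the markers inside the
minimum haplotype block; markers with inconsistent calls among replicate
exemplars are excluded, and groups with coinciding profiles merge into a
single resolvability class ("H1/2"). Line assignment matches non-missing
calls against each profile: one match → that group; several → merged
label; none → novel labels N1, N2, … by first appearance; call rate
below 80% → unassigned. The missing-call semantics are parameterised
because no canonical rule exists.

Panel design greedily adds the marker maximising the minimum pairwise
Hamming distance between group profiles (capped at the target of 3),
breaking ties toward the marker that most reduces the largest positional
gap across the block, until every pair differs at ≥ 3 markers. Greedy
selection is not guaranteed minimal in general but meets the ≥ 3
constraint whenever the full candidate set does (checked directly), and
its output is verified against brute-force minima on small instances in
the tests.

## Synthetic pangenome

The generator draws an ancestral chromosome uniformly over ACGT and
derives each cultivar by i.i.d. per-site substitutions (no indels).
Defaults encode the study conditions above:

* background per-pair divergence 3.2×10⁻⁴ (= 2·1.6×10⁻⁸·10⁴; each
  lineage substitutes at half that), the near-identical level;
* planted IBS blocks: member cultivars share one substitution draw over
  the interval, so within-block identity is exactly 100%;
* introgressions at 0.7×10⁻² divergence;
* purifying selection: substitution probability inside gene bodies is
  scaled by `genic_divergence_factor = 0.1`, so genic sequence
  under-reports divergence — the mechanism that makes CDS-only window
  calling imprecise and flanking sequence informative;
* gene density 8 per Mbp with 3-kb genes (wheat-like), collinear
  projections across cultivars;
* N runs as specified, which fragment alignments.

Alignment records are emitted by construction: collinear segments broken
at N runs and at random fragmentation breakpoints (mean spacing 100 kb,
with ~5% of cuts opening bursts of 5–19 kb fragments so the ≥ 20 kb
filter has work to do), each carrying the exact mismatch count of its
span. Gene BLAST tables, SNP lists against the first cultivar and a
genotype matrix over subsampled SNP positions are derived from the same
sequences. All randomness flows from one seeded generator in fixed
order; identical spec + seed gives byte-identical outputs.

What the generator does **not** emulate: indels and structural variants
(only emulated via record segmentation), recombination/coalescent
genealogies, transposon turnover, polyploid homoeology, and real
aligner artefacts. Passing recovery tests therefore demonstrate the
callers' correctness under the stated divergence model, not robustness
to assembly error or alignment noise.

## Problem sizes and numerical choices

The test suite runs the recovery property on twenty 25-Mb two-cultivar
replicates (10-Mb planted block, 2.5-Mb bins — bin ≤ block/4) and the
remaining properties on a shared 12-Mb three-cultivar fixture; the
acceptance script uses the same 12-Mb design. These sizes keep full runs
in minutes while leaving dozens of bins and hundreds of alignments per
chromosome, ample resolution for every rule being exercised. Floating
comparisons at thresholds use a 10⁻⁹ guard; ties in HSP selection,
longest-run fallback and panel design are broken deterministically
(documented order, then input order) so all results are reproducible.

## Known limitations

* The whole-chromosome caller reports block bounds at bin resolution;
  true breakpoints inside a bin are not refined.
* Reciprocal filtering needs a lifter; for scaffold pairs only the
  gene-window caller applies, as in the motivating study.
* The liftover assumes gene order is locally preserved; large
  rearrangements fragment lifts into runs rather than failing loudly.
* Genome-size denominators are taken from the supplied size table;
  unplaced scaffolds are the caller's responsibility to include or not.
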