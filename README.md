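# panhap

Identical-by-state haplotype block discovery across crop pangenome
assemblies.

Modern crop breeding shuffles large chromosomal blocks, not single SNPs.
With multiple chromosome-scale assemblies of a crop available — the
motivating case is hexaploid bread wheat (*Triticum aestivum*), where 15
cultivar assemblies exist — one can ask directly which physical intervals
of two cultivars are *identical by state* (IBS), i.e. indistinguishable at
the sequence level, and which are merely *near-identical* (~99.95%
identity, the residue of ~10,000 years of divergence). The distinction
matters: conventional haplotyping tolerances of 1–3% diversity happily
merge haplotypes that differ by tens of thousands of mutations. `panhap`
implements a stringent, assembly-based haplotype framework:

* **Whole-chromosome caller** (`nucmer_blocks`). From MUMmer-style
  pairwise alignments, keep alignments ≥ 20 kb, compute per-alignment
  identity `100·(1 − m/ℓ)` (ℓ alignment length, m mismatch columns), bin
  alignments by reference midpoint into 5-, 2.5- or 1-Mbp bins, and call a
  bin IBS when its **median** identity ≥ 99.99% (at most one mismatch per
  10 kb). Adjacent qualifying bins are stitched into blocks, absorbing up
  to two consecutive sub-threshold or empty bins; blocks must be called in
  both reciprocal alignment directions.
* **Gene-window caller** (`gene_window_blocks`). For scaffold-level
  assemblies, per-gene BLASTN alignments (gene ± 2 kb flank) are scanned
  with a 25-gene sliding window; after dropping the lowest 10% of
  identities (3 of 25), a window is IBS iff the trimmed mean equals 100%.
  A precision/recall sweep against the whole-chromosome blocks justifies
  the window and flank choices. Both block sets are combined, dropping
  gene-window blocks that a whole-chromosome block already represents.
* **Gene-anchored liftover** (`coordinate_lift`). Intervals are converted
  between assemblies using shared gene projections: anchors are sorted by
  target position and joined into runs bridging gaps of ≤ 20 genes; runs
  with ≥ 10 genes are kept (otherwise the longest run).
* **Sharing and conservation** (`pangenome_stats`). Per-pair shared
  percentage, per-position partner coverage (GenomicRanges-style sweep
  line), "highly conserved" regions shared with ≥ 5 other cultivars, and
  block length/gene content summaries by 500-kb sampling, 1% position
  bins and R1/R2a/C/R2b/R3 recombination compartments.
* **Sequence metrics** (`sequence_metrics`). Expected identity
  `100·(1 − 2rt)` at substitution rate r and divergence time t; 2-mer
  Shannon richness (effective k-mer number) of SNP ± 10 bp flanks; SNP
  collation; alignment breadth/identity reports.
* **Markers and haplotype groups** (`markers_haplotyping`). Haplotype
  group profiles over a minimum haplotype block, assignment of genotyped
  germplasm (exact / merged "H4/5/6/7" / novel "N1" labels), and greedy
  design of marker panels with ≥ 3 pairwise profile differences.
* **Synthetic pangenome** (`synthetic`). A seeded generator planting IBS
  blocks on a near-identical background with introgressions, N runs, gene
  projections, alignment/BLAST tables, SNPs and genotype matrices — the
  ground truth all of the above is tested against.

## Worked example

```bash
panhap simulate --n-cultivars 2 --chrom-len 3000000 --seed 17 \
    --planted 0,1:1000001:2500000 --out sim/
panhap call-nucmer --coords sim/cv0_vs_cv1.coords --chrom-len 3000000 \
    --bin-size 500000 --ref cv0 --query cv1 --out nuc.bed
# -> "1 blocks -> nuc.bed" (the planted 1.5-Mb block at bin resolution)
printf 'chr1\t3000000\n' > sizes.tsv
panhap share --blocks nuc.bed --sizes sizes.tsv --reference cv0
```

The final command prints

```json
{"reference": "cv0", "shared_pct": 50.0}
```

meaning half of cv0's 3-Mb chromosome lies inside a haplotype block
shared with at least one other cultivar — exactly the planted 1.5-Mb
identical segment, recovered at 500-kb bin resolution. The same
calculation applied to real assemblies gives the per-cultivar shared
percentages and, with `panhap conserve`, the highly conserved regions.

```bash
panhap expected-identity --years 10000
# 99.9680   <- % identity expected after 10 kyr at 1.6e-8 nt^-1 yr^-1
```

The library mirrors the CLI one-to-one; see the module docstrings for the
Python API.

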