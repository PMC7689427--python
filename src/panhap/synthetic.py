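"""Synthetic multi-cultivar pangenome with planted haplotype structure.

The generator emulates the inputs of the whole pipeline: a set of cultivar
chromosomes descended from one ancestral sequence, with

* planted identical-by-descent blocks shared by chosen cultivar subsets
  (zero divergence within the block — the ground truth for recovery),
* a near-identical background (default per-pair divergence 3.2e-4, the
  level expected after ~10,000 years at the wheat intergenic substitution
  rate 1.6e-8 nt^-1 yr^-1 on two lineages),
* introgression-like segments of markedly higher divergence (default
  0.7%),
* N runs that break alignments (so the >= 20 kb length filter is
  exercised by the short fragments they create),
* gene projections at a chosen density, per-gene BLAST-style alignment
  tables at configurable flank sizes, SNP lists against the first
  cultivar, and a genotype matrix over marker positions.

Substitutions are i.i.d. per site; there are no indels, so alignment
records are emitted by construction as collinear segments with exact
mismatch counts (segments split at N runs in either sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (AlignmentRecord, GeneProjection, GenotypeMatrix,
                         SnpRecord)
from .nucmer_blocks import percent_identity

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
N_CODE = ord("N")

#: per-pair divergence matching ~10 kyr of two-lineage evolution
NEAR_IDENTICAL_DIVERGENCE = 3.2e-4
INTROGRESSION_DIVERGENCE = 0.7e-2


@dataclass
class PangenomeSpec:
    """Study conditions for one simulated chromosome set."""

    n_cultivars: int = 2
    chrom_len: int = 10_000_000
    chrom_name: str = "chr1"
    #: (cultivar index tuple, start, end) identical-by-descent segments
    planted_blocks: list[tuple[tuple[int, ...], int, int]] = field(
        default_factory=list)
    background_divergence: float = NEAR_IDENTICAL_DIVERGENCE
    #: (cultivar index, start, end, divergence)
    introgressions: list[tuple[int, int, int, float]] = field(
        default_factory=list)
    #: (cultivar index, start, length)
    n_runs: list[tuple[int, int, int]] = field(default_factory=list)
    gene_density: float = 8.0  # genes per Mbp, wheat-like
    gene_length: int = 3_000
    #: purifying selection: substitution probability inside gene bodies is
    #: background * this factor, so genic sequence alone under-reports
    #: divergence (the reason flanking sequence is needed to tell
    #: haplotypes from near-identical regions)
    genic_divergence_factor: float = 0.1
    marker_density: float = 2.0  # markers per Mbp
    blast_flanks: tuple = (0, 2000)
    #: typical emitted alignment length (bp); real whole-chromosome
    #: alignments are fragmented by repeats and indels, so records are cut
    #: at random breakpoints of roughly this spacing as well as at N runs
    aln_segment_mean: int = 100_000
    #: fraction of segments further shattered into sub-20-kb pieces
    #: (retrotransposon-scale fragments that the length filter removes)
    short_record_frac: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if not 0 <= self.background_divergence < 1:
            raise ValueError("background_divergence outside [0, 1)")
        for cs, s, e in self.planted_blocks:
            if not (1 <= s <= e <= self.chrom_len):
                raise ValueError(f"planted block {s}-{e} outside chromosome")
            if any(c >= self.n_cultivars for c in cs):
                raise ValueError("planted block names unknown cultivar")

    def cultivar_names(self) -> list[str]:
        return [f"cv{i}" for i in range(self.n_cultivars)]


@dataclass
class PangenomeTruth:
    """Planted ground truth for recovery tests."""

    #: ordered (ref, query) name pair -> list of (start, end) IBS intervals
    ibs_intervals: dict[tuple[str, str], list[tuple[int, int]]]
    n_runs: dict[str, list[tuple[int, int]]]
    group_labels: dict[str, str]


@dataclass
class SyntheticPangenome:
    spec: PangenomeSpec
    sequences: dict[str, np.ndarray] = field(repr=False)
    alignments: dict[tuple[str, str], list[AlignmentRecord]]
    projections: list[GeneProjection]
    gene_tables: dict[tuple[str, str, int], pd.DataFrame] = field(repr=False)
    snps: list[SnpRecord]
    genotype_matrix: GenotypeMatrix
    truth: PangenomeTruth

    def sequence_str(self, cultivar: str) -> str:
        return self.sequences[cultivar].tobytes().decode("ascii")

    def chrom_sizes(self) -> dict[str, int]:
        return {self.spec.chrom_name: self.spec.chrom_len}

    def write_outputs(self, outdir) -> None:
        """Emit every downstream input as plain-text files under outdir."""
        import os

        from .io_formats import (write_blast_tab, write_coords,
                                 write_genotype_tsv, write_gff3_projections)
        os.makedirs(outdir, exist_ok=True)
        names = self.spec.cultivar_names()
        for name in names:
            with open(os.path.join(outdir, f"{name}.fa"), "w") as fh:
                fh.write(f">{self.spec.chrom_name}\n")
                seq = self.sequence_str(name)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
            write_gff3_projections(
                [p for p in self.projections if p.assembly == name],
                os.path.join(outdir, f"{name}.gff3"))
        for (a, b), recs in self.alignments.items():
            write_coords(recs, os.path.join(outdir, f"{a}_vs_{b}.coords"))
        for (a, b, flank), df in self.gene_tables.items():
            write_blast_tab(df, os.path.join(
                outdir, f"{a}_vs_{b}.flank{flank}.blast.tsv"))
        with open(os.path.join(outdir, "snps.tsv"), "w") as fh:
            fh.write("ref_chrom\tref_pos\tref_allele\talt_allele\tquery\n")
            for s in self.snps:
                fh.write(f"{s.ref_chrom}\t{s.ref_pos}\t{s.ref_allele}\t"
                         f"{s.alt_allele}\t{s.query_assembly}\n")
        write_genotype_tsv(self.genotype_matrix,
                           os.path.join(outdir, "genotypes.tsv"))
        with open(os.path.join(outdir, "truth.bed"), "w") as fh:
            fh.write('track name="planted_ibs"\n')
            for (a, b), ivs in self.truth.ibs_intervals.items():
                for s, e in ivs:
                    fh.write(f"{self.spec.chrom_name}\t{s - 1}\t{e}\t"
                             f"{a}|{b}|truth|.\n")


def expected_mismatches(divergence: float, length: int) -> dict:
    """Binomial mean and normal-approximation 95% interval for the
    mismatch count of a ``length``-bp segment at the given divergence."""
    mean = divergence * length
    sd = math.sqrt(max(length, 0) * divergence * (1.0 - divergence))
    return {"mean": mean, "sd": sd,
            "lo95": mean - 1.96 * sd, "hi95": mean + 1.96 * sd}


def _check_planted_consistency(spec: PangenomeSpec) -> None:
    blocks = spec.planted_blocks
    for i, (cs1, s1, e1) in enumerate(blocks):
        for cs2, s2, e2 in blocks[i + 1:]:
            if s1 <= e2 and s2 <= e1:
                shared = set(cs1) & set(cs2)
                if shared and set(cs1) != set(cs2):
                    raise ValueError(
                        "overlapping planted blocks with contradictory "
                        f"cultivar sets at {max(s1, s2)}-{min(e1, e2)}")


def _substitute(seq: np.ndarray, mask: np.ndarray, offsets: np.ndarray,
                start: int) -> None:
    """Apply substitutions in place: at masked positions, shift the base by
    offset (1..3) in the ACGT alphabet."""
    pos = np.nonzero(mask)[0]
    if len(pos) == 0:
        return
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[b] = i
    idx = lut[seq[start + pos]]
    seq[start + pos] = BASES[(idx + offsets[pos]) % 4]


def simulate_pangenome(spec: PangenomeSpec) -> SyntheticPangenome:
    """Generate the full synthetic pangenome described by ``spec``.

    Deterministic given (spec, seed): all randomness flows from a single
    numpy Generator in a fixed draw order.
    """
    _check_planted_consistency(spec)
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_len
    names = spec.cultivar_names()
    ancestor = BASES[rng.integers(0, 4, size=L)]

    projections = _make_projections(spec, rng, names)
    # per-site substitution probability profile: background halved per
    # lineage, thinned inside gene bodies by the purifying-selection factor
    p_lineage = spec.background_divergence / 2.0
    genic = np.zeros(L, dtype=bool)
    for p in projections:
        if p.assembly == names[0]:
            genic[p.start - 1:p.end] = True
    p_site = np.where(genic, p_lineage * spec.genic_divergence_factor,
                      p_lineage)
    seqs: dict[str, np.ndarray] = {}
    # independent background substitutions per lineage
    masks = {}
    offsets = {}
    for name in names:
        masks[name] = rng.random(L) < p_site
        offsets[name] = rng.integers(1, 4, size=L).astype(np.uint8)
    # planted blocks: members share one lineage draw over the interval
    for cs, s, e in spec.planted_blocks:
        span = e - s + 1
        shared_mask = rng.random(span) < p_site[s - 1:e]
        shared_off = rng.integers(1, 4, size=span).astype(np.uint8)
        for c in cs:
            masks[names[c]][s - 1:e] = shared_mask
            offsets[names[c]][s - 1:e] = shared_off
    # introgressions: replace the lineage draw with a high-divergence one
    for c, s, e, div in spec.introgressions:
        span = e - s + 1
        p_intro = np.where(genic[s - 1:e],
                           div * spec.genic_divergence_factor, div)
        masks[names[c]][s - 1:e] = rng.random(span) < p_intro
        offsets[names[c]][s - 1:e] = rng.integers(
            1, 4, size=span).astype(np.uint8)
    for name in names:
        seq = ancestor.copy()
        _substitute(seq, masks[name], offsets[name], 0)
        seqs[name] = seq
    # N runs applied last
    n_run_map: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for c, s, length in spec.n_runs:
        e = min(s + length - 1, L)
        seqs[names[c]][s - 1:e] = N_CODE
        n_run_map[names[c]].append((s, e))

    breakpoints = _segment_breakpoints(spec, rng)
    alignments = _make_alignments(spec, seqs, names, breakpoints)
    gene_tables = _make_gene_tables(spec, seqs, projections, names)
    snps = _make_snps(spec, seqs, names)
    genotype_matrix = _make_genotypes(spec, rng, seqs, snps, names)
    truth = _make_truth(spec, names, n_run_map)
    return SyntheticPangenome(
        spec=spec, sequences=seqs, alignments=alignments,
        projections=projections, gene_tables=gene_tables, snps=snps,
        genotype_matrix=genotype_matrix, truth=truth)


def _make_projections(spec, rng, names) -> list[GeneProjection]:
    n_genes = int(spec.gene_density * spec.chrom_len / 1e6)
    if n_genes == 0:
        return []
    spacing = spec.chrom_len / n_genes
    jitter = rng.integers(-int(spacing * 0.2), int(spacing * 0.2) + 1,
                          size=n_genes)
    out = []
    for i in range(n_genes):
        start = int(i * spacing + spacing * 0.1) + int(jitter[i])
        start = max(1, min(start, spec.chrom_len - spec.gene_length))
        end = start + spec.gene_length - 1
        gid = f"gene{i + 1:05d}"
        # collinear pangenome: identical projected coordinates everywhere
        for name in names:
            out.append(GeneProjection(
                gene_id=gid, assembly=name, chrom=spec.chrom_name,
                start=start, end=end, strand="+", ref_rank=i + 1))
    return out


def _segments_excluding_n(seq_a, seq_b, L) -> list[tuple[int, int]]:
    ok = (seq_a != N_CODE) & (seq_b != N_CODE)
    if not ok.any():
        return []
    edges = np.diff(ok.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if ok[0]:
        starts = [0] + starts
    if ok[-1]:
        ends = ends + [L - 1]
    return [(s + 1, e + 1) for s, e in zip(starts, ends)]  # 1-based


def _segment_breakpoints(spec, rng) -> np.ndarray:
    """Shared alignment cut positions emulating repeat/indel fragmentation.

    Gaps between cuts are uniform in [0.5, 1.5] * aln_segment_mean; a
    ``short_record_frac`` share of cuts opens a burst of 5-19 kb fragments
    so the downstream >= 20 kb filter has something to remove.
    """
    cuts = []
    pos = 0
    mean = max(spec.aln_segment_mean, 1000)
    while pos < spec.chrom_len:
        if rng.random() < spec.short_record_frac:
            for _ in range(int(rng.integers(2, 5))):
                pos += int(rng.integers(5_000, 19_000))
                cuts.append(pos)
        else:
            pos += int(rng.integers(mean // 2, mean * 3 // 2))
            cuts.append(pos)
    return np.array([c for c in cuts if 0 < c < spec.chrom_len],
                    dtype=np.int64)


def _split_at(segment: tuple[int, int], cuts: np.ndarray):
    """Split a 1-based inclusive segment at cut positions (cut c ends a
    piece at c)."""
    s, e = segment
    inner = cuts[(cuts >= s) & (cuts < e)]
    start = s
    for c in inner:
        yield (start, int(c))
        start = int(c) + 1
    yield (start, e)


def _make_alignments(spec, seqs, names, breakpoints):
    """Collinear alignment records per ordered pair, split at N runs and
    at the shared fragmentation breakpoints."""
    L = spec.chrom_len
    out = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            diff = seqs[a] != seqs[b]
            cum = np.concatenate([[0], np.cumsum(diff, dtype=np.int64)])
            recs = []
            pieces = [p
                      for seg in _segments_excluding_n(seqs[a], seqs[b], L)
                      for p in _split_at(seg, breakpoints)]
            for s, e in pieces:
                length = e - s + 1
                mism = int(cum[e] - cum[s - 1])
                recs.append(AlignmentRecord(
                    ref_name=spec.chrom_name, query_name=spec.chrom_name,
                    ref_start=s, ref_end=e, query_start=s, query_end=e,
                    aln_length=length, mismatches=mism, n_count=0,
                    identity_pct=percent_identity(length, mism)))
            out[(a, b)] = recs
    return out


def _make_gene_tables(spec, seqs, projections, names):
    """13-column BLAST-dialect table per ordered pair and flank size."""
    from .io_formats import BLAST_COLUMNS
    genes = sorted({(p.gene_id, p.start, p.end) for p in projections
                    if p.assembly == names[0]}, key=lambda g: g[1])
    out = {}
    L = spec.chrom_len
    for a in names:
        for b in names:
            if a == b:
                continue
            diff = seqs[a] != seqs[b]
            cum = np.concatenate([[0], np.cumsum(diff, dtype=np.int64)])
            for flank in spec.blast_flanks:
                rows = []
                for gid, gstart, gend in genes:
                    s = max(1, gstart - flank)
                    e = min(L, gend + flank)
                    length = e - s + 1
                    qn = int((seqs[a][s - 1:e] == N_CODE).sum())
                    sn = int((seqs[b][s - 1:e] == N_CODE).sum())
                    mism = int(cum[e] - cum[s - 1])
                    pident = percent_identity(length, mism)
                    rows.append([gid, gid, pident, length, mism, 0,
                                 1, length, s, e,
                                 round(2.0 * length - 3.0 * mism, 1),
                                 qn, sn])
                out[(a, b, flank)] = pd.DataFrame(rows,
                                                  columns=BLAST_COLUMNS)
    return out


def _make_snps(spec, seqs, names) -> list[SnpRecord]:
    """SNPs of every cultivar against the first (reference) cultivar."""
    ref_name = names[0]
    ref = seqs[ref_name]
    out = []
    for name in names[1:]:
        q = seqs[name]
        pos = np.nonzero((ref != q) & (ref != N_CODE) & (q != N_CODE))[0]
        for p in pos:
            out.append(SnpRecord(
                ref_chrom=spec.chrom_name, ref_pos=int(p) + 1,
                ref_allele=chr(ref[p]), alt_allele=chr(q[p]),
                query_assembly=name))
    return out


def _make_genotypes(spec, rng, seqs, snps, names) -> GenotypeMatrix:
    n_markers = int(spec.marker_density * spec.chrom_len / 1e6)
    positions = sorted({s.ref_pos for s in snps})
    if positions and n_markers and len(positions) > n_markers:
        idx = rng.choice(len(positions), size=n_markers, replace=False)
        positions = sorted(positions[i] for i in idx)
    ref = seqs[names[0]]
    markers = [(f"mk{p}", spec.chrom_name, p) for p in positions]
    data = {}
    for name in names:
        calls = []
        for p in positions:
            base = seqs[name][p - 1]
            if base == N_CODE:
                calls.append(np.nan)
            elif base == ref[p - 1]:
                calls.append("0")
            else:
                calls.append("1")
        data[name] = calls
    df = pd.DataFrame(data, index=[m[0] for m in markers]).T
    return GenotypeMatrix(markers, df)


def _make_truth(spec, names, n_run_map) -> PangenomeTruth:
    ibs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if a == b:
                continue
            ivs = [(s, e) for cs, s, e in spec.planted_blocks
                   if i in cs and j in cs]
            ibs[(a, b)] = sorted(ivs)
    membership = {}
    for i, name in enumerate(names):
        pattern = tuple(i in cs for cs, _, _ in spec.planted_blocks)
        membership.setdefault(pattern, []).append(name)
    labels = {}
    for k, (pattern, members) in enumerate(membership.items(), 1):
        for m in members:
            labels[m] = f"H{k}"
    return PangenomeTruth(ibs_intervals=ibs, n_runs=n_run_map,
                          group_labels=labels)
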