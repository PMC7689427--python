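"""Gene-anchored haplotype block calling via a trimmed-mean sliding window.

Whole-chromosome alignments are unavailable for scaffold-level assemblies,
so a complementary caller works from per-gene BLASTn alignments (gene
models plus flanking sequence, typically +/- 2 kb). The best HSP per gene
pair is kept, genes with ambiguous projections or N-containing alignments
are dropped, and a window of W consecutive surviving genes (default 25) is
identical-by-state when, after trimming the lowest 10% of identities
(ceil(0.10*25) = 3 for the default), the mean of the remainder equals
100%. Identical windows are merged and lifted into assembly coordinates.

A precision/recall sweep against blocks from the whole-chromosome caller
selects window size and flank: flanking sequence discriminates haplotypes
that genic sequence alone cannot (precision rises with flank and W), at
the cost of N-driven data loss (recall falls).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .coordinate_lift import ProjectionIndex, lift_interval
from .io_formats import GeneProjection
from .nucmer_blocks import IDENTITY_EPS, PairwiseBlock

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 25
DEFAULT_TRIM_FRAC = 0.10


@dataclass(frozen=True)
class GeneAlignment:
    """Best-HSP alignment of one gene between two cultivars."""

    gene_id: str
    cultivar_a: str
    cultivar_b: str
    identity_pct: float
    hsp_length: int
    contains_n: bool
    ref_rank: int
    flank: int | str = 2000  # bp, or "CDS"


@dataclass(frozen=True)
class WindowCall:
    start_rank: int
    end_rank: int
    identical: bool
    trimmed_mean: float
    #: positional indices (within the surviving-gene ordering) of the
    #: window's first and last gene; used for run merging
    start_pos: int = 0
    end_pos: int = 0


@dataclass(frozen=True)
class PRResult:
    precision: float
    recall: float
    f1: float
    parameters: tuple = ()
    precision_defined: bool = True
    recall_defined: bool = True


def select_best_hsp(hsps: pd.DataFrame, *, cultivar_a: str = ".",
                    cultivar_b: str = ".", ref_rank: int = 0,
                    flank: int | str = 2000) -> GeneAlignment:
    """Pick one HSP for a gene pair: largest aligned length, ties broken by
    bitscore then identity."""
    if len(hsps) == 0:
        raise ValueError("select_best_hsp requires at least one HSP")
    best = hsps.sort_values(
        ["length", "bitscore", "pident"], ascending=False,
        kind="mergesort").iloc[0]
    return GeneAlignment(
        gene_id=str(best["qseqid"]), cultivar_a=cultivar_a,
        cultivar_b=cultivar_b, identity_pct=float(best["pident"]),
        hsp_length=int(best["length"]),
        contains_n=(int(best["qNs"]) + int(best["sNs"])) > 0,
        ref_rank=ref_rank, flank=flank)


def best_hsp_per_gene(hsps: pd.DataFrame, *, cultivar_a: str = ".",
                      cultivar_b: str = ".",
                      rank_of: dict[str, int] | None = None,
                      flank: int | str = 2000) -> list[GeneAlignment]:
    """Group an HSP table by gene and keep the best HSP for each."""
    out = []
    for gid, grp in hsps.groupby("qseqid", sort=False):
        ga = select_best_hsp(grp, cultivar_a=cultivar_a,
                             cultivar_b=cultivar_b,
                             ref_rank=(rank_of or {}).get(str(gid), 0),
                             flank=flank)
        out.append(ga)
    out.sort(key=lambda g: g.ref_rank)
    return out


def filter_gene_alignments(gas: list[GeneAlignment],
                           projections: list[GeneProjection],
                           expected_chrom: str) -> list[GeneAlignment]:
    """Keep genes with exactly one projection on the expected chromosome
    and N-free alignments.

    Drops (a) genes whose projections land on another chromosome only,
    (b) genes with more than one projection on the expected chromosome,
    (c) alignments whose aligned sequence contains Ns.
    """
    on_expected: dict[str, int] = {}
    for p in projections:
        if p.chrom == expected_chrom:
            on_expected[p.gene_id] = on_expected.get(p.gene_id, 0) + 1
    # projections on other chromosomes are simply ignored; a gene is kept
    # iff exactly one of its projections lands on the expected chromosome
    kept = []
    for ga in gas:
        if ga.contains_n:
            continue
        if on_expected.get(ga.gene_id, 0) != 1:
            continue
        kept.append(ga)
    return kept


def trim_count(window: int, trim_frac: float) -> int:
    """Number of lowest-identity alignments removed per window
    (ceil(trim_frac * window); 3 for the default 25-gene, 10% window)."""
    return math.ceil(trim_frac * window)


def window_scan(gas: list[GeneAlignment], window: int = DEFAULT_WINDOW,
                trim_frac: float = DEFAULT_TRIM_FRAC) -> list[WindowCall]:
    """Slide a W-gene window over the surviving genes (step 1).

    Genes removed by the filters do not break windows: "consecutive" means
    consecutive among survivors. Windows shorter than W (at the end of a
    chromosome) are not emitted.
    """
    gas = sorted(gas, key=lambda g: g.ref_rank)
    if len(gas) < window:
        logger.warning("window_scan: only %d genes for window %d",
                       len(gas), window)
        return []
    k = trim_count(window, trim_frac)
    calls = []
    for i in range(len(gas) - window + 1):
        chunk = gas[i:i + window]
        idents = sorted(g.identity_pct for g in chunk)
        kept = idents[k:]
        mean = sum(kept) / len(kept)
        calls.append(WindowCall(
            start_rank=chunk[0].ref_rank, end_rank=chunk[-1].ref_rank,
            identical=mean >= 100.0 - IDENTITY_EPS, trimmed_mean=mean,
            start_pos=i, end_pos=i + window - 1))
    return calls


def windows_to_blocks(calls: list[WindowCall], projections,
                      target_assembly: str, *, source_assembly: str,
                      ref_chrom: str, gas: list[GeneAlignment] | None = None,
                      ref_cultivar: str = ".", query_cultivar: str = ".",
                      gap: int = 20, min_run: int = 10) -> list[PairwiseBlock]:
    """Merge identical windows into gene runs and lift them to the target.

    Overlapping or adjacent identical windows merge into maximal runs over
    surviving-gene positions; each run spans the full extent of its first
    and last genes in the source annotation and is converted to the target
    assembly with the gene-anchored lift. Runs whose lift fails are dropped
    with a warning.
    """
    index = (projections if isinstance(projections, ProjectionIndex)
             else ProjectionIndex(projections))
    ident = [c for c in calls if c.identical]
    if not ident:
        return []
    ident.sort(key=lambda c: c.start_pos)
    runs = [[ident[0]]]
    for c in ident[1:]:
        if c.start_pos <= runs[-1][-1].end_pos + 1:
            runs[-1].append(c)
        else:
            runs.append([c])
    rank_to_span = {}
    if gas is not None:
        for g in gas:
            p = index.get(source_assembly, g.gene_id)
            if p is not None and p.chrom == ref_chrom:
                rank_to_span[g.ref_rank] = (p.start, p.end)
    blocks = []
    for run in runs:
        lo_rank, hi_rank = run[0].start_rank, run[-1].end_rank
        if rank_to_span:
            start = min(s for r, (s, e) in rank_to_span.items()
                        if lo_rank <= r <= hi_rank)
            end = max(e for r, (s, e) in rank_to_span.items()
                      if lo_rank <= r <= hi_rank)
        else:
            span = _rank_span(index, source_assembly, ref_chrom,
                              lo_rank, hi_rank)
            if span is None:
                logger.warning("windows_to_blocks: no genes for ranks "
                               "%d-%d", lo_rank, hi_rank)
                continue
            start, end = span
        if target_assembly == source_assembly:
            blocks.append(PairwiseBlock(
                ref_cultivar=ref_cultivar, query_cultivar=query_cultivar,
                chrom=ref_chrom, start=start, end=end, source="blast",
                bin_size=None))
            continue
        lifted = lift_interval((ref_chrom, start, end), source_assembly,
                               target_assembly, index, gap=gap,
                               min_run=min_run)
        span = lifted.span()
        if span is None:
            logger.warning("windows_to_blocks: lift failed for run "
                           "%d-%d", lo_rank, hi_rank)
            continue
        chrom, tstart, tend = span
        blocks.append(PairwiseBlock(
            ref_cultivar=ref_cultivar, query_cultivar=query_cultivar,
            chrom=chrom, start=tstart, end=tend, source="blast",
            bin_size=None))
    return blocks


def _rank_span(index: ProjectionIndex, assembly: str, chrom: str,
               lo_rank: int, hi_rank: int):
    genes = index.genes_in(assembly, chrom, 1, 10 ** 12)
    spans = [(p.start, p.end) for rank, p in enumerate(genes, 1)
             if lo_rank <= rank <= hi_rank]
    if not spans:
        return None
    return min(s for s, _ in spans), max(e for _, e in spans)


def combine_blocks(nucmer: list[PairwiseBlock], blast: list[PairwiseBlock],
                   bin_size: int) -> list[PairwiseBlock]:
    """Final block set: all whole-chromosome blocks plus gene-window blocks
    not already represented.

    A gene-window block is redundant when it overlaps (>= 1 bp) a
    whole-chromosome block AND is shorter than that caller's bin size: it
    adds no resolution the binned caller lacks.
    """
    out = list(nucmer)
    for b in blast:
        redundant = (b.length < bin_size
                     and any(b.overlaps(n) for n in nucmer))
        if not redundant:
            out.append(b)
    return out


def precision_recall_f1(blast_blocks: list[PairwiseBlock],
                        nucmer_blocks: list[PairwiseBlock],
                        parameters: tuple = ()) -> PRResult:
    """Precision/recall of gene-window blocks against whole-chromosome
    blocks as ground truth.

    precision = fraction of blast blocks overlapping >= 1 nucmer block;
    recall = fraction of nucmer blocks overlapping >= 1 blast block;
    F1 = 2PR/(P+R), 0 when P + R = 0. Empty inputs give an undefined
    (flagged) score reported as 0.
    """
    p_def = len(blast_blocks) > 0
    r_def = len(nucmer_blocks) > 0
    precision = (sum(1 for b in blast_blocks
                     if any(b.overlaps(n) for n in nucmer_blocks))
                 / len(blast_blocks)) if p_def else 0.0
    recall = (sum(1 for n in nucmer_blocks
                  if any(n.overlaps(b) for b in blast_blocks))
              / len(nucmer_blocks)) if r_def else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return PRResult(precision=precision, recall=recall, f1=f1,
                    parameters=parameters, precision_defined=p_def,
                    recall_defined=r_def)


def parameter_sweep(blocks_by_config: dict, nucmer_truth: list[PairwiseBlock]
                    ) -> pd.DataFrame:
    """Score one block set per (window, flank) configuration against the
    whole-chromosome truth set; the best-F1 row is marked ``selected``."""
    rows = []
    for params, blocks in blocks_by_config.items():
        pr = precision_recall_f1(blocks, nucmer_truth, parameters=params)
        window, flank = params
        rows.append({"window": window, "flank": flank,
                     "precision": pr.precision, "recall": pr.recall,
                     "f1": pr.f1})
    df = pd.DataFrame(rows)
    if len(df):
        df["selected"] = df["f1"] == df["f1"].max()
    return df
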