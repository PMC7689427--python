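"""Identical-by-state block calling from whole-chromosome alignments.

Pairwise alignments (MUMmer-style, >= 20 kb after filtering) are binned by
their reference midpoint into fixed-width bins (5, 2.5 or 1 Mbp). A bin
whose median alignment identity is >= 99.99% is identical-by-state; runs of
qualifying bins are stitched into blocks, absorbing up to two consecutive
sub-threshold or empty bins. Blocks called in only one of the two
reciprocal alignment directions are discarded.

The 99.99% threshold is one mismatch per 10 kb: stricter than the ~99.97%
identity expected from ~10,000 years of divergence at the wheat
intergenic substitution rate, so near-identical haplotypes do not qualify,
while Ns and sequencing error in low-complexity runs are tolerated.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

from .io_formats import AlignmentRecord

logger = logging.getLogger(__name__)

#: float guard on the percent scale for >= comparisons at the threshold
IDENTITY_EPS = 1e-9

DEFAULT_MIN_ALN_LEN = 20_000
DEFAULT_BIN_SIZE = 5_000_000
DEFAULT_THRESHOLD = 99.99
DEFAULT_MAX_ERR_RUN = 2


@dataclass
class IdentityBin:
    """Fixed-width reference bin holding the identity values assigned to it.

    Bin ``index`` i (1-based) spans [(i-1)*B + 1, i*B], truncated at the
    chromosome end for the last bin.
    """

    chrom: str
    index: int
    start: int
    end: int
    identities: list[float] = field(default_factory=list)
    aligned_bp: int = 0

    @property
    def median_identity(self) -> float | None:
        if not self.identities:
            return None
        return statistics.median(self.identities)

    @property
    def aligned_fraction_pct(self) -> float:
        """Aligned bp as a percent of bin breadth."""
        return 100.0 * self.aligned_bp / (self.end - self.start + 1)

    def is_good(self, threshold: float) -> bool:
        med = self.median_identity
        return med is not None and med >= threshold - IDENTITY_EPS


@dataclass(frozen=True)
class PairwiseBlock:
    """A called haplotype block for an ordered (reference, query) pair."""

    ref_cultivar: str
    query_cultivar: str
    chrom: str
    start: int
    end: int
    source: str = "nucmer"  # nucmer | blast | combined
    bin_size: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"block end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "PairwiseBlock") -> bool:
        """>= 1 bp overlap on the same chromosome of the same cultivar pair
        (order-insensitive), so pooled multi-pair block lists compare
        correctly."""
        return (self.chrom == other.chrom
                and {self.ref_cultivar, self.query_cultivar}
                == {other.ref_cultivar, other.query_cultivar}
                and self.start <= other.end and other.start <= self.end)


def percent_identity(aln_length: int, mismatches: int) -> float:
    """Match fraction of an alignment as a percentage.

    100*(1 - mismatches/aln_length); 10,000 bp with a single mismatch gives
    99.99, the block-calling threshold boundary.
    """
    if aln_length < 1:
        raise ValueError("aln_length must be >= 1")
    if not 0 <= mismatches <= aln_length:
        raise ValueError("mismatches outside [0, aln_length]")
    return 100.0 * (1.0 - mismatches / aln_length)


def filter_alignments(records: list[AlignmentRecord],
                      min_len: int = DEFAULT_MIN_ALN_LEN) -> list[AlignmentRecord]:
    """Drop alignments shorter than ``min_len`` (default 20 kb).

    The default excludes short alignments between non-syntenic
    retrotransposons (median ~9.6 kb in wheat) that are not informative
    about haplotype identity.
    """
    return [r for r in records if r.aln_length >= min_len]


def bin_alignments(records: list[AlignmentRecord], bin_size: int,
                   chrom_len: int) -> list[IdentityBin]:
    """Assign each alignment to one bin by its reference midpoint.

    Every bin from 1 to ceil(chrom_len/bin_size) is materialised, so empty
    bins are visible to the stitcher. ``aligned_bp`` accumulates the
    reference span of the alignments assigned to each bin.
    """
    if chrom_len < 1:
        raise ValueError("chrom_len must be >= 1")
    n_bins = math.ceil(chrom_len / bin_size)
    chrom = records[0].ref_name if records else "."
    bins = [IdentityBin(chrom=chrom, index=i,
                        start=(i - 1) * bin_size + 1,
                        end=min(i * bin_size, chrom_len))
            for i in range(1, n_bins + 1)]
    for rec in records:
        mid = rec.ref_midpoint
        if mid > chrom_len:
            raise ValueError(
                f"alignment midpoint {mid} beyond chromosome end {chrom_len}")
        idx = (mid - 1) // bin_size  # 0-based bin index
        bins[idx].identities.append(rec.identity_pct)
        bins[idx].aligned_bp += rec.ref_span
    return bins


def call_blocks(bins: list[IdentityBin],
                threshold: float = DEFAULT_THRESHOLD,
                max_err_run: int = DEFAULT_MAX_ERR_RUN,
                *, ref_cultivar: str = ".", query_cultivar: str = ".",
                bin_size: int | None = None) -> list[PairwiseBlock]:
    """Stitch qualifying bins into blocks.

    A bin is good when its median identity is defined and >= threshold;
    empty bins count as errors (N gaps produce empty bins inside true
    blocks). Two consecutive good bins are joined when at most
    ``max_err_run`` error bins lie between them; blocks start and end on
    good bins, and a single good bin forms a valid block.
    """
    good_idx = [i for i, b in enumerate(bins) if b.is_good(threshold)]
    if not good_idx:
        return []
    groups: list[list[int]] = [[good_idx[0]]]
    for i in good_idx[1:]:
        if i - groups[-1][-1] - 1 <= max_err_run:
            groups[-1].append(i)
        else:
            groups.append([i])
    blocks = []
    for grp in groups:
        first, last = bins[grp[0]], bins[grp[-1]]
        blocks.append(PairwiseBlock(
            ref_cultivar=ref_cultivar, query_cultivar=query_cultivar,
            chrom=first.chrom, start=first.start, end=last.end,
            source="nucmer", bin_size=bin_size))
    return blocks


def reciprocal_consistency(blocks_ab: list[PairwiseBlock],
                           blocks_ba: list[PairwiseBlock],
                           lifter) -> tuple[list[PairwiseBlock], list[PairwiseBlock]]:
    """Keep only blocks called in both reciprocal alignment directions.

    ``lifter(block, direction)`` maps a block into the other assembly's
    coordinates, returning ``(chrom, start, end)`` or None on failure;
    direction is "ab" for blocks_ab members and "ba" for blocks_ba. A block
    survives when its lifted interval overlaps (>= 1 bp) any block of the
    opposite direction. Blocks whose lift fails are dropped with a warning.
    """

    def _kept(blocks, others, direction):
        kept = []
        for blk in blocks:
            lifted = lifter(blk, direction)
            if lifted is None:
                logger.warning("reciprocal filter: lift failed for %s", blk)
                continue
            chrom, start, end = lifted
            if any(o.chrom == chrom and start <= o.end and o.start <= end
                   for o in others):
                kept.append(blk)
        return kept

    return (_kept(blocks_ab, blocks_ba, "ab"),
            _kept(blocks_ba, blocks_ab, "ba"))


def identity_lifter(block: PairwiseBlock, direction: str):
    """Trivial lifter for collinear assemblies sharing one coordinate system."""
    return (block.chrom, block.start, block.end)


def call_pairwise_nucmer(records: list[AlignmentRecord],
                         chrom_len: int,
                         bin_size: int = DEFAULT_BIN_SIZE,
                         threshold: float = DEFAULT_THRESHOLD,
                         max_err_run: int = DEFAULT_MAX_ERR_RUN,
                         min_aln_len: int = DEFAULT_MIN_ALN_LEN,
                         *, ref_cultivar: str = ".",
                         query_cultivar: str = ".") -> list[PairwiseBlock]:
    """Full single-direction pipeline: length filter, binning, stitching."""
    kept = filter_alignments(records, min_aln_len)
    bins = bin_alignments(kept, bin_size, chrom_len)
    return call_blocks(bins, threshold, max_err_run,
                       ref_cultivar=ref_cultivar,
                       query_cultivar=query_cultivar, bin_size=bin_size)
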