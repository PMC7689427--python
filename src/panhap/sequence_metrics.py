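"""Sequence-level utilities: expected divergence, SNP flank complexity,
SNP collation and region identity/breadth reports.

Expected identity after t years of independent evolution on both lineages
at per-site substitution rate r is 100*(1 - 2*r*t); at the wheat
intergenic rate of 1.6e-8 nt^-1 yr^-1 and 10,000 years this is 99.968%,
the yardstick separating true identical-by-state haplotypes from merely
near-identical sequence.

Sequence complexity around SNPs is the Shannon richness (effective number)
of overlapping k-mers of the SNP +/- 10 bp flank: exp of the natural-log
Shannon entropy of k-mer frequencies. Low-complexity flanks concentrate
sequencing error, which is why block calling tolerates sub-100% bins.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import SnpRecord
from .nucmer_blocks import PairwiseBlock

logger = logging.getLogger(__name__)

WHEAT_SUBSTITUTION_RATE = 1.6e-8  # substitutions nt^-1 yr^-1, intergenic
DEFAULT_FLANK = 10
DEFAULT_K = 2


def expected_identity(rate: float, years: float) -> float:
    """Percent identity expected between two lineages after ``years`` of
    divergence at per-site, per-year substitution rate ``rate``.

    Divergence accumulates on both lineages since the common ancestor,
    hence the factor 2. Floored at 0.
    """
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be non-negative")
    return max(0.0, 100.0 * (1.0 - 2.0 * rate * years))


def kmer_shannon_richness(seq: str, k: int = DEFAULT_K,
                          as_entropy: bool = False) -> float:
    """Effective number of k-mers of ``seq`` (exp of Shannon entropy).

    All len(seq)-k+1 overlapping k-mers are counted; with frequencies p_i,
    H = -sum p_i ln p_i and the richness is exp(H), between 1 (single
    k-mer species) and min(4^k, number of k-mers). ``as_entropy`` returns
    H itself. Sequences containing N must be excluded upstream.
    """
    seq = seq.upper()
    if "N" in seq:
        raise ValueError("sequence contains N; exclude N flanks upstream")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts = Counter(seq[i:i + k] for i in range(len(seq) - k + 1))
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h if as_entropy else math.exp(h)


def snp_flank_extract(snps: list[SnpRecord], sequences,
                      flank: int = DEFAULT_FLANK
                      ) -> list[tuple[SnpRecord, str]]:
    """Extract the 2*flank+1 bp of reference sequence around each SNP.

    ``sequences`` maps chromosome name to sequence (plain dict of strings
    or a pyfaidx.Fasta). SNPs too close to a sequence end are dropped with
    a warning; flanks containing N are excluded.
    """
    out = []
    for snp in snps:
        seq = sequences[snp.ref_chrom]
        seqlen = len(seq)
        if snp.ref_pos - flank < 1 or snp.ref_pos + flank > seqlen:
            logger.warning("SNP %s:%d too close to sequence end; dropped",
                           snp.ref_chrom, snp.ref_pos)
            continue
        window = str(seq[snp.ref_pos - flank - 1: snp.ref_pos + flank]).upper()
        if "N" in window:
            continue
        out.append((snp, window))
    return out


def collate_snps(per_pair_snps: list[list[SnpRecord]]) -> list[SnpRecord]:
    """Pool SNPs across pairwise comparisons into one reference set.

    Records whose reference or query allele is "N" or "." (indel columns
    in show-snps output) are removed; duplicate reference positions keep
    the first occurrence in input order.
    """
    seen: set[tuple[str, int]] = set()
    out = []
    for snps in per_pair_snps:
        for snp in snps:
            if snp.ref_allele.upper() in ("N", ".") \
                    or snp.alt_allele.upper() in ("N", "."):
                continue
            key = (snp.ref_chrom, snp.ref_pos)
            if key in seen:
                continue
            seen.add(key)
            out.append(snp)
    return out


@dataclass(frozen=True)
class RegionReport:
    """Identity and breadth tallies for one aligned region pair."""

    total_sequence: int
    n_count: int
    matched: int
    mismatch_indel: int

    def __post_init__(self):
        if min(self.total_sequence, self.n_count, self.matched,
               self.mismatch_indel) < 0:
            raise ValueError("tallies must be non-negative")
        if self.total_aligned > self.max_alignable:
            raise ValueError("aligned sequence exceeds maximum alignable")

    @property
    def max_alignable(self) -> int:
        return self.total_sequence - self.n_count

    @property
    def total_aligned(self) -> int:
        return self.matched + self.mismatch_indel

    @property
    def identity_defined(self) -> bool:
        return self.total_aligned > 0

    @property
    def identity_pct(self) -> float | None:
        if not self.identity_defined:
            return None
        return 100.0 * self.matched / self.total_aligned

    @property
    def breadth_pct(self) -> float:
        return 100.0 * self.total_aligned / self.max_alignable

    def summary(self) -> dict:
        """Percentages rounded to 1 decimal place for reporting."""
        return {
            "total_sequence": self.total_sequence,
            "max_alignable": self.max_alignable,
            "total_aligned": self.total_aligned,
            "identity_pct": (None if not self.identity_defined
                             else round(self.identity_pct, 1)),
            "breadth_pct": round(self.breadth_pct, 1),
        }


def region_identity_report(total: int, n_count: int, matched: int,
                           mismatch_indel: int) -> RegionReport:
    """Build a RegionReport from raw tallies.

    identity = matched / (matched + mismatch_indel); breadth =
    (matched + mismatch_indel) / (total - Ns).
    """
    return RegionReport(total_sequence=total, n_count=n_count,
                        matched=matched, mismatch_indel=mismatch_indel)


@dataclass
class ComplexityComparison:
    in_block: np.ndarray
    out_block: np.ndarray
    p_value: float | None
    flag: str | None = None

    @property
    def median_in(self) -> float | None:
        return float(np.median(self.in_block)) if len(self.in_block) else None

    @property
    def median_out(self) -> float | None:
        return float(np.median(self.out_block)) if len(self.out_block) else None


def complexity_by_block_status(flanks: list[tuple[SnpRecord, str]],
                               blocks: list[PairwiseBlock],
                               subsample: int = 10_000,
                               seed: int = 0, k: int = DEFAULT_K
                               ) -> ComplexityComparison:
    """Compare flank complexity of SNPs inside vs outside haplotype blocks.

    SNPs are labelled by membership in any block interval on their
    chromosome; each category is subsampled to ``subsample`` SNPs (whole
    category when smaller), complexities computed, and the groups compared
    with a two-sided rank-sum test. An empty category is flagged and no
    test is run.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    inside, outside = [], []
    for snp, window in flanks:
        hit = any(s <= snp.ref_pos <= e
                  for s, e in by_chrom.get(snp.ref_chrom, []))
        (inside if hit else outside).append(window)
    rng = np.random.default_rng(seed)

    def _sample(seqs):
        if len(seqs) > subsample:
            idx = rng.choice(len(seqs), size=subsample, replace=False)
            seqs = [seqs[i] for i in sorted(idx)]
        return np.array([kmer_shannon_richness(s, k) for s in seqs])

    cin, cout = _sample(inside), _sample(outside)
    if len(cin) == 0 or len(cout) == 0:
        which = "in-block" if len(cin) == 0 else "out-of-block"
        return ComplexityComparison(cin, cout, None,
                                    flag=f"{which} category empty")
    p = float(sps.mannwhitneyu(cin, cout, alternative="two-sided").pvalue)
    return ComplexityComparison(cin, cout, p)
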