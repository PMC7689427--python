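"""Haplotype sharing, conserved regions and block length/gene-content
summaries across a pangenome.

Sharing between a pair of cultivars is the union of their blocks as a
percentage of the reference cultivar's chromosome or genome size. Across
all cultivars, a per-position coverage profile counts how many OTHER
cultivars share a block with the reference at that position
(GenomicRanges::coverage semantics, computed by a sweep line); positions
covered by >= 5 partners (shared among >= 6 cultivars including the
reference) are "highly conserved".

Block length and gene content are summarised positionally by sampling each
chromosome every 500 kb — a block contributes at every sampling point it
spans — scaling positions to % of chromosome length, taking medians in 1%
bins and aggregating those bins into the recombination-based compartments
R1, R2a, C, R2b, R3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nucmer_blocks import PairwiseBlock

DEFAULT_MIN_PARTNERS = 5
DEFAULT_SAMPLE_STEP = 500_000

COMPARTMENT_ORDER = ["R1", "R2a", "C", "R2b", "R3"]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; adjacent intervals merge."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def union_bp(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def pairwise_shared_fraction(blocks: list[PairwiseBlock],
                             ref_sizes: dict[str, int]) -> float:
    """Percent of the reference cultivar's sequence inside blocks of one
    pair: 100 * union(block bp) / sum(ref_sizes)."""
    total = sum(ref_sizes.values())
    if total <= 0:
        raise ValueError("reference size must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    covered = sum(union_bp(ivs) for ivs in by_chrom.values())
    return 100.0 * covered / total


@dataclass
class CoverageProfile:
    """Piecewise-constant partner counts along one reference genome.

    ``segments[chrom]`` is a list of (start, end, coverage) triples
    partitioning [1, chrom_len]; coverage is the number of other cultivars
    sharing a block with the reference at that position.
    """

    reference: str
    chrom_sizes: dict[str, int]
    segments: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def covered_bp(self, min_cov: int = 1) -> int:
        return sum(e - s + 1
                   for segs in self.segments.values()
                   for s, e, c in segs if c >= min_cov)

    def shared_fraction(self, min_cov: int = 1) -> float:
        """Percent of the genome covered by >= min_cov partners."""
        return 100.0 * self.covered_bp(min_cov) / sum(self.chrom_sizes.values())

    def integral(self) -> int:
        """sum over positions of coverage (= sum of partner block bp)."""
        return sum((e - s + 1) * c
                   for segs in self.segments.values()
                   for s, e, c in segs)


def coverage_profile(all_pair_blocks: list[PairwiseBlock], reference: str,
                     chrom_sizes: dict[str, int]) -> CoverageProfile:
    """Sweep-line partner coverage for one reference cultivar.

    Blocks of each partner are unioned per chromosome first, so a partner
    contributes at most 1 at any position regardless of how its blocks
    tile.
    """
    per_partner: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in all_pair_blocks:
        if b.ref_cultivar != reference:
            continue
        per_partner.setdefault((b.query_cultivar, b.chrom), []).append(
            (b.start, b.end))
    profile = CoverageProfile(reference=reference, chrom_sizes=chrom_sizes)
    for chrom, length in chrom_sizes.items():
        events: dict[int, int] = {}
        for (partner, c), ivs in per_partner.items():
            if c != chrom:
                continue
            for s, e in merge_intervals(ivs):
                s, e = max(1, s), min(length, e)
                if e < s:
                    continue
                events[s] = events.get(s, 0) + 1
                events[e + 1] = events.get(e + 1, 0) - 1
        segs: list[tuple[int, int, int]] = []
        cov, pos = 0, 1
        for x in sorted(events):
            if x > pos:
                segs.append((pos, x - 1, cov))
            cov += events[x]
            pos = max(pos, x)
        if pos <= length:
            segs.append((pos, length, cov))
        profile.segments[chrom] = segs
    return profile


def conserved_regions(profile: CoverageProfile,
                      min_partners: int = DEFAULT_MIN_PARTNERS) -> pd.DataFrame:
    """Maximal intervals with coverage >= min_partners.

    Returns a DataFrame with chrom/start/end/max_coverage plus positions
    scaled to % of chromosome length (pct_start, pct_end) so conserved
    regions can be compared across cultivars with different assembly sizes.
    """
    rows = []
    for chrom, segs in profile.segments.items():
        length = profile.chrom_sizes[chrom]
        current = None
        for s, e, c in segs:
            if c >= min_partners:
                if current is None:
                    current = [s, e, c]
                else:
                    current[1] = e
                    current[2] = max(current[2], c)
            elif current is not None:
                rows.append((chrom, *current))
                current = None
        if current is not None:
            rows.append((chrom, *current))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "max_coverage"])
    if len(df):
        sizes = df["chrom"].map(profile.chrom_sizes)
        df["pct_start"] = 100.0 * df["start"] / sizes
        df["pct_end"] = 100.0 * df["end"] / sizes
    else:
        df["pct_start"] = df["pct_end"] = pd.Series(dtype=float)
    return df


@dataclass(frozen=True)
class BlockSample:
    """One (block, sampling point) incidence."""

    chrom: str
    sample_pos_bp: int
    pct_pos: float
    block_length: int
    gene_count: int


def sample_blocks(blocks: list[PairwiseBlock], gene_index,
                  chrom_sizes: dict[str, int],
                  step: int = DEFAULT_SAMPLE_STEP) -> list[BlockSample]:
    """Sample blocks at fixed positions every ``step`` bp.

    Grid points sit at step, 2*step, ...; a block registers at every point
    p with start <= p <= end, so a 5-Mb block appears at 10-12 points for
    the default grid. ``gene_index`` is a list of GeneProjection (reference
    annotation) or None; gene_count counts genes overlapping the block.
    """
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in (gene_index or []):
        genes_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for ivs in genes_by_chrom.values():
        ivs.sort()
    out = []
    for b in blocks:
        length = chrom_sizes[b.chrom]
        genes = genes_by_chrom.get(b.chrom, [])
        n_genes = sum(1 for s, e in genes if s <= b.end and b.start <= e)
        first = ((b.start + step - 1) // step) * step
        p = max(first, step)
        while p <= min(b.end, length):
            out.append(BlockSample(
                chrom=b.chrom, sample_pos_bp=p,
                pct_pos=100.0 * p / length,
                block_length=b.length, gene_count=n_genes))
            p += step
    return out


class CompartmentMap:
    """Recombination-based chromosome partition R1, R2a, C, R2b, R3.

    Boundaries per chromosome are the four internal breakpoints (bp); the
    five compartments tile [1, chrom_len].
    """

    def __init__(self, boundaries: dict[str, tuple[int, int, int, int]],
                 chrom_sizes: dict[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.boundaries = {}
        for chrom, bnds in boundaries.items():
            if list(bnds) != sorted(bnds) or len(bnds) != 4:
                raise ValueError(f"{chrom}: need 4 increasing boundaries")
            if bnds[-1] >= chrom_sizes[chrom]:
                raise ValueError(f"{chrom}: boundary beyond chromosome end")
            self.boundaries[chrom] = tuple(int(b) for b in bnds)

    @classmethod
    def read_tsv(cls, path, chrom_sizes: dict[str, int]) -> "CompartmentMap":
        df = pd.read_csv(path, sep="\t",
                         names=["chrom", "b1", "b2", "b3", "b4"],
                         comment="#")
        return cls({r.chrom: (r.b1, r.b2, r.b3, r.b4)
                    for r in df.itertuples()}, chrom_sizes)

    def compartment_of(self, chrom: str, pos: int) -> str:
        b1, b2, b3, b4 = self.boundaries[chrom]
        if pos <= b1:
            return "R1"
        if pos <= b2:
            return "R2a"
        if pos <= b3:
            return "C"
        if pos <= b4:
            return "R2b"
        return "R3"


def compartment_summary(samples: list[BlockSample], cmap: CompartmentMap,
                        value: str = "block_length") -> dict:
    """Positional and compartment summaries of a sampled block statistic.

    Per chromosome, sampling points fall into 1% position bins whose
    medians form the chromosome-level profile; compartment medians are
    medians of those chromosome-level 1%-bin medians, while min/max come
    from the raw samples. Pairwise compartment contrasts use rank-sum
    tests with Benjamini-Hochberg adjustment on the raw values.

    Returns {"bins": per-(chrom, 1% bin) medians, "compartments":
    per-compartment median/min/max/n, "tests": pairwise adjusted p-values}.
    """
    from statsmodels.stats.multitest import multipletests

    if not samples:
        empty = pd.DataFrame()
        return {"bins": empty, "compartments": empty, "tests": empty}
    df = pd.DataFrame([{
        "chrom": s.chrom, "pct_bin": min(int(s.pct_pos) + 1, 100),
        "value": getattr(s, value),
        "compartment": cmap.compartment_of(s.chrom, s.sample_pos_bp),
    } for s in samples])
    bins = (df.groupby(["chrom", "pct_bin"])["value"].median()
            .reset_index(name="median"))
    # map each (chrom, 1% bin) to a compartment via the bin midpoint
    bins["compartment"] = [
        cmap.compartment_of(r.chrom,
                            int((r.pct_bin - 0.5) / 100.0
                                * cmap.chrom_sizes[r.chrom]) or 1)
        for r in bins.itertuples()]
    comp_rows = []
    for comp in COMPARTMENT_ORDER:
        med_of_bins = bins.loc[bins["compartment"] == comp, "median"]
        raw = df.loc[df["compartment"] == comp, "value"]
        if len(raw) == 0:
            continue
        comp_rows.append({
            "compartment": comp,
            "median": float(med_of_bins.median()) if len(med_of_bins)
            else float(raw.median()),
            "min": float(raw.min()), "max": float(raw.max()),
            "n_samples": int(len(raw))})
    comps = pd.DataFrame(comp_rows)
    test_rows = []
    present = [c for c in COMPARTMENT_ORDER
               if (df["compartment"] == c).any()]
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    pvals = []
    for a, b in pairs:
        va = df.loc[df["compartment"] == a, "value"]
        vb = df.loc[df["compartment"] == b, "value"]
        if len(va) < 2 or len(vb) < 2 or (va.nunique() == 1
                                          and vb.nunique() == 1
                                          and va.iloc[0] == vb.iloc[0]):
            p = 1.0
        else:
            p = sps.mannwhitneyu(va, vb, alternative="two-sided").pvalue
        pvals.append(p)
        test_rows.append({"a": a, "b": b, "p_raw": p})
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["p_adj"] = multipletests(pvals, method="fdr_bh")[1]
    return {"bins": bins, "compartments": comps, "tests": tests}
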