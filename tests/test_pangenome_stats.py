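import numpy as np
import pytest

from panhap import pangenome_stats as ps
from panhap.io_formats import GeneProjection
from panhap.nucmer_blocks import PairwiseBlock


def _blk(start, end, query="B", ref="A", chrom="chr1"):
    return PairwiseBlock(ref, query, chrom, start, end)


class TestPairwiseSharedFraction:
    SIZES = {"chr1": 10_000_000}

    def test_full_coverage(self):
        blocks = [_blk(1, 10_000_000)]
        assert ps.pairwise_shared_fraction(blocks, self.SIZES) == 100.0

    def test_overlapping_blocks_union(self):
        blocks = [_blk(1_000_001, 2_000_000), _blk(1_500_001, 3_000_000)]
        assert ps.pairwise_shared_fraction(blocks, self.SIZES) == \
            pytest.approx(20.0)

    def test_no_blocks(self):
        assert ps.pairwise_shared_fraction([], self.SIZES) == 0.0

    def test_invariant_under_block_splitting(self):
        whole = [_blk(1_000_001, 4_000_000)]
        split = [_blk(1_000_001, 2_500_000), _blk(2_500_001, 4_000_000)]
        assert ps.pairwise_shared_fraction(whole, self.SIZES) == \
            pytest.approx(ps.pairwise_shared_fraction(split, self.SIZES))


class TestCoverageProfile:
    SIZES = {"chr1": 10_000_000}

    def test_three_partners_same_interval(self):
        blocks = [_blk(1, 5_000_000, query=q) for q in ("B", "C", "D")]
        prof = ps.coverage_profile(blocks, "A", self.SIZES)
        assert prof.segments["chr1"] == [
            (1, 5_000_000, 3), (5_000_001, 10_000_000, 0)]

    def test_no_partners(self):
        prof = ps.coverage_profile([], "A", self.SIZES)
        assert prof.segments["chr1"] == [(1, 10_000_000, 0)]

    def test_whole_chromosome_single_partner(self):
        prof = ps.coverage_profile([_blk(1, 10_000_000)], "A", self.SIZES)
        assert prof.segments["chr1"] == [(1, 10_000_000, 1)]
        assert prof.shared_fraction(1) == 100.0

    def test_partner_blocks_unioned_before_counting(self):
        # two overlapping blocks from ONE partner still count coverage 1
        blocks = [_blk(1, 3_000_000), _blk(2_000_000, 4_000_000)]
        prof = ps.coverage_profile(blocks, "A", self.SIZES)
        assert max(c for _, _, c in prof.segments["chr1"]) == 1

    def test_coverage_conservation(self):
        """sum over partners of unioned block bp = integral of coverage."""
        rng = np.random.default_rng(8)
        blocks = []
        for q in "BCDEF":
            for _ in range(4):
                s = int(rng.integers(1, 9_000_000))
                blocks.append(_blk(s, s + int(rng.integers(1, 10**6)),
                                   query=q))
        prof = ps.coverage_profile(blocks, "A", self.SIZES)
        per_partner = {}
        for b in blocks:
            per_partner.setdefault(b.query_cultivar, []).append(
                (b.start, b.end))
        total = sum(ps.union_bp(ivs) for ivs in per_partner.values())
        assert prof.integral() == total

    def test_profile_partitions_chromosome(self):
        prof = ps.coverage_profile([_blk(5, 10), _blk(3, 7, query="C")],
                                   "A", {"chr1": 20})
        segs = prof.segments["chr1"]
        assert segs[0][0] == 1 and segs[-1][1] == 20
        for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
            assert s2 == e1 + 1


class TestConservedRegions:
    SIZES = {"chr1": 1_000_000}

    def _profile(self, n_partners, start=1, end=500_000):
        blocks = [_blk(start, end, query=f"q{i}")
                  for i in range(n_partners)]
        return ps.coverage_profile(blocks, "A", self.SIZES)

    def test_coverage_five_reported(self):
        df = ps.conserved_regions(self._profile(5))
        assert len(df) == 1
        assert df.iloc[0]["max_coverage"] == 5
        assert df.iloc[0]["pct_start"] == pytest.approx(0.0001)
        assert df.iloc[0]["pct_end"] == pytest.approx(50.0)

    def test_coverage_four_not_reported(self):
        assert len(ps.conserved_regions(self._profile(4))) == 0

    def test_all_zero_profile_empty(self):
        assert len(ps.conserved_regions(self._profile(0))) == 0

    def test_min_partners_zero_returns_whole_chromosome(self):
        df = ps.conserved_regions(self._profile(2), min_partners=0)
        assert len(df) == 1
        assert (df.iloc[0]["start"], df.iloc[0]["end"]) == (1, 1_000_000)

    def test_nested_decreasing_in_min_partners(self):
        rng = np.random.default_rng(12)
        blocks = [_blk(int(s), int(s) + 200_000, query=f"q{i}")
                  for i, s in enumerate(rng.integers(1, 700_000, 12))]
        prof = ps.coverage_profile(blocks, "A", self.SIZES)
        prev_bp = None
        for k in range(0, 8):
            df = ps.conserved_regions(prof, min_partners=k)
            bp = int((df["end"] - df["start"] + 1).sum()) if len(df) else 0
            if prev_bp is not None:
                assert bp <= prev_bp
            prev_bp = bp


class TestSampleBlocks:
    SIZES = {"chr1": 100_000_000}

    def test_five_mb_block_sampled_10_to_12_times(self):
        rng = np.random.default_rng(1)
        for start in rng.integers(1, 50_000_000, 20):
            b = _blk(int(start), int(start) + 5_000_000 - 1)
            samples = ps.sample_blocks([b], [], self.SIZES)
            assert 10 <= len(samples) <= 12

    def test_short_block_straddling_one_point(self):
        b = _blk(490_000, 510_000)
        samples = ps.sample_blocks([b], [], self.SIZES)
        assert len(samples) == 1
        assert samples[0].sample_pos_bp == 500_000
        assert samples[0].block_length == 20_001  # 1-based inclusive span

    def test_block_avoiding_grid(self):
        b = _blk(510_000, 520_000)
        assert ps.sample_blocks([b], [], self.SIZES) == []

    def test_gene_count_and_pct(self):
        genes = [GeneProjection(f"g{i}", "R", "chr1", i * 100_000,
                                i * 100_000 + 999, ref_rank=i)
                 for i in range(1, 50)]
        b = _blk(1_000_000, 2_000_000)
        samples = ps.sample_blocks([b], genes, self.SIZES)
        assert samples[0].gene_count == 11  # genes 10..20 overlap
        assert samples[0].pct_pos == pytest.approx(1.0)


class TestCompartmentSummary:
    def _cmap(self):
        return ps.CompartmentMap(
            {"chr1": (20_000_000, 40_000_000, 60_000_000, 80_000_000)},
            {"chr1": 100_000_000})

    def test_compartment_lookup(self):
        cmap = self._cmap()
        assert cmap.compartment_of("chr1", 1) == "R1"
        assert cmap.compartment_of("chr1", 50_000_000) == "C"
        assert cmap.compartment_of("chr1", 99_999_999) == "R3"

    def test_all_identical_values(self):
        cmap = self._cmap()
        samples = [ps.BlockSample("chr1", p, p / 1e6, 7_000_000, 10)
                   for p in range(500_000, 100_000_001, 500_000)]
        out = ps.compartment_summary(samples, cmap)
        assert (out["compartments"]["median"] == 7_000_000).all()
        assert (out["bins"]["median"] == 7_000_000).all()

    def test_centromeric_blocks_larger(self):
        """Long centromere-spanning blocks drive median(C) > median(R1)."""
        cmap = self._cmap()
        blocks = (
            [_blk(1 + i * 4_000_000, 1 + i * 4_000_000 + 2_000_000)
             for i in range(5)]                       # short distal blocks
            + [_blk(40_000_001, 80_000_000)])         # one long C block
        samples = ps.sample_blocks(blocks, [], {"chr1": 100_000_000})
        out = ps.compartment_summary(samples, cmap)
        comp = out["compartments"].set_index("compartment")
        assert comp.loc["C", "median"] > comp.loc["R1", "median"]
        tests = out["tests"]
        assert ((tests["p_adj"] >= 0) & (tests["p_adj"] <= 1)).all()

    def test_single_sample(self):
        cmap = self._cmap()
        samples = [ps.BlockSample("chr1", 500_000, 0.5, 123, 4)]
        out = ps.compartment_summary(samples, cmap)
        assert out["bins"].iloc[0]["median"] == 123
        assert out["compartments"].iloc[0]["compartment"] == "R1"

    def test_empty_samples(self):
        out = ps.compartment_summary([], self._cmap())
        assert len(out["bins"]) == 0

    def test_rejects_bad_boundaries(self):
        with pytest.raises(ValueError):
            ps.CompartmentMap({"chr1": (5, 4, 3, 2)}, {"chr1": 100})
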