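import itertools

import numpy as np
import pandas as pd
import pytest

from panhap import gene_window_blocks as gw
from panhap.coordinate_lift import ProjectionIndex
from panhap.io_formats import BLAST_COLUMNS, GeneProjection
from panhap.nucmer_blocks import PairwiseBlock


def _hsp_rows(rows):
    """rows: list of (length, bitscore, pident) for one gene pair."""
    data = [["g1", "g1", pid, ln, 0, 0, 1, ln, 1, ln, bs, 0, 0]
            for ln, bs, pid in rows]
    return pd.DataFrame(data, columns=BLAST_COLUMNS)


def _ga(gene_id, rank, identity, contains_n=False):
    return gw.GeneAlignment(gene_id=gene_id, cultivar_a="A", cultivar_b="B",
                            identity_pct=identity, hsp_length=3000,
                            contains_n=contains_n, ref_rank=rank)


class TestSelectBestHsp:
    def test_largest_hsp_wins(self):
        ga = gw.select_best_hsp(_hsp_rows([(500, 900, 99.0), (300, 950, 100.0)]))
        assert ga.hsp_length == 500

    def test_single_hsp(self):
        ga = gw.select_best_hsp(_hsp_rows([(777, 100, 98.0)]))
        assert ga.hsp_length == 777

    def test_tie_breaks_match_exhaustive_comparison(self):
        # documented order: length, then bitscore, then identity
        rows = [(500, 10, 99.0), (500, 20, 98.0), (500, 20, 99.5),
                (400, 99, 100.0)]
        best = max(rows, key=lambda r: (r[0], r[1], r[2]))
        ga = gw.select_best_hsp(_hsp_rows(rows))
        assert (ga.hsp_length, ga.identity_pct) == (best[0], best[2])

    def test_n_flag_set(self):
        df = _hsp_rows([(500, 10, 99.0)])
        df.loc[0, "qNs"] = 3
        assert gw.select_best_hsp(df).contains_n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gw.select_best_hsp(_hsp_rows([]))


class TestFilterGeneAlignments:
    def _projs(self):
        return [
            GeneProjection("g1", "B", "chr1", 100, 200),
            GeneProjection("g2", "B", "chr1", 300, 400),
            GeneProjection("g2", "B", "chr1", 900, 950),  # duplicated
            GeneProjection("g3", "B", "chr2", 10, 20),    # wrong chromosome
        ]

    def test_rules(self):
        gas = [_ga("g1", 1, 100.0), _ga("g2", 2, 100.0),
               _ga("g3", 3, 100.0), _ga("g4", 4, 100.0, contains_n=True)]
        kept = gw.filter_gene_alignments(gas, self._projs(), "chr1")
        assert [g.gene_id for g in kept] == ["g1"]

    def test_clean_input_unchanged(self):
        gas = [_ga("g1", 1, 100.0)]
        assert gw.filter_gene_alignments(gas, self._projs(), "chr1") == gas


class TestWindowScan:
    def test_trim_count_exact(self):
        assert gw.trim_count(25, 0.10) == 3
        assert gw.trim_count(10, 0.10) == 1
        assert gw.trim_count(30, 0.10) == 3
        assert gw.trim_count(20, 0.10) == 2

    def test_all_identical(self):
        gas = [_ga(f"g{i}", i, 100.0) for i in range(1, 26)]
        (call,) = gw.window_scan(gas)
        assert call.identical and call.trimmed_mean == pytest.approx(100.0)

    def test_three_low_values_trimmed(self):
        idents = [100.0] * 22 + [99.5] * 3
        gas = [_ga(f"g{i}", i, idents[i - 1]) for i in range(1, 26)]
        (call,) = gw.window_scan(gas)
        assert call.identical

    def test_four_low_values_break_identity(self):
        idents = [100.0] * 21 + [99.9] * 4
        gas = [_ga(f"g{i}", i, idents[i - 1]) for i in range(1, 26)]
        (call,) = gw.window_scan(gas)
        assert not call.identical
        # trimmed-mean oracle: one sub-100 value survives the trim of 3
        expected = (21 * 100.0 + 99.9) / 22
        assert call.trimmed_mean == pytest.approx(expected)

    def test_too_few_genes(self):
        gas = [_ga(f"g{i}", i, 100.0) for i in range(1, 10)]
        assert gw.window_scan(gas, window=25) == []

    def test_monotonicity_raising_identity_never_unmakes_identical(self):
        rng = np.random.default_rng(2)
        idents = list(100.0 - 0.5 * (rng.random(40) < 0.2))
        gas = [_ga(f"g{i}", i, v) for i, v in enumerate(idents, 1)]
        before = gw.window_scan(gas)
        for j in range(len(gas)):
            bumped = list(gas)
            bumped[j] = _ga(gas[j].gene_id, gas[j].ref_rank, 100.0)
            after = gw.window_scan(bumped)
            for c0, c1 in zip(before, after):
                if c0.identical:
                    assert c1.identical


def _collinear_index(n_genes=60, gene_len=1000, spacing=5000,
                     assemblies=("A", "B")):
    projs = []
    for i in range(n_genes):
        start = 1 + i * spacing
        for asm in assemblies:
            projs.append(GeneProjection(f"g{i + 1}", asm, "chr1", start,
                                        start + gene_len - 1,
                                        ref_rank=i + 1))
    return projs


class TestWindowsToBlocks:
    def _call(self, start_pos, w=5, identical=True):
        return gw.WindowCall(start_rank=start_pos + 1,
                             end_rank=start_pos + w, identical=identical,
                             trimmed_mean=100.0, start_pos=start_pos,
                             end_pos=start_pos + w - 1)

    def test_merge_into_single_block(self):
        projs = _collinear_index()
        gas = [_ga(f"g{i}", i, 100.0) for i in range(1, 41)]
        calls = [self._call(i) for i in range(0, 36)]  # ranks 1..40
        blocks = gw.windows_to_blocks(
            calls, projs, target_assembly="A", source_assembly="A",
            ref_chrom="chr1", gas=gas)
        assert len(blocks) == 1
        assert blocks[0].start == 1
        assert blocks[0].end == 1 + 39 * 5000 + 999

    def test_gap_splits_runs(self):
        projs = _collinear_index()
        gas = [_ga(f"g{i}", i, 100.0) for i in range(1, 61)]
        calls = ([self._call(i) for i in range(0, 5)]
                 + [self._call(9, identical=False)]
                 + [self._call(i) for i in range(20, 25)])
        blocks = gw.windows_to_blocks(
            calls, projs, target_assembly="A", source_assembly="A",
            ref_chrom="chr1", gas=gas)
        assert len(blocks) == 2

    def test_no_identical_windows(self):
        projs = _collinear_index()
        assert gw.windows_to_blocks(
            [self._call(0, identical=False)], projs, target_assembly="A",
            source_assembly="A", ref_chrom="chr1") == []

    def test_lift_to_other_assembly(self):
        projs = _collinear_index()
        gas = [_ga(f"g{i}", i, 100.0) for i in range(1, 41)]
        calls = [self._call(i) for i in range(0, 36)]
        blocks = gw.windows_to_blocks(
            calls, ProjectionIndex(projs), target_assembly="B",
            source_assembly="A", ref_chrom="chr1", gas=gas)
        assert len(blocks) == 1 and blocks[0].start == 1


def _blk(start, end, source="nucmer", ref="A", query="B"):
    return PairwiseBlock(ref, query, "chr1", start, end, source)


class TestCombineBlocks:
    def test_small_contained_blast_block_removed(self):
        nuc = [_blk(1, 10_000_000)]
        bla = [_blk(2_000_000, 4_000_000, "blast")]
        out = gw.combine_blocks(nuc, bla, bin_size=5_000_000)
        assert out == nuc

    def test_non_overlapping_small_blast_kept(self):
        nuc = [_blk(1, 10_000_000)]
        bla = [_blk(12_000_000, 14_000_000, "blast")]
        out = gw.combine_blocks(nuc, bla, bin_size=5_000_000)
        assert bla[0] in out and nuc[0] in out

    def test_large_overlapping_blast_kept(self):
        nuc = [_blk(1, 10_000_000)]
        bla = [_blk(5_000_000, 12_000_000, "blast")]
        out = gw.combine_blocks(nuc, bla, bin_size=5_000_000)
        assert bla[0] in out

    def test_empty_blast_list(self):
        nuc = [_blk(1, 10_000_000)]
        assert gw.combine_blocks(nuc, [], 5_000_000) == nuc

    def test_output_covers_nucmer(self):
        rng = np.random.default_rng(3)
        nuc = [_blk(int(s), int(s) + int(l))
               for s, l in zip(rng.integers(1, 10**7, 10),
                               rng.integers(10**5, 10**6, 10))]
        bla = [_blk(int(s), int(s) + int(l), "blast")
               for s, l in zip(rng.integers(1, 10**7, 10),
                               rng.integers(10**4, 10**7, 10))]
        out = gw.combine_blocks(nuc, bla, 5_000_000)
        assert all(n in out for n in nuc)


class TestPrecisionRecallF1:
    def test_identical_sets(self):
        blocks = [_blk(1, 10), _blk(20, 30)]
        pr = gw.precision_recall_f1(blocks, blocks)
        assert (pr.precision, pr.recall, pr.f1) == (1.0, 1.0, 1.0)

    def test_half_precision(self):
        bla = [_blk(1, 10, "blast"), _blk(20, 30, "blast")]
        nuc = [_blk(5, 15)]
        pr = gw.precision_recall_f1(bla, nuc)
        assert pr.precision == pytest.approx(0.5)
        assert pr.recall == pytest.approx(1.0)
        assert pr.f1 == pytest.approx(2 / 3)

    def test_disjoint_sets(self):
        pr = gw.precision_recall_f1([_blk(1, 10, "blast")], [_blk(20, 30)])
        assert (pr.precision, pr.recall, pr.f1) == (0.0, 0.0, 0.0)

    def test_empty_sets_flagged(self):
        pr = gw.precision_recall_f1([], [_blk(1, 10)])
        assert not pr.precision_defined and pr.precision == 0.0
        pr = gw.precision_recall_f1([_blk(1, 10, "blast")], [])
        assert not pr.recall_defined and pr.recall == 0.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            bla = [_blk(int(s), int(s + l), "blast")
                   for s, l in zip(rng.integers(1, 10**6, 8),
                                   rng.integers(1, 10**5, 8))]
            nuc = [_blk(int(s), int(s + l))
                   for s, l in zip(rng.integers(1, 10**6, 8),
                                   rng.integers(1, 10**5, 8))]
            pr = gw.precision_recall_f1(bla, nuc)
            hits_b = sum(1 for b in bla if any(
                max(b.start, n.start) <= min(b.end, n.end) for n in nuc))
            hits_n = sum(1 for n in nuc if any(
                max(b.start, n.start) <= min(b.end, n.end) for b in bla))
            assert pr.precision == pytest.approx(hits_b / len(bla))
            assert pr.recall == pytest.approx(hits_n / len(nuc))

    def test_f1_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bla = [_blk(int(s), int(s) + 10**4, "blast")
                   for s in rng.integers(1, 10**6, 6)]
            nuc = [_blk(int(s), int(s) + 10**4)
                   for s in rng.integers(1, 10**6, 6)]
            pr = gw.precision_recall_f1(bla, nuc)
            assert 0.0 <= pr.precision <= 1.0
            assert 0.0 <= pr.recall <= 1.0
            if pr.precision + pr.recall > 0:
                assert pr.f1 <= 2 * min(pr.precision, pr.recall) / (
                    pr.precision + pr.recall) + 1e-12


def test_parameter_sweep_marks_best_f1():
    nuc = [_blk(1, 10_000)]
    configs = {
        (10, 0): [_blk(1, 10_000, "blast")],
        (25, 0): [_blk(50_000, 60_000, "blast")],
    }
    df = gw.parameter_sweep(configs, nuc)
    best = df.loc[df["selected"]]
    assert len(df) == 2
    assert best.iloc[0]["window"] == 10
    assert best.iloc[0]["f1"] == pytest.approx(1.0)
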