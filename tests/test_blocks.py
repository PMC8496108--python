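"""Block construction against brute-force interval and string oracles."""

import numpy as np
import pandas as pd
import pytest

import haploblup as hb
from haploblup.blocks import (
    block_stats,
    build_fixed_blocks,
    build_gene_blocks,
    coverage_after_overlap_removal,
)


def _random_genotypes(make, n_ind, positions, chrom_length, seed=0):
    rng = np.random.default_rng(seed)
    m = len(positions)
    haps = rng.integers(0, 2, size=(n_ind, 2, m), dtype=np.int8)
    return make(haps, positions, chrom_length=chrom_length)


class TestFixedBlocks:
    def test_two_windows_two_snps_each(self, make_genotypes):
        g = _random_genotypes(
            make_genotypes, 4, [10_000, 20_000, 60_000, 70_000], 100_000
        )
        bs = build_fixed_blocks(g, 50)
        assert len(bs) == 2
        assert all(b.snp_indices.size == 2 for b in bs)
        assert (bs[0].start, bs[0].end) == (0, 50_000)
        assert (bs[1].start, bs[1].end) == (50_000, 100_000)

    def test_all_snps_in_first_window(self, make_genotypes):
        g = _random_genotypes(make_genotypes, 4, [100, 200, 300], 100_000)
        bs = build_fixed_blocks(g, 50)
        assert len(bs) == 1

    def test_union_matches_direct_window_assignment(self, make_genotypes):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(1_000_000, size=1000, replace=False))
        g = _random_genotypes(make_genotypes, 3, pos, 1_000_000, seed=5)
        size = 37_000
        bs = build_fixed_blocks(g, 37)
        got = sorted(int(i) for b in bs for i in b.snp_indices)
        windows = pos // size
        expected = sorted(
            int(i)
            for i in range(1000)
            if np.sum(windows == windows[i]) >= 2
        )
        assert got == expected

    def test_no_overlap_and_monotone_snps_per_block(self, make_genotypes):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(2_000_000, size=400, replace=False))
        g = _random_genotypes(make_genotypes, 3, pos, 2_000_000, seed=9)
        prev_mean = 0.0
        for kb in (50, 100, 250, 500, 1000):
            bs = build_fixed_blocks(g, kb)
            ivals = sorted((b.start, b.end) for b in bs)
            assert all(
                ivals[i][1] <= ivals[i + 1][0] for i in range(len(ivals) - 1)
            )
            mean_snps = np.mean([b.snp_indices.size for b in bs])
            assert mean_snps >= prev_mean
            prev_mean = mean_snps


class TestGeneBlocks:
    def _genes(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end"]
        )

    def test_small_gene_extended_and_clipped(self, make_genotypes):
        g = _random_genotypes(
            make_genotypes, 4, [5_000, 150_000, 200_000], 1_000_000
        )
        genes = self._genes([("g1", "1", 100_000, 130_000)])
        bs = build_gene_blocks(genes, g)
        assert len(bs) == 1
        assert (bs[0].start, bs[0].end) == (0, 230_000)
        assert bs[0].source == "gene-extended"

    def test_large_gene_split_equally(self, make_genotypes):
        pos = list(range(10_000, 1_210_000, 40_000))
        g = _random_genotypes(make_genotypes, 4, pos, 2_000_000)
        genes = self._genes([("big", "1", 0, 1_200_000)])
        bs = build_gene_blocks(genes, g)
        assert len(bs) == 3  # ceil(1200/500) pieces of 400 kb
        for i, b in enumerate(bs):
            assert (b.start, b.end) == (i * 400_000, (i + 1) * 400_000)
            assert b.source == "gene-split"

    def test_block_with_one_snp_dropped(self, make_genotypes):
        g = _random_genotypes(make_genotypes, 4, [500_000], 1_000_000)
        genes = self._genes([("g1", "1", 450_000, 460_000)])
        bs = build_gene_blocks(genes, g)
        assert len(bs) == 0

    def test_malformed_gene_rejected(self, make_genotypes):
        g = _random_genotypes(make_genotypes, 4, [100, 200], 1_000_000)
        genes = self._genes([("bad", "1", 500, 500)])
        with pytest.raises(ValueError, match="malformed"):
            build_gene_blocks(genes, g)

    def test_gene_blocks_may_overlap(self, make_genotypes):
        # two short genes 10 kb apart both extend over the same region
        g = _random_genotypes(
            make_genotypes, 4, [95_000, 105_000, 115_000], 1_000_000
        )
        genes = self._genes(
            [("a", "1", 100_000, 101_000), ("b", "1", 110_000, 111_000)]
        )
        bs = build_gene_blocks(genes, g)
        assert len(bs) == 2
        assert bs[0].end > bs[1].start  # overlapping intervals retained


class TestCoverage:
    def _blocks(self, make_genotypes, intervals, chrom_length):
        g = _random_genotypes(
            make_genotypes,
            2,
            sorted({s + 1 for s, _ in intervals} | {e - 1 for _, e in intervals}),
            chrom_length,
        )
        blocks = [
            hb.Block(f"b{i}", "1", s, e, [0, 1], "fixed")
            for i, (s, e) in enumerate(intervals)
        ]
        return hb.BlockSet(blocks)

    def test_overlapping_pair(self, make_genotypes):
        bs = self._blocks(make_genotypes, [(0, 100), (50, 150)], 200)
        covered, frac = coverage_after_overlap_removal(bs, {"1": 200})
        assert covered == 150
        assert frac == pytest.approx(0.75)

    def test_disjoint_sum(self, make_genotypes):
        bs = self._blocks(make_genotypes, [(0, 10), (20, 40)], 200)
        covered, _ = coverage_after_overlap_removal(bs, {"1": 200})
        assert covered == 30

    def test_matches_per_bp_marking(self, make_genotypes):
        rng = np.random.default_rng(3)
        intervals = []
        for _ in range(1000):
            s = int(rng.integers(0, 9_000))
            e = int(rng.integers(s + 1, min(s + 500, 10_000)))
            intervals.append((s, e))
        bs = self._blocks(make_genotypes, intervals, 10_000)
        covered, _ = coverage_after_overlap_removal(bs, {"1": 10_000})
        marked = np.zeros(10_000, dtype=bool)
        for s, e in intervals:
            marked[s:e] = True
        assert covered == int(marked.sum())


class TestBlockStats:
    def test_identical_homozygotes_single_haplotype(self, make_genotypes):
        haps = np.ones((5, 2, 2), dtype=np.int8)
        g = make_genotypes(haps, [10, 20], chrom_length=100)
        bs = hb.BlockSet([hb.Block("b", "1", 0, 100, [0, 1], "fixed")])
        stats = block_stats(bs, g)
        assert stats.total_haplotypes == 1

    def test_haplotype_count_bound(self, small_pop):
        g = small_pop["genotypes"]
        stats = block_stats(small_pop["blocks"], g)
        for b in small_pop["blocks"]:
            strings = g.haplotype_strings(b.snp_indices).ravel()
            k = b.snp_indices.size
            assert len(set(strings)) <= min(2 * g.n_individuals, 2**k)

    def test_counts_match_string_set_oracle(self, make_genotypes):
        rng = np.random.default_rng(11)
        haps = rng.integers(0, 2, size=(8, 2, 6), dtype=np.int8)
        g = make_genotypes(haps, [10, 20, 30, 40, 50, 60], chrom_length=100)
        bs = hb.BlockSet([hb.Block("b", "1", 0, 100, list(range(6)), "fixed")])
        stats = block_stats(bs, g)
        oracle = {
            tuple(haps[i, j, :]) for i in range(8) for j in range(2)
        }
        assert stats.total_haplotypes == len(oracle)
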