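"""Haplotype-block construction and block statistics.

Blocks are contiguous chromosome intervals whose phased SNP alleles are
concatenated into a multi-allelic "locus"; each distinct allele sequence over
the block's member SNPs is one haplotype "allele". Two constructions are
supported: tiling each chromosome with fixed-size windows, and gene-boundary
blocks where small genes are extended and large genes are split.

Coordinates are 0-based half-open internally; GFF3 I/O converts at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .genotypes import PhasedGenotypes

__all__ = [
    "Block",
    "BlockSet",
    "BlockSetStats",
    "build_fixed_blocks",
    "build_gene_blocks",
    "coverage_after_overlap_removal",
    "block_stats",
]


@dataclass
class Block:
    """One haplotype block: a chromosome interval with >= 2 member SNPs."""

    block_id: str
    chrom: str
    start: int                 # bp, inclusive
    end: int                   # bp, exclusive
    snp_indices: np.ndarray    # global SNP indices, ordered by position
    source: str                # fixed | gene | gene-split | gene-extended

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)
        if self.end <= self.start:
            raise ValueError(f"block {self.block_id}: end <= start")
        if self.snp_indices.size < 2:
            raise ValueError(f"block {self.block_id}: fewer than 2 SNPs")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class BlockSet:
    blocks: list[Block] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, i: int) -> Block:
        return self.blocks[i]

    def to_frame(self) -> pd.DataFrame:
        """BED-like table: chrom, start, end, block_id, n_snps, source."""
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.blocks],
                "start": [b.start for b in self.blocks],
                "end": [b.end for b in self.blocks],
                "block_id": [b.block_id for b in self.blocks],
                "n_snps": [b.snp_indices.size for b in self.blocks],
                "source": [b.source for b in self.blocks],
            }
        )


@dataclass
class BlockSetStats:
    n_blocks: int
    total_haplotypes: int
    mean_haplotypes: float
    min_haplotypes: int
    max_haplotypes: int
    mean_snps: float
    min_snps: int
    max_snps: int
    mean_length_bp: float
    min_length_bp: int
    max_length_bp: int
    coverage_bp: int
    coverage_fraction: float


def _member_snps(
    genotypes: PhasedGenotypes, chrom: str, start: int, end: int
) -> np.ndarray:
    idx = genotypes.snp_indices(chrom)
    pos = genotypes.positions[idx]
    return idx[(pos >= start) & (pos < end)]


def build_fixed_blocks(
    genotypes: PhasedGenotypes, block_kb: float
) -> BlockSet:
    """Tile each chromosome from position 0 with windows of ``block_kb`` kb.

    Windows with fewer than 2 SNPs are dropped; the trailing partial window
    is kept when it has at least 2 SNPs. Fixed blocks never overlap.
    """
    if block_kb <= 0:
        raise ValueError("block_kb must be > 0")
    size = int(round(block_kb * 1000))
    out: list[Block] = []
    for chrom in genotypes.chrom_names:
        length = genotypes.chrom_lengths[chrom]
        for w in range(ceil(length / size)):
            start, end = w * size, min((w + 1) * size, length)
            snps = _member_snps(genotypes, chrom, start, end)
            if snps.size >= 2:
                out.append(
                    Block(
                        block_id=f"fix{block_kb:g}kb_{chrom}_{w}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        snp_indices=snps,
                        source="fixed",
                    )
                )
    return BlockSet(out)


def _split_intervals(start: int, end: int, split_max_bp: int):
    """Split [start, end) into ceil(L / split_max) equal-length pieces."""
    length = end - start
    k = ceil(length / split_max_bp)
    bounds = [start + round(i * length / k) for i in range(k + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(k)]


def build_gene_blocks(
    genes: pd.DataFrame,
    genotypes: PhasedGenotypes,
    split_min_kb: float = 200,
    split_max_kb: float = 500,
    small_gene_kb: float = 50,
    extension_kb: float = 100,
) -> BlockSet:
    """Blocks from gene intervals (0-based half-open, columns chrom/start/end).

    Genes shorter than ``small_gene_kb`` are extended by ``extension_kb`` at
    each end (clipped to chromosome bounds); genes longer than
    ``split_max_kb`` are split into ceil(L/split_max) equal pieces, which fall
    within [split_min, split_max] kb whenever possible. Gene blocks may
    overlap each other; overlaps are only removed for coverage accounting.
    Blocks with fewer than 2 SNPs are dropped.
    """
    small_bp = int(small_gene_kb * 1000)
    split_max_bp = int(split_max_kb * 1000)
    ext_bp = int(extension_kb * 1000)
    pieces: list[tuple[str, int, int, str, str]] = []
    for row in genes.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        gene_id = getattr(row, "gene_id", f"{chrom}:{start}-{end}")
        if end <= start:
            raise ValueError(f"malformed gene interval {gene_id}: end <= start")
        length = end - start
        chrom_len = genotypes.chrom_lengths.get(chrom)
        if chrom_len is None:
            continue
        if length < small_bp:
            s = max(0, start - ext_bp)
            e = min(chrom_len, end + ext_bp)
            pieces.append((chrom, s, e, f"{gene_id}", "gene-extended"))
        elif length > split_max_bp:
            for i, (s, e) in enumerate(_split_intervals(start, end, split_max_bp)):
                pieces.append((chrom, s, e, f"{gene_id}.{i + 1}", "gene-split"))
        else:
            pieces.append((chrom, start, end, f"{gene_id}", "gene"))
    chrom_order = {c: i for i, c in enumerate(genotypes.chrom_names)}
    pieces.sort(key=lambda t: (chrom_order.get(t[0], len(chrom_order)), t[1], t[2]))
    out: list[Block] = []
    for chrom, s, e, gid, source in pieces:
        snps = _member_snps(genotypes, chrom, s, e)
        if snps.size >= 2:
            out.append(
                Block(
                    block_id=gid,
                    chrom=chrom,
                    start=s,
                    end=e,
                    snp_indices=snps,
                    source=source,
                )
            )
    return BlockSet(out)


def coverage_after_overlap_removal(
    blocks: BlockSet, chrom_lengths: dict[str, int]
) -> tuple[int, float]:
    """Covered bp (union of block intervals) and fraction of the genome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    covered = 0
    for ivals in by_chrom.values():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = sum(chrom_lengths.values())
    return covered, covered / total if total else 0.0


def block_stats(
    blocks: BlockSet, genotypes: PhasedGenotypes
) -> BlockSetStats:
    """Summary statistics over blocks: haplotype, SNP and length counts.

    Distinct haplotype alleles per block are counted over all 2n phased
    sequences restricted to the block's member SNPs.
    """
    if len(blocks) == 0:
        raise ValueError("empty block set")
    n_haps, n_snps, lengths = [], [], []
    for b in blocks:
        strings = genotypes.haplotype_strings(b.snp_indices).ravel()
        n_haps.append(len(set(strings.tolist())))
        n_snps.append(b.snp_indices.size)
        lengths.append(b.length)
    n_haps_a = np.asarray(n_haps)
    n_snps_a = np.asarray(n_snps)
    len_a = np.asarray(lengths)
    cov_bp, cov_frac = coverage_after_overlap_removal(
        blocks, genotypes.chrom_lengths
    )
    return BlockSetStats(
        n_blocks=len(blocks),
        total_haplotypes=int(n_haps_a.sum()),
        mean_haplotypes=float(n_haps_a.mean()),
        min_haplotypes=int(n_haps_a.min()),
        max_haplotypes=int(n_haps_a.max()),
        mean_snps=float(n_snps_a.mean()),
        min_snps=int(n_snps_a.min()),
        max_snps=int(n_snps_a.max()),
        mean_length_bp=float(len_a.mean()),
        min_length_bp=int(len_a.min()),
        max_length_bp=int(len_a.max()),
        coverage_bp=cov_bp,
        coverage_fraction=cov_frac,
    )
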