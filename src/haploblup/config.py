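"""Simulation configuration for the synthetic single-breed pig population.

The generator emulates the data structure of a nucleus-farm Duroc population:
a small number of autosomes carrying phased biallelic SNPs with
distance-decaying linkage disequilibrium, gene annotations dominated by short
genes, and phenotypes assembled from SNP additive, SNP dominance and
haplotype-allele genetic components plus year-season fixed effects and noise.
Phenotypic (genetic + residual) variance is standardized to 1, so the entries
of ``var_fractions`` are heritabilities directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["SimConfig"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    Parameters
    ----------
    n_individuals
        Number of diploid individuals.
    n_chromosomes
        Number of autosomes.
    chrom_length_bp
        Physical length of every chromosome, in bp.
    n_snps_per_chrom
        Biallelic SNPs per chromosome (positions drawn without replacement).
    n_founders
        Size of the founder haplotype pool the population copies from. Small
        pools give strong LD and few distinct haplotypes per block.
    ld_decay_rate
        Per-bp probability rate of switching founder template between
        adjacent SNPs; the switch probability over distance ``d`` is
        ``1 - exp(-ld_decay_rate * d)``.
    maf_floor
        Minimum empirical minor allele frequency enforced on the output.
    n_genes_per_chrom
        Gene intervals simulated per chromosome.
    gene_length_range
        (min bp, max bp) bounds on simulated gene lengths.
    gene_length_scale_bp
        Scale of the min-shifted exponential gene-length distribution; the
        default 33 kb puts ~78% of genes below 50 kb.
    n_year_seasons
        Number of levels of the year-season fixed effect.
    year_season_effects
        Explicit fixed-effect value per level; drawn from
        ``N(0, fixed_effect_sd^2)`` when None.
    fixed_effect_sd
        SD used to draw fixed-effect values when not given explicitly.
    var_fractions
        (h2_additive, h2_dominance, h2_haplotype, residual), non-negative,
        summing to 1.
    n_causal_snps
        SNPs carrying additive/dominance effects; None means all SNPs.
    n_causal_blocks
        Blocks carrying haplotype-allele effects; None means all blocks.
    seed
        Seed of the single RNG stream driving the whole simulation.
    """

    n_individuals: int = 500
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    n_snps_per_chrom: int = 300
    n_founders: int = 20
    ld_decay_rate: float = 1e-6
    maf_floor: float = 0.05
    n_genes_per_chrom: int = 60
    gene_length_range: tuple[int, int] = (600, 1_638_000)
    gene_length_scale_bp: float = 33_000.0
    n_year_seasons: int = 4
    year_season_effects: Optional[Sequence[float]] = None
    fixed_effect_sd: float = 0.5
    var_fractions: tuple[float, float, float, float] = (0.30, 0.05, 0.10, 0.55)
    n_causal_snps: Optional[int] = None
    n_causal_blocks: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be > 0")
        if self.n_snps_per_chrom < 2:
            raise ValueError("n_snps_per_chrom must be >= 2")
        if self.n_snps_per_chrom > self.chrom_length_bp:
            raise ValueError("more SNPs than base pairs on a chromosome")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        # A tiny founder pool cannot reliably segregate both alleles above
        # the MAF floor; require at least 1/(2*floor) founder haplotypes.
        if self.n_founders < max(2, int(round(1.0 / (2 * self.maf_floor)))):
            raise ValueError(
                f"n_founders={self.n_founders} too small to sustain "
                f"MAF >= {self.maf_floor}"
            )
        if self.ld_decay_rate < 0:
            raise ValueError("ld_decay_rate must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < min <= max")
        if self.n_year_seasons < 1:
            raise ValueError("n_year_seasons must be >= 1")
        if self.year_season_effects is not None and len(
            self.year_season_effects
        ) != self.n_year_seasons:
            raise ValueError("year_season_effects length != n_year_seasons")
        vf = self.var_fractions
        if len(vf) != 4 or any(v < 0 for v in vf):
            raise ValueError("var_fractions must be 4 non-negative entries")
        if abs(sum(vf) - 1.0) > 1e-12:
            raise ValueError("var_fractions must sum to 1 (±1e-12)")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}
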