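"""Synthetic phased genomes, gene annotations and phenotypes.

The generator emulates the data structure of a single-breed nucleus pig
population. Haplotypes are produced by a founder-copying (mosaic) process:
each of the 2n population haplotypes copies a founder template and switches
templates between adjacent SNPs with probability 1 - exp(-rate * distance),
which yields linkage disequilibrium that decays with physical distance and
few distinct haplotypes per block. Phenotypes are assembled exactly from the
generative form of the prediction model:

    y = X b + W_add a0 + W_dom d0 + W_hap ah0 + e,

with each genetic component and the residual rescaled so its realized
variance equals the configured fraction of a unit phenotypic variance —
the configured fractions are therefore realized heritabilities. Haplotype
allele effects are drawn per distinct allele within causal blocks, inducing
within-block interaction ("haplotype epistasis") that SNP additive coding
cannot represent.

All randomness flows from ``SimConfig.seed``; every operation derives its
own independent stream from it, so the full simulation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coding
from .blocks import BlockSet
from .config import SimConfig
from .genotypes import PhasedGenotypes

__all__ = [
    "TruthRecord",
    "simulate_genotypes",
    "simulate_genes",
    "simulate_phenotypes",
]

# stream offsets so each operation has its own substream of config.seed
_GENO_STREAM, _GENE_STREAM, _PHENO_STREAM = 1, 2, 3


@dataclass
class TruthRecord:
    """Ground truth of one simulated phenotype, for recovery tests."""

    fixed_effects: np.ndarray          # value per year-season level
    year_season: np.ndarray            # level index per individual
    causal_snp_indices: np.ndarray
    additive_effects: np.ndarray       # a0 per causal SNP (post-scaling)
    dominance_effects: np.ndarray      # d0 per causal SNP (post-scaling)
    causal_block_ids: list[str]
    haplotype_allele_effects: pd.DataFrame  # block_id, allele, effect
    components: dict[str, np.ndarray]  # per-individual a, d, ah, e
    realized_variances: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_genotypes(config: SimConfig) -> PhasedGenotypes:
    """Phased biallelic genotypes with distance-decaying LD.

    Founder allele frequencies are drawn inside [maf_floor, 1 - maf_floor];
    any SNP whose realized population minor allele frequency falls below the
    floor has its founder alleles resampled (copy paths fixed) until the
    floor holds, so the output respects it exactly.
    """
    rng = _rng(config, _GENO_STREAM)
    n, f = config.n_individuals, config.n_founders
    n_hap = 2 * n
    chroms, positions, hap_chunks = [], [], []
    for chrom in config.chrom_names:
        m = config.n_snps_per_chrom
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=m, replace=False)
        )
        # founder pool
        p0 = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
        founders = (rng.random((f, m)) < p0).astype(np.int8)
        # copying paths for all 2n haplotypes
        path = np.empty((n_hap, m), dtype=np.int64)
        path[:, 0] = rng.integers(f, size=n_hap)
        gaps = np.diff(pos)
        switch_p = 1.0 - np.exp(-config.ld_decay_rate * gaps)
        for j in range(1, m):
            switch = rng.random(n_hap) < switch_p[j - 1]
            path[:, j] = np.where(
                switch, rng.integers(f, size=n_hap), path[:, j - 1]
            )
        alleles = founders[path, np.arange(m)]
        # enforce the empirical MAF floor by resampling founder columns
        for j in range(m):
            for attempt in range(200):
                freq = alleles[:, j].mean()
                if min(freq, 1.0 - freq) >= config.maf_floor:
                    break
                p_new = rng.uniform(
                    config.maf_floor, 1.0 - config.maf_floor
                )
                founders[:, j] = (rng.random(f) < p_new).astype(np.int8)
                alleles[:, j] = founders[path[:, j], j]
            else:
                raise RuntimeError(
                    f"could not reach MAF >= {config.maf_floor} at SNP {j} "
                    f"on chromosome {chrom}; increase n_founders"
                )
        chroms.append(np.full(m, chrom, dtype=object))
        positions.append(pos)
        hap_chunks.append(alleles.reshape(n, 2, m))
    return PhasedGenotypes(
        samples=[f"ind{i + 1}" for i in range(n)],
        chrom=np.concatenate(chroms),
        positions=np.concatenate(positions),
        haplotypes=np.concatenate(hap_chunks, axis=2),
        chrom_lengths=config.chrom_lengths,
    )


def simulate_genes(config: SimConfig) -> pd.DataFrame:
    """Gene intervals per chromosome (0-based half-open).

    Lengths follow a min-shifted exponential (scale
    ``gene_length_scale_bp``), resampled above the configured maximum; with
    the defaults about 78% of genes are shorter than 50 kb, mirroring the
    preponderance of short genes in mammalian annotations. Genes may
    overlap; each lies fully within its chromosome.
    """
    rng = _rng(config, _GENE_STREAM)
    lo, hi = config.gene_length_range
    hi = min(hi, config.chrom_length_bp)
    rows = []
    for chrom in config.chrom_names:
        k = 0
        while k < config.n_genes_per_chrom:
            length = int(lo + rng.exponential(config.gene_length_scale_bp))
            if length > hi:
                continue
            start = int(rng.integers(0, config.chrom_length_bp - length + 1))
            rows.append((chrom, start, start + length))
            k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["gene_id"] = [f"gene{i + 1}" for i in range(len(df))]
    return df[["gene_id", "chrom", "start", "end"]]


def _scale_to_variance(x: np.ndarray, target: float, what: str) -> np.ndarray:
    """Rescale so the population variance (ddof=0) equals ``target``."""
    if target == 0.0:
        return np.zeros_like(x)
    v = float(np.var(x))
    if v == 0.0:
        raise ValueError(f"{what} component has zero variance; cannot scale")
    return x * np.sqrt(target / v)


def simulate_phenotypes(
    genotypes: PhasedGenotypes,
    blocks: BlockSet,
    config: SimConfig,
    year_season: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes from the generative SNP + haplotype model.

    Causal SNPs carry additive and dominance effects; causal blocks carry
    one effect per distinct haplotype allele. Each component is rescaled so
    its realized variance equals the configured fraction exactly. Year-season
    labels are uniform unless given explicitly.

    Returns the phenotype table (id, year_season, trait) and the truth.
    """
    rng = _rng(config, _PHENO_STREAM)
    n = genotypes.n_individuals
    m = genotypes.n_snps
    h2_a, h2_d, h2_h, h2_e = config.var_fractions

    n_causal = config.n_causal_snps if config.n_causal_snps is not None else m
    if n_causal > m:
        raise ValueError(f"n_causal_snps={n_causal} exceeds SNP count {m}")
    causal_snps = np.sort(rng.choice(m, size=n_causal, replace=False))

    n_blocks = len(blocks)
    n_causal_b = (
        config.n_causal_blocks
        if config.n_causal_blocks is not None
        else n_blocks
    )
    if n_causal_b > n_blocks:
        raise ValueError("n_causal_blocks exceeds block count")
    causal_block_pos = np.sort(
        rng.choice(n_blocks, size=n_causal_b, replace=False)
    )
    causal_blocks = BlockSet([blocks[int(i)] for i in causal_block_pos])

    a0 = rng.standard_normal(n_causal)
    d0 = rng.standard_normal(n_causal)
    w_add = coding.additive_matrix(genotypes, causal_snps)
    w_dom = coding.dominance_matrix(genotypes, causal_snps)
    a_raw = w_add @ a0
    d_raw = w_dom @ d0

    if h2_h > 0:
        w_hap, hap_meta = coding.haplotype_matrix(genotypes, causal_blocks)
        ah0 = rng.standard_normal(w_hap.shape[1])
        ah_raw = w_hap @ ah0
    else:
        hap_meta = pd.DataFrame(columns=["block_id", "allele", "freq"])
        ah0 = np.zeros(0)
        ah_raw = np.zeros(n)

    e_raw = rng.standard_normal(n)

    a = _scale_to_variance(a_raw, h2_a, "additive")
    d = _scale_to_variance(d_raw, h2_d, "dominance")
    ah = _scale_to_variance(ah_raw, h2_h, "haplotype")
    e = _scale_to_variance(e_raw - e_raw.mean(), h2_e, "residual")

    def _scaled(effects, raw, comp):
        if raw.size and np.var(raw) > 0 and comp > 0:
            return effects * np.sqrt(comp / np.var(raw))
        return np.zeros_like(effects)

    a0_s = _scaled(a0, a_raw, h2_a)
    d0_s = _scaled(d0, d_raw, h2_d)
    ah0_s = _scaled(ah0, ah_raw, h2_h) if ah0.size else ah0

    if year_season is None:
        labels = rng.integers(config.n_year_seasons, size=n)
    else:
        labels = np.asarray(year_season, dtype=np.int64)
        if labels.size != n or labels.max() >= config.n_year_seasons:
            raise ValueError("invalid explicit year_season labels")
    if config.year_season_effects is not None:
        b = np.asarray(config.year_season_effects, dtype=float)
    else:
        b = rng.normal(0.0, config.fixed_effect_sd, config.n_year_seasons)

    y = b[labels] + a + d + ah + e
    table = pd.DataFrame(
        {"id": genotypes.samples, "year_season": labels, "trait": y}
    )
    hap_effects = hap_meta.copy()
    hap_effects["effect"] = ah0_s
    truth = TruthRecord(
        fixed_effects=b,
        year_season=labels,
        causal_snp_indices=causal_snps,
        additive_effects=a0_s,
        dominance_effects=d0_s,
        causal_block_ids=[blk.block_id for blk in causal_blocks],
        haplotype_allele_effects=hap_effects[["block_id", "allele", "effect"]],
        components={"add": a, "dom": d, "hap": ah, "residual": e},
        realized_variances={
            "add": float(np.var(a)),
            "dom": float(np.var(d)),
            "hap": float(np.var(ah)),
            "residual": float(np.var(e)),
        },
    )
    return table, truth
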