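import numpy as np
import pytest

import haploblup as hb


@pytest.fixture(scope="session")
def small_cfg():
    return hb.SimConfig(
        n_individuals=100,
        n_chromosomes=1,
        chrom_length_bp=5_000_000,
        n_snps_per_chrom=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    """Shared 100-individual population with 500-kb blocks and GRMs."""
    genotypes = hb.simulate_genotypes(small_cfg)
    blocks = hb.build_fixed_blocks(genotypes, 500)
    dm = hb.build_design_matrices(genotypes, blocks)
    grms = hb.build_grms(dm)
    pheno, truth = hb.simulate_phenotypes(genotypes, blocks, small_cfg)
    return {
        "config": small_cfg,
        "genotypes": genotypes,
        "blocks": blocks,
        "dm": dm,
        "grms": grms,
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pop500():
    """500-individual population matching the recovery study conditions."""
    cfg = hb.SimConfig(
        n_individuals=500,
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        n_snps_per_chrom=150,
        seed=42,
    )
    genotypes = hb.simulate_genotypes(cfg)
    blocks = hb.build_fixed_blocks(genotypes, 500)
    dm = hb.build_design_matrices(genotypes, blocks)
    grms = hb.build_grms(dm)
    pheno, truth = hb.simulate_phenotypes(genotypes, blocks, cfg)
    return {
        "config": cfg,
        "genotypes": genotypes,
        "blocks": blocks,
        "dm": dm,
        "grms": grms,
        "pheno": pheno,
        "truth": truth,
    }


def manual_genotypes(haps, positions, chrom="1", chrom_length=None):
    """Build a PhasedGenotypes from an explicit (n, 2, m) allele array."""
    haps = np.asarray(haps, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    if chrom_length is None:
        chrom_length = int(positions.max()) + 1
    return hb.PhasedGenotypes(
        samples=[f"s{i}" for i in range(haps.shape[0])],
        chrom=np.full(haps.shape[2], chrom, dtype=object),
        positions=positions,
        haplotypes=haps,
        chrom_lengths={chrom: chrom_length},
    )


@pytest.fixture
def make_genotypes():
    return manual_genotypes
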