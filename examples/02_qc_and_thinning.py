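"""Phenotype and SNP quality control.

Removes phenotype values beyond 4 SD of the mean (single pass), filters
SNPs on minor allele frequency and Hardy-Weinberg equilibrium, and thins to
one SNP per 10-SNP window with approximately equal spacing.
"""

import numpy as np

import haploblup as hb

cfg = hb.SimConfig(n_individuals=200, seed=4)
genotypes = hb.simulate_genotypes(cfg)
blocks = hb.build_fixed_blocks(genotypes, 500)
pheno, _ = hb.simulate_phenotypes(genotypes, blocks, cfg)

# inject two gross outliers, then filter at 4 SD
y = pheno["trait"].to_numpy().copy()
y[[5, 17]] = [25.0, -25.0]
res = hb.filter_phenotype_outliers(y, k_sd=4)
print(
    f"outlier filter: removed {res.removed_indices.size} of {y.size} "
    f"values (indices {[int(i) for i in res.removed_indices]}), "
    f"mean {res.mean:.2f}, SD {res.sd:.2f}"
)

kept = hb.snp_qc(genotypes, maf_min=0.05, hwe_alpha=1e-5)
print(f"SNP QC: {kept.size}/{genotypes.n_snps} SNPs pass MAF/HWE filters")

qc_genotypes = genotypes.subset_snps(kept)
thinned = hb.thin_genotypes(qc_genotypes, window_size=10)
print(
    f"thinning: {thinned.size} SNPs kept (one per 10-SNP window, "
    "spacing-balanced selection)"
)
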