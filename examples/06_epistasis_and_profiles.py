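"""Haplotype epistasis heritability and heritability profiles.

h2_E is the total-heritability difference between a haplotype model and its
matched SNP model: the within-block interaction variance that SNP additive
and dominance coding cannot capture. The per-block heritability profile
locates where the haplotype variance sits on the genome.
"""

import numpy as np

import haploblup as hb
from haploblup.reference_data import reference_table

# --- on simulated data: one causal block, haplotype-allele effects only
cfg = hb.SimConfig(
    n_individuals=300,
    var_fractions=(0.10, 0.0, 0.30, 0.60),
    n_causal_blocks=1,
    seed=8,
)
genotypes = hb.simulate_genotypes(cfg)
blocks = hb.build_fixed_blocks(genotypes, 500)
dm = hb.build_design_matrices(genotypes, blocks)
grms = hb.build_grms(dm)
pheno, truth = hb.simulate_phenotypes(genotypes, blocks, cfg)
y = pheno["trait"].to_numpy()
x = np.ones((len(y), 1))

h_fit = hb.fit_model(y, x, grms, model=4)   # haplotype-only
s_fit = hb.fit_model(y, x, grms, model=6)   # SNP additive-only
h2_e = hb.epistasis_h2(h_fit.herit, s_fit.herit, 4)
h2_er = hb.relative_epistasis_h2(h2_e, s_fit.herit["add"], 4)
print(
    f"simulated: h2_g(H) = {h_fit.herit.h2_total:.3f}, "
    f"h2_s(A) = {s_fit.herit.h2_total:.3f}, h2_E = {h2_e:.3f} "
    f"({h2_er:.1f}% of the SNP additive heritability)"
)

profile = hb.heritability_profile(h_fit, dm, genotypes, blocks)
hap = profile[profile.component == "hap_add"]
top = hap.loc[hap["h2_share"].idxmax()]
print(
    f"top haplotype block: {top.unit_id} (share {top.h2_share:.3f}); "
    f"true causal block: {truth.causal_block_ids[0]}"
)

# --- on the published Duroc reference values: the exact arithmetic chain
print("\npublished reference arithmetic (per trait):")
ref = reference_table()
for trait, row in ref.iterrows():
    model = int(row.best_haplo_model)
    h2_e = hb.epistasis_h2(row.h2_g, row.h2_s_matched, model)
    denom = row.h2_a1 if model in (2, 4) else row.h2_a2
    print(
        f"  {trait}: h2_E = {h2_e:+.3f}, relative = "
        f"{hb.relative_epistasis_h2(h2_e, denom, model):5.2f}%, "
        f"accuracy gain = "
        f"{hb.accuracy_increase(row.best_haplo_acc_original, row.best_snp_acc_original):.2f}%"
    )
print(
    "Traits with large relative epistasis heritability gain most from "
    "haplotype models (r = 0.78 across the eight traits)."
)
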