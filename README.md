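# haploblup

Haplotype-block GBLUP/GREML genomic prediction with SNP additive, SNP
dominance and multi-allelic haplotype components.

## The problem

Genomic selection in livestock mostly relies on SNP additive models. When
phased genotypes are available, contiguous chromosome intervals — defined by
fixed distances (50 kb–5 Mb) or by gene boundaries — can instead be treated
as multi-allelic *loci* whose alleles are the distinct haplotype sequences.
Haplotype models capture local interaction (epistasis) variance invisible to
SNP additive/dominance coding, and in a Duroc boar population this raised
cross-validated prediction accuracy by up to 7.4% depending on the trait.
`haploblup` implements that full analysis as a tested Python library for
quantitative geneticists: block construction, genomic relationship matrices,
REML variance components, conditional-expectation GBLUP, cross-validated
accuracies, haplotype-epistasis heritability, and per-locus heritability
profiles — together with a synthetic-data generator so every stage can be
validated against known truth (the original pig data are private).

## The model

Phenotypes follow the multi-component mixed model

    y = Xb + Wα α₀ + Wδ δ₀ + Wαh α₀h + e
      = Xb + a + d + aₕ + e,

where `b` are year-season fixed effects, `Wα`/`Wδ` carry the quantitative-
genetics SNP additive and dominance codings (AA/Aa/aa → 2−2p, 1−2p, −2p and
−2q², 2pq, −2p²), and `Wαh` carries centered per-allele haplotype dosages.
With kₓ = tr(Wₓ Wₓ′)/n and Tₓ = Wₓ/√kₓ, the equivalent variance structure is

    var(y) = σ²α A_g + σ²δ D_g + σ²αh A_gh + σ²e I,
    A_g = Wα Wα′/kα,   D_g = Wδ Wδ′/kδ,   A_gh = Wαh Wαh′/kαh,

so each relationship matrix has trace exactly n and the σ² are on the
phenotypic scale. Six models drop or keep components (A+D+H, A+H, D+H, H,
A+D, A). Variance components are estimated by REML (EM warm start, then
average-information steps); genetic values of masked individuals are
predicted by the conditional-expectation form σ²ₓ Kₓ[all, train] P y, which
never forms the effect-level mixed model equations (those are kept as a
small-instance testing oracle). The haplotype-epistasis heritability of a
haplotype model is ĥ²_E = ĥ²_g − ĥ²_s against its matched SNP model, and a
unit's heritability share is (effect²/Σeffect²)·ĥ²-component.

## Worked example

```python
import numpy as np
import haploblup as hb

cfg = hb.SimConfig(n_individuals=300, seed=3)          # two 10-Mb autosomes
genotypes = hb.simulate_genotypes(cfg)                  # phased, MAF >= 0.05
blocks = hb.build_fixed_blocks(genotypes, 500)          # 500-kb blocks
dm = hb.build_design_matrices(genotypes, blocks)
grms = hb.build_grms(dm)                                # A_g, D_g, A_gh
pheno, truth = hb.simulate_phenotypes(genotypes, blocks, cfg)

y = pheno["trait"].to_numpy()
X, _ = hb.build_fixed_design(pheno["year_season"].to_numpy())
fit = hb.fit_model(y, X, grms, model=1)                 # A+D+H GREML
for comp in ("add", "dom", "hap"):
    print(comp, round(fit.herit[comp], 3))
```

prints the estimated heritabilities of the three genetic components

```
add 0.272
dom 0.0
hap 0.25
```

against simulated truth (0.30, 0.05, 0.10): at n = 300 a single replicate is
noisy and the SNP-additive and haplotype relationship matrices are strongly
correlated, so individual components wander while their sum is stable; the
test suite shows the estimates are unbiased over replicates at n = 500. The
scripts in `examples/` walk through each capability (simulation, QC, block
statistics, GBLUP, cross-validation, epistasis and profiles) and print the
numbers with one-line interpretations.

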